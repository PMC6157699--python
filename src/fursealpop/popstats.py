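"""Diversity, differentiation, isolation-by-distance, AMOVA and PCA.

Estimators follow the conventions of the classical population-genetics
packages: unbiased gene diversity (2n/(2n-1) * 2pq), Weir & Cockerham (1984)
variance-component theta combined across loci as a ratio of sums, Slatkin's
linearized FST, a permutation Mantel test on off-diagonal distances, and a
three-level AMOVA on squared dosage differences. Permutation p-values use
(k+1)/(n+1) smoothing throughout so that p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, PopulationMap, GenotypeError

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# allele frequencies and diversity
# ---------------------------------------------------------------------------

def allele_freqs(g: GenotypeMatrix, pops: PopulationMap, level: str = "colony") -> pd.DataFrame:
    """Alternate-allele frequency per group x locus (NaN where all missing)."""
    idx = pops.indices(g, level)
    rows = {}
    for grp, ii in idx.items():
        calls = g.calls[ii]
        ok = calls != MISSING
        n = ok.sum(axis=0)
        s = np.where(ok, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            rows[grp] = np.where(n > 0, s / (2.0 * n), np.nan)
    return pd.DataFrame(rows, index=g.locus_ids).T


def _group_het(calls: np.ndarray):
    """Per-locus (Ho, He, n_nonmissing) for one group of rows."""
    ok = calls != MISSING
    n = ok.sum(axis=0).astype(float)
    s = np.where(ok, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, s / (2.0 * n), np.nan)
        ho = np.where(n > 0, np.where(ok, calls == 1, False).sum(axis=0) / n, np.nan)
        he = np.where(n > 1, (2.0 * n / (2.0 * n - 1.0)) * 2.0 * p * (1.0 - p), np.nan)
    return ho, he, n


def heterozygosity(g: GenotypeMatrix, pops: PopulationMap, level: str = "colony") -> pd.DataFrame:
    """Mean observed and unbiased expected heterozygosity per group.

    He per locus is (2n/(2n-1)) * 2p(1-p) with n the non-missing individual
    count; group values average across loci with defined values.
    """
    idx = pops.indices(g, level)
    out = []
    for grp, ii in idx.items():
        ho, he, _ = _group_het(g.calls[ii])
        out.append(
            {
                "group": grp,
                "n": len(ii),
                "Ho": float(np.nanmean(ho)),
                "He": float(np.nanmean(he)) if np.isfinite(he).any() else np.nan,
            }
        )
    return pd.DataFrame(out).set_index("group")


def fis_test(g: GenotypeMatrix, pops: PopulationMap, group: str, n_perm: int = 1000,
             seed: int = 0, level: str = "colony"):
    """Multilocus FIS = 1 - Ho/He with an allele-permutation null.

    The null re-pairs gametes: per locus, the 2n allele copies are shuffled
    among individuals. Returns (FIS, p, defined).
    """
    ii = pops.indices(g, level)[group]
    if len(ii) < 2:
        raise GenotypeError("fis_test needs >= 2 individuals in the group")
    calls = g.calls[ii]
    rng = np.random.default_rng(seed)

    def multilocus_fis(c: np.ndarray) -> float:
        ho, he, _ = _group_het(c)
        mh, mhe = np.nanmean(ho), np.nanmean(he)
        return 1.0 - mh / mhe if mhe > 0 else np.nan

    obs = multilocus_fis(calls)
    if not np.isfinite(obs):
        return np.nan, np.nan, False

    n, L = calls.shape
    count = 0
    for _ in range(n_perm):
        perm = np.empty_like(calls)
        for j in range(L):
            col = calls[:, j]
            ok = col != MISSING
            al = np.concatenate([(col[ok] >= 1).astype(np.int8), (col[ok] == 2).astype(np.int8)])
            rng.shuffle(al)
            k = ok.sum()
            newcol = np.full(n, MISSING, dtype=np.int8)
            newcol[ok] = al[:k] + al[k:]
            perm[:, j] = newcol
        f = multilocus_fis(perm)
        if np.isfinite(f) and abs(f) >= abs(obs):
            count += 1
    p = (count + 1) / (n_perm + 1)
    return float(obs), float(p), True


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def wc_components(n_mat: np.ndarray, p_mat: np.ndarray, h_mat: np.ndarray):
    """Weir & Cockerham (1984) per-locus variance components a, b, c.

    Parameters are (r populations x L loci) arrays of sample sizes
    (individuals with calls), alternate-allele frequencies and observed
    heterozygote fractions. Loci where fewer than two populations have data
    yield NaN components.
    """
    n = n_mat.astype(float)
    valid = n >= 1
    r = valid.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        nsum = np.where(valid, n, 0).sum(axis=0)
        nbar = nsum / r
        nc = (nsum - np.where(valid, n * n, 0).sum(axis=0) / nsum) / (r - 1.0)
        pbar = np.where(valid, n * p_mat, 0).sum(axis=0) / nsum
        s2 = np.where(valid, n * (p_mat - pbar) ** 2, 0).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = np.where(valid, n * h_mat, 0).sum(axis=0) / nsum
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1.0) / r - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    bad = (r < 2) | (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    a = np.where(bad, np.nan, a)
    b = np.where(bad, np.nan, b)
    c = np.where(bad, np.nan, c)
    return a, b, c


def _pop_locus_arrays(g: GenotypeMatrix, row_groups):
    """Stack per-population (n, p, h) arrays for wc_components."""
    ns, ps, hs = [], [], []
    for rows in row_groups:
        calls = g.calls[rows]
        ok = calls != MISSING
        n = ok.sum(axis=0).astype(float)
        s = np.where(ok, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, s / (2.0 * n), np.nan)
            h = np.where(n > 0, np.where(ok, calls == 1, False).sum(axis=0) / n, np.nan)
        ns.append(n)
        ps.append(p)
        hs.append(h)
    return np.array(ns), np.array(ps), np.array(hs)


def theta_from_calls(g: GenotypeMatrix, row_groups):
    """(multilocus theta, per-locus theta) for the given row groups."""
    n, p, h = _pop_locus_arrays(g, row_groups)
    a, b, c = wc_components(n, p, h)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = a / (a + b + c)
    denom = a + b + c
    ok = np.isfinite(denom) & (denom != 0)
    if not ok.any():
        return np.nan, per_locus
    theta = np.nansum(a[ok]) / np.nansum(denom[ok])
    return float(theta), per_locus


def wc_fst(g: GenotypeMatrix, pops: PopulationMap, colony_a: str, colony_b: str,
           n_perm: int = 0, seed: int = 0):
    """Pairwise multilocus Weir-Cockerham theta with a permutation test.

    Significance permutes individuals between the two colonies; p is the
    (k+1)/(n+1)-smoothed fraction of permuted theta >= observed.
    Returns (theta, per-locus theta, p or NaN when n_perm == 0).
    """
    idx = pops.indices(g, "colony")
    ra = sorted(idx[colony_a])
    rb = sorted(idx[colony_b])
    if len(ra) < 2 or len(rb) < 2:
        raise GenotypeError("wc_fst needs >= 2 individuals per colony")
    theta, per_locus = theta_from_calls(g, [ra, rb])
    if np.isnan(theta):
        raise GenotypeError("no locus with a defined theta denominator")
    p_val = np.nan
    if n_perm > 0:
        # canonical pool order and split so (a, b) and (b, a) permute identically
        rng = np.random.default_rng(seed)
        pool = np.sort(np.concatenate([ra, rb]))
        na = min(len(ra), len(rb))
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pool)
            t, _ = theta_from_calls(g, [perm[:na], perm[na:]])
            if t >= theta:
                count += 1
        p_val = (count + 1) / (n_perm + 1)
    return theta, per_locus, p_val


def pairwise_fst_matrix(g: GenotypeMatrix, pops: PopulationMap, n_perm: int = 0,
                        seed: int = 0):
    """Colony x colony multilocus theta, linearized theta, and p-values."""
    colonies = pops.colonies()
    k = len(colonies)
    theta = np.zeros((k, k))
    pmat = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            t, _, p = wc_fst(g, pops, colonies[i], colonies[j], n_perm=n_perm,
                             seed=int(rng.integers(2**31 - 1)))
            theta[i, j] = theta[j, i] = t
            pmat[i, j] = pmat[j, i] = p
    lin = linearize_fst(theta)
    idx = pd.Index(colonies)
    return (pd.DataFrame(theta, idx, idx), pd.DataFrame(lin, idx, idx),
            pd.DataFrame(pmat, idx, idx))


def linearize_fst(theta):
    """Slatkin's linearized FST, theta / (1 - theta); infinite at theta = 1."""
    theta = np.asarray(theta, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(theta == 1.0, np.inf, theta / (1.0 - theta))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Mantel / IBD
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    defined: bool = True


def mantel_test(A: np.ndarray, B: np.ndarray, n_perm: int = 999, seed: int = 0) -> MantelResult:
    """Mantel matrix correlation with a one-sided permutation p-value.

    r is the Pearson correlation of upper-triangle entries; the null permutes
    the row/column labels of B jointly; p = (k+1)/(n+1) for permuted r >=
    observed.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise GenotypeError("mantel_test needs two square matrices of equal size")
    if not (np.allclose(A, A.T) and np.allclose(B, B.T)):
        raise GenotypeError("mantel_test matrices must be symmetric")
    iu = np.triu_indices(A.shape[0], k=1)
    x = A[iu]
    if x.std() == 0 or B[iu].std() == 0:
        return MantelResult(np.nan, np.nan, n_perm, defined=False)

    def corr(bm):
        y = bm[iu]
        return np.corrcoef(x, y)[0, 1]

    r_obs = corr(B)
    rng = np.random.default_rng(seed)
    count = 0
    n = A.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(B[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    return MantelResult(float(r_obs), (count + 1) / (n_perm + 1), n_perm)


def great_circle_km(coord_a, coord_b) -> float:
    """Haversine great-circle distance between (lat, lon) pairs, km."""
    la1, lo1 = np.radians(coord_a)
    la2, lo2 = np.radians(coord_b)
    h = np.sin((la2 - la1) / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def geographic_distance_matrix(pops: PopulationMap) -> pd.DataFrame:
    colonies = pops.colonies()
    missing = [c for c in colonies if c not in pops.coords]
    if missing:
        raise GenotypeError(f"no coordinates for colonies: {missing}")
    k = len(colonies)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            D[i, j] = D[j, i] = great_circle_km(pops.coords[colonies[i]], pops.coords[colonies[j]])
    return pd.DataFrame(D, index=colonies, columns=colonies)


def ibd_test(g: GenotypeMatrix, pops: PopulationMap, n_perm: int = 999, seed: int = 0,
             geo: pd.DataFrame | None = None) -> MantelResult:
    """Isolation by distance: Mantel of linearized FST vs geographic distance."""
    _, lin, _ = pairwise_fst_matrix(g, pops)
    if geo is None:
        geo = geographic_distance_matrix(pops)
    geo = geo.loc[lin.index, lin.columns]
    return mantel_test(lin.to_numpy(), geo.to_numpy(), n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    """Three-level AMOVA: among groups / among colonies within groups / within."""

    sigma_among_groups: float
    sigma_among_pops: float
    sigma_within: float
    pct_among_groups: float
    pct_among_pops: float
    pct_within: float
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_phi_st: float = np.nan
    p_phi_ct: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": ["among_groups", "among_pops_within_groups", "within_pops"],
                "sigma2": [self.sigma_among_groups, self.sigma_among_pops, self.sigma_within],
                "percent": [self.pct_among_groups, self.pct_among_pops, self.pct_within],
                "phi": [self.phi_ct, self.phi_sc, self.phi_st],
            }
        )


def _amova_components(D2: np.ndarray, pop_of: np.ndarray, group_of_pop: np.ndarray):
    """Variance components from a squared-distance matrix and labels."""
    N = D2.shape[0]
    pops_u = np.unique(pop_of)
    groups_u = np.unique(group_of_pop)
    P, G = len(pops_u), len(groups_u)

    def ss_within(labels, values):
        ss = 0.0
        for v in values:
            rows = np.flatnonzero(labels == v)
            if len(rows) > 1:
                sub = D2[np.ix_(rows, rows)]
                ss += sub[np.triu_indices(len(rows), k=1)].sum() / len(rows)
        return ss

    ss_total = D2[np.triu_indices(N, k=1)].sum() / N
    ss_wp = ss_within(pop_of, pops_u)
    group_of_ind = group_of_pop[np.searchsorted(pops_u, pop_of)]
    ss_wg = ss_within(group_of_ind, groups_u)
    ss_ag = ss_total - ss_wg
    ss_ap = ss_wg - ss_wp

    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    n_p = np.array([(pop_of == v).sum() for v in pops_u], dtype=float)
    n_g = np.array([(group_of_ind == v).sum() for v in groups_u], dtype=float)
    sum_np2_over_ng = sum(
        (n_p[np.searchsorted(pops_u, pops_u[group_of_pop == gv])] ** 2).sum() / n_g[i]
        for i, gv in enumerate(groups_u)
    )
    n1 = (N - sum_np2_over_ng) / df_ap if df_ap > 0 else np.nan
    n2 = (sum_np2_over_ng - (n_p**2).sum() / N) / df_ag
    n3 = (N - (n_g**2).sum() / N) / df_ag

    ms_wp = ss_wp / df_wp if df_wp > 0 else 0.0
    sigma_c = ms_wp
    if df_ap > 0:
        sigma_b = (ss_ap / df_ap - sigma_c) / n1
    else:
        sigma_b = 0.0
    sigma_a = (ss_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


def amova(g: GenotypeMatrix, pops: PopulationMap, grouping: dict | None = None,
          n_perm: int = 0, seed: int = 0) -> AmovaResult:
    """Three-level AMOVA on squared dosage differences summed over loci.

    ``grouping`` maps colony -> group label (defaults to the cluster labels).
    Missing dosages are mean-imputed per locus before distances are formed.
    Permutation tests: individuals across everything (Phi_ST) and whole
    colonies among groups (Phi_CT).
    """
    grouping = grouping or dict(pops.cluster_of)
    colony_arr = np.array([pops.colony_of[i] for i in g.individuals])
    groups = np.array(sorted({grouping[c] for c in colony_arr}))
    if len(groups) < 2:
        raise GenotypeError("amova needs >= 2 groups")

    X = g.dosage(missing_to_nan=True)
    mu = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mu, X)
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)

    pops_u = np.unique(colony_arr)
    group_of_pop = np.array([grouping[c] for c in pops_u])
    sa, sb, sc = _amova_components(sq, colony_arr, group_of_pop)
    total = sa + sb + sc
    phi_st = (sa + sb) / total if total > 0 else np.nan
    phi_ct = sa / total if total > 0 else np.nan
    phi_sc = sb / (sb + sc) if (sb + sc) > 0 else np.nan

    p_st = p_ct = np.nan
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        c_st = c_ct = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(colony_arr))
            a1, b1, c1 = _amova_components(sq, colony_arr[perm], group_of_pop)
            t1 = a1 + b1 + c1
            if t1 > 0 and (a1 + b1) / t1 >= phi_st:
                c_st += 1
            gperm = group_of_pop[rng.permutation(len(group_of_pop))]
            a2, b2, c2 = _amova_components(sq, colony_arr, gperm)
            t2 = a2 + b2 + c2
            if t2 > 0 and a2 / t2 >= phi_ct:
                c_ct += 1
        p_st = (c_st + 1) / (n_perm + 1)
        p_ct = (c_ct + 1) / (n_perm + 1)

    pct = [100.0 * s / total if total > 0 else 0.0 for s in (sa, sb, sc)]
    return AmovaResult(sa, sb, sc, *pct, phi_ct, phi_sc, phi_st, p_st, p_ct)


# ---------------------------------------------------------------------------
# marker-set concordance and PCA
# ---------------------------------------------------------------------------

def marker_concordance(he_a, he_b, fst_a, fst_b, n_perm: int = 999, seed: int = 0):
    """Concordance of two marker sets: Pearson r on He, Mantel on FST.

    Returns (pearson_r, pearson_p, mantel_r, mantel_p); Pearson values are
    NaN when either He vector is constant.
    """
    from scipy import stats

    he_a = np.asarray(he_a, dtype=float)
    he_b = np.asarray(he_b, dtype=float)
    if he_a.shape != he_b.shape:
        raise GenotypeError("He vectors must have matching colony labels/length")
    if he_a.std() == 0 or he_b.std() == 0:
        pr, pp = np.nan, np.nan
    else:
        pr, pp = stats.pearsonr(he_a, he_b)
    m = mantel_test(np.asarray(fst_a, float), np.asarray(fst_b, float), n_perm=n_perm, seed=seed)
    return float(pr) if np.isfinite(pr) else np.nan, pp, m.r, m.p


def pca(g: GenotypeMatrix, n_components: int = 10):
    """PCA of mean-imputed, frequency-centred dosages.

    Returns (scores DataFrame, explained-variance fractions). Missing calls
    are imputed with twice the allele frequency; components are deterministic
    up to sign.
    """
    X = g.dosage(missing_to_nan=True)
    p = np.nanmean(X, axis=0) / 2.0
    X = np.where(np.isnan(X), 2.0 * p, X) - 2.0 * p
    n = g.n_individuals
    cov = X @ X.T / max(1, g.n_loci)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0.0, None)
    rank = int((vals > 1e-12 * max(vals.max(), 1.0)).sum())
    k = min(n_components, rank)
    if k < n_components:
        import warnings

        warnings.warn(f"pca: truncated to rank {k}", RuntimeWarning, stacklevel=2)
    scores = vecs[:, :k] * np.sqrt(vals[:k] * n)
    frac = vals[:k] / vals.sum() if vals.sum() > 0 else np.zeros(k)
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=g.individuals, columns=cols), frac


def diversity_table(g: GenotypeMatrix, pops: PopulationMap, n_perm: int = 0,
                    seed: int = 0) -> pd.DataFrame:
    """Per-colony and per-cluster n / Ho / He / FIS (+ permutation p)."""
    frames = []
    rng = np.random.default_rng(seed)
    for level in ("cluster", "colony"):
        het = heterozygosity(g, pops, level)
        recs = []
        for grp, row in het.iterrows():
            fis = 1.0 - row.Ho / row.He if row.He > 0 else np.nan
            p = np.nan
            if n_perm > 0 and np.isfinite(fis):
                _, p, _ = fis_test(g, pops, grp, n_perm=n_perm,
                                   seed=int(rng.integers(2**31 - 1)), level=level)
            recs.append({"level": level, "group": grp, "n": int(row.n),
                         "Ho": row.Ho, "He": row.He, "FIS": fis, "FIS_p": p})
        frames.append(pd.DataFrame(recs))
    return pd.concat(frames, ignore_index=True)
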