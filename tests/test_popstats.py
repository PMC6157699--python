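"""Diversity, Weir-Cockerham theta, Mantel, AMOVA and PCA estimators."""

import numpy as np
import pandas as pd
import pytest

from fursealpop.genotypes import MISSING, GenotypeError, PopulationMap
from fursealpop.popstats import (
    allele_freqs,
    amova,
    diversity_table,
    fis_test,
    great_circle_km,
    heterozygosity,
    ibd_test,
    linearize_fst,
    mantel_test,
    marker_concordance,
    pca,
    pairwise_fst_matrix,
    wc_fst,
)
from fursealpop.synth import SynthConfig, generate_study

from conftest import make_matrix, two_pop_map


# ---------------------------------------------------------------------------
# allele frequencies and heterozygosity
# ---------------------------------------------------------------------------

def test_allele_freqs_hand_counts():
    g = make_matrix([[0, 2], [1, 2], [2, MISSING]])
    pops = two_pop_map(g, split=3)  # single colony A
    f = allele_freqs(g, pops, "colony")
    assert f.loc["A", "L0"] == pytest.approx(0.5)
    assert f.loc["A", "L1"] == pytest.approx(1.0)  # missing call excluded


def test_allele_freqs_all_missing_is_nan():
    g = make_matrix([[MISSING], [MISSING], [0]])
    pops = two_pop_map(g, split=2)
    f = allele_freqs(g, pops, "colony")
    assert np.isnan(f.loc["A", "L0"])
    assert f.loc["B", "L0"] == 0.0


def test_heterozygosity_unbiased_formula():
    # 4 individuals, p = 0.5 -> per-locus He = (8/7) * 0.5 = 0.5714...
    g = make_matrix([[0], [1], [1], [2]])
    pops = two_pop_map(g, split=4)
    het = heterozygosity(g, pops, "colony")
    assert het.loc["A", "He"] == pytest.approx(8 / 7 * 0.5)
    assert het.loc["A", "Ho"] == pytest.approx(0.5)


def test_heterozygosity_extreme_cases():
    all_het = make_matrix(np.ones((6, 4), dtype=int))
    pops = two_pop_map(all_het, split=6)
    het = heterozygosity(all_het, pops, "colony")
    assert het.loc["A", "Ho"] == 1.0
    mono = make_matrix(np.zeros((6, 4), dtype=int))
    het = heterozygosity(mono, two_pop_map(mono, split=6), "colony")
    assert het.loc["A", "Ho"] == 0.0
    assert het.loc["A", "He"] == 0.0


def test_fis_sign_and_formula():
    rng = np.random.default_rng(0)
    # all heterozygotes at p = 0.5 -> strong heterozygote excess, FIS < 0
    g = make_matrix(np.ones((12, 30), dtype=int))
    pops = two_pop_map(g, split=12)
    fis, p, ok = fis_test(g, pops, "A", n_perm=200, seed=1)
    assert ok and fis < 0
    # hand formula on a small group
    calls = rng.binomial(2, 0.4, size=(10, 20)).astype(np.int8)
    g2 = make_matrix(calls)
    pops2 = two_pop_map(g2, split=10)
    het = heterozygosity(g2, pops2, "colony")
    fis2, _, _ = fis_test(g2, pops2, "A", n_perm=10, seed=2)
    assert fis2 == pytest.approx(1 - het.loc["A", "Ho"] / het.loc["A", "He"])


def test_fis_null_case_not_significant():
    rng = np.random.default_rng(3)
    p = rng.uniform(0.2, 0.8, size=200)
    alleles = (rng.random((2, 40, 200)) < p).astype(np.int8)  # independent gametes
    g = make_matrix(alleles[0] + alleles[1])
    pops = two_pop_map(g, split=40)
    fis, pval, ok = fis_test(g, pops, "A", n_perm=300, seed=4)
    assert ok and abs(fis) < 0.05 and pval > 0.05


# ---------------------------------------------------------------------------
# Weir-Cockerham theta vs a literal component-formula oracle
# ---------------------------------------------------------------------------

def wc_oracle(pop_calls):
    """Loop-coded WC84 a/b/c components, combined as ratio of sums."""
    num = den = 0.0
    r = len(pop_calls)
    L = pop_calls[0].shape[1]
    for j in range(L):
        ns, ps, hs = [], [], []
        for calls in pop_calls:
            col = calls[:, j]
            col = col[col != MISSING]
            if len(col) == 0:
                continue
            ns.append(len(col))
            ps.append(col.sum() / (2 * len(col)))
            hs.append((col == 1).sum() / len(col))
        rr = len(ns)
        if rr < 2:
            continue
        nbar = sum(ns) / rr
        if nbar <= 1:
            continue
        nc = (sum(ns) - sum(n * n for n in ns) / sum(ns)) / (rr - 1)
        if nc <= 0:
            continue
        pbar = sum(n * p for n, p in zip(ns, ps)) / sum(ns)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((rr - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / sum(ns)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (rr - 1) / rr * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (rr - 1) / rr * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        if a + b + c != 0:
            num += a
            den += a + b + c
    return num / den


def test_wc_fst_matches_component_oracle():
    rng = np.random.default_rng(7)
    calls = np.vstack([
        rng.binomial(2, 0.3, size=(4, 3)),
        rng.binomial(2, 0.7, size=(4, 3)),
    ]).astype(np.int8)
    g = make_matrix(calls)
    pops = two_pop_map(g, split=4)
    theta, per_locus, _ = wc_fst(g, pops, "A", "B")
    assert theta == pytest.approx(wc_oracle([calls[:4], calls[4:]]), abs=1e-12)


def test_wc_fst_limits_and_symmetry():
    same = np.tile([[0], [1], [2], [1]], (2, 5)).astype(np.int8)
    g = make_matrix(same)
    pops = two_pop_map(g, split=4)
    theta, _, _ = wc_fst(g, pops, "A", "B")
    assert abs(theta) < 0.3  # identical compositions: near zero (may be negative)
    fixed = np.vstack([np.zeros((20, 5)), np.full((20, 5), 2)]).astype(np.int8)
    gf = make_matrix(fixed)
    popsf = two_pop_map(gf, split=20)
    tf, _, _ = wc_fst(gf, popsf, "A", "B")
    assert tf > 0.95
    t_ab, _, p_ab = wc_fst(gf, popsf, "A", "B", n_perm=50, seed=9)
    t_ba, _, p_ba = wc_fst(gf, popsf, "B", "A", n_perm=50, seed=9)
    assert t_ab == t_ba and p_ab == p_ba


def test_theta_increases_with_divergence_parameter():
    """Mean multilocus theta is monotone in the generator's F across a grid."""
    thetas = []
    for F in (0.001, 0.01, 0.05, 0.2):
        cfg = SynthConfig(
            colonies=tuple(
                c for c in SynthConfig().colonies[:2]
            ),
            n_loci=800,
            cluster_F=1e-6,
            missing_rate=0.0,
            seed=17,
        )
        cfg = SynthConfig(
            colonies=(
                cfg.colonies[0].__class__("A1", "NZ-North-West", 25, (-41, 172), F),
                cfg.colonies[0].__class__("B1", "NZ-South", 25, (-46, 169), F),
            ),
            n_loci=800,
            cluster_F=1e-6,
            missing_rate=0.0,
            seed=17,
        )
        g, pops, _ = generate_study(cfg)
        t, _, _ = wc_fst(g, pops, "A1", "B1")
        thetas.append(t)
    assert thetas == sorted(thetas)


def test_linearize_fst_values():
    assert linearize_fst(0.0) == 0.0
    assert linearize_fst(0.5) == pytest.approx(1.0)
    assert linearize_fst(0.02) == pytest.approx(0.02 / 0.98)
    assert np.isinf(linearize_fst(1.0))
    assert linearize_fst(-0.01) < 0  # negative passes through in sign


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def _random_dist(rng, n):
    M = rng.random((n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0)
    return M


def test_mantel_perfect_and_hand_computed():
    rng = np.random.default_rng(5)
    A = _random_dist(rng, 6)
    res = mantel_test(A, A, n_perm=99, seed=0)
    assert res.r == pytest.approx(1.0)
    B = _random_dist(rng, 4)
    res2 = mantel_test(A[:4, :4], B, n_perm=99, seed=0)
    iu = np.triu_indices(4, 1)
    assert res2.r == pytest.approx(np.corrcoef(A[:4, :4][iu], B[iu])[0, 1])


def test_mantel_agrees_with_skbio_oracle():
    skbio_mantel = pytest.importorskip("skbio.stats.distance").mantel
    from skbio import DistanceMatrix

    rng = np.random.default_rng(8)
    A, B = _random_dist(rng, 7), _random_dist(rng, 7)
    ours = mantel_test(A, B, n_perm=999, seed=1)
    r_skbio, p_skbio, _ = skbio_mantel(DistanceMatrix(A), DistanceMatrix(B),
                                       permutations=999, alternative="greater")
    assert ours.r == pytest.approx(r_skbio, abs=1e-12)
    assert ours.p == pytest.approx(p_skbio, abs=0.05)  # independent permutation streams


def test_mantel_constant_matrix_flagged():
    A = np.zeros((4, 4))
    res = mantel_test(A, A, n_perm=9, seed=0)
    assert not res.defined


def test_mantel_p_floor():
    rng = np.random.default_rng(2)
    A = _random_dist(rng, 8)
    res = mantel_test(A, A, n_perm=99, seed=3)
    assert res.p >= 1 / (99 + 1)


# ---------------------------------------------------------------------------
# AMOVA vs a nested sums-of-squares oracle
# ---------------------------------------------------------------------------

def amova_oracle(X, pop_of, group_of_pop):
    """Literal nested ANOVA on squared Euclidean dosage distances."""
    N = X.shape[0]
    D2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    pops_u = sorted(set(pop_of))
    groups_u = sorted(set(group_of_pop.values()))
    group_of_ind = [group_of_pop[p] for p in pop_of]

    def ss(labels, values):
        tot = 0.0
        for v in values:
            rows = [i for i, l in enumerate(labels) if l == v]
            s = sum(D2[i][j] for i in rows for j in rows if i < j)
            tot += s / len(rows)
        return tot

    ss_t = sum(D2[i][j] for i in range(N) for j in range(N) if i < j) / N
    ss_wp = ss(pop_of, pops_u)
    ss_wg = ss(group_of_ind, groups_u)
    P, G = len(pops_u), len(groups_u)
    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    n_p = {p: pop_of.count(p) for p in pops_u}
    n_g = {g: group_of_ind.count(g) for g in groups_u}
    s_ng = sum(n_p[p] ** 2 / n_g[group_of_pop[p]] for p in pops_u)
    n1 = (N - s_ng) / df_ap
    n2 = (s_ng - sum(v**2 for v in n_p.values()) / N) / df_ag
    n3 = (N - sum(v**2 for v in n_g.values()) / N) / df_ag
    sc = ss_wp / df_wp
    sb = ((ss_wg - ss_wp) / df_ap - sc) / n1
    sa = ((ss_t - ss_wg) / df_ag - sc - n2 * sb) / n3
    return sa, sb, sc


def test_amova_matches_nested_ss_oracle():
    rng = np.random.default_rng(11)
    X = rng.binomial(2, 0.4, size=(12, 6)).astype(np.int8)
    g = make_matrix(X)
    colonies = ["P1"] * 3 + ["P2"] * 3 + ["P3"] * 3 + ["P4"] * 3
    colony_of = dict(zip(g.individuals, colonies))
    grouping = {"P1": "G1", "P2": "G1", "P3": "G2", "P4": "G2"}
    pops = PopulationMap(colony_of, grouping)
    res = amova(g, pops)
    sa, sb, sc = amova_oracle(X.astype(float), colonies, grouping)
    assert res.sigma_among_groups == pytest.approx(sa, abs=1e-9)
    assert res.sigma_among_pops == pytest.approx(sb, abs=1e-9)
    assert res.sigma_within == pytest.approx(sc, abs=1e-9)
    assert res.pct_among_groups + res.pct_among_pops + res.pct_within == pytest.approx(100, abs=1e-6)


def test_amova_extreme_partitions():
    X = np.zeros((12, 5), dtype=np.int8)
    g = make_matrix(X)
    colony_of = {ind: f"P{i // 3}" for i, ind in enumerate(g.individuals)}
    grouping = {"P0": "G1", "P1": "G1", "P2": "G2", "P3": "G2"}
    pops = PopulationMap(colony_of, grouping)
    res = amova(g, pops)
    assert res.sigma_among_groups == res.sigma_among_pops == res.sigma_within == 0.0
    # two groups fixed for opposite alleles, colonies identical within group
    X2 = np.vstack([np.zeros((6, 5)), np.full((6, 5), 2)]).astype(np.int8)
    res2 = amova(make_matrix(X2), pops)
    assert res2.pct_among_groups > 95


def test_amova_permutation_p(small_study):
    g, pops, _ = small_study
    sub = g.subset(loci=np.arange(100))
    res = amova(sub, pops, n_perm=49, seed=2)
    assert res.p_phi_st >= 1 / 50


# ---------------------------------------------------------------------------
# concordance, PCA, IBD plumbing
# ---------------------------------------------------------------------------

def test_marker_concordance_identity_and_constant():
    rng = np.random.default_rng(13)
    he = rng.uniform(0.2, 0.3, size=8)
    F = _random_dist(rng, 8)
    r, p, mr, mp = marker_concordance(he, he, F, F, n_perm=99, seed=0)
    assert r == pytest.approx(1.0) and mr == pytest.approx(1.0)
    r2, _, _, _ = marker_concordance(np.full(8, 0.25), he, F, F, n_perm=9, seed=0)
    assert np.isnan(r2)


def test_pca_separates_duplicated_blocks():
    rng = np.random.default_rng(15)
    a = rng.binomial(2, 0.2, size=40)
    b = rng.binomial(2, 0.8, size=40)
    X = np.vstack([np.tile(a, (5, 1)), np.tile(b, (5, 1))]).astype(np.int8)
    X[0, 3] = MISSING  # exercise mean imputation
    g = make_matrix(X)
    scores, frac = pca(g, n_components=3)
    pc1 = scores.PC1.to_numpy()
    assert (pc1[:5] > 0).all() != (pc1[5:] > 0).all()  # blocks on opposite sides
    assert (np.diff(frac) <= 1e-12).all() and frac.sum() <= 1 + 1e-9
    assert (frac >= 0).all()


def test_pca_eigenvalues_match_numpy_oracle():
    rng = np.random.default_rng(16)
    X = rng.binomial(2, 0.5, size=(10, 20)).astype(np.int8)
    g = make_matrix(X)
    scores, frac = pca(g, n_components=5)
    Xc = X - X.mean(axis=0)
    vals = np.linalg.eigvalsh(Xc @ Xc.T / 20)[::-1]
    vals = np.clip(vals, 0, None)
    assert frac[:5] == pytest.approx(vals[:5] / vals.sum(), abs=1e-9)


def test_great_circle_distance_sanity():
    assert great_circle_km((0, 0), (0, 0)) == 0
    assert great_circle_km((0, 0), (0, 90)) == pytest.approx(10007.5, rel=0.01)


def test_ibd_positive_on_structured_study(small_study):
    g, pops, _ = small_study
    res = ibd_test(g, pops, n_perm=199, seed=3)
    assert res.defined and -1 <= res.r <= 1


def test_diversity_table_layout(small_study):
    g, pops, _ = small_study
    tab = diversity_table(g, pops)
    assert set(tab.level) == {"colony", "cluster"}
    assert tab.n.sum() == 2 * g.n_individuals  # each individual in one colony + one cluster
    assert tab.He.between(0, 1).all()
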