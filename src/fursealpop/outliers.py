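"""FST-outlier scan against a coalescent island-model null (FDIST-style).

The scan calibrates a finite-island null so its expected FST matches the
trimmed mean of the observed per-locus Weir-Cockerham theta, simulates a
large number of single-SNP island loci with matched sample sizes, bins the
simulated (He, theta) pairs by pooled heterozygosity, and assigns each
observed locus a two-sided rank-based p-value within its bin. p-values are
converted to Benjamini-Hochberg q-values, and loci with q at or below the
FDR threshold are called outliers (diversifying for the high-theta tail,
balancing for the low tail).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coalsim import SimConfig, expected_island_fst, island_scenario, simulate_derived
from .genotypes import GenotypeMatrix, PopulationMap, MISSING, GenotypeError
from .popstats import wc_components

logger = logging.getLogger(__name__)


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; ties keep original order stable."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise GenotypeError("p-values outside [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def _per_locus_theta(calls: np.ndarray, groups: list) -> tuple:
    """(theta per locus, pooled He per locus) for r population row groups."""
    ns, ps, hs = [], [], []
    for rows in groups:
        sub = calls[rows]
        ok = sub != MISSING
        n = ok.sum(axis=0).astype(float)
        s = np.where(ok, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ps.append(np.where(n > 0, s / (2.0 * n), np.nan))
            hs.append(np.where(n > 0, np.where(ok, sub == 1, False).sum(axis=0) / n, np.nan))
        ns.append(n)
    n_mat, p_mat, h_mat = np.array(ns), np.array(ps), np.array(hs)
    a, b, c = wc_components(n_mat, p_mat, h_mat)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
        ntot = n_mat.sum(axis=0)
        pbar = np.nansum(n_mat * p_mat, axis=0) / ntot
        ng = 2.0 * ntot
        he = (ng / (ng - 1.0)) * 2.0 * pbar * (1.0 - pbar)
    return theta, he


def _bin_index(he: np.ndarray, width: float) -> np.ndarray:
    return np.clip((np.asarray(he) / width).astype(int), 0, int(0.5 / width))


def _bin_pvalues(obs_he, obs_theta, sim_he, sim_theta, width: float = 0.02):
    """Two-sided rank p-values of observed theta within matched He bins.

    Observed loci falling in an empty bin are merged with the nearest
    non-empty bin. Returns (p, lower tail counts, bin sizes, bin id used).
    """
    obs_he = np.asarray(obs_he, float)
    obs_theta = np.asarray(obs_theta, float)
    sim_bin = _bin_index(sim_he, width)
    nbins = int(0.5 / width) + 1
    by_bin = [np.sort(np.asarray(sim_theta)[sim_bin == b]) for b in range(nbins)]
    occupied = np.array([len(v) > 0 for v in by_bin])
    if not occupied.any():
        raise GenotypeError("no simulated loci to build the null envelope")
    occ_ids = np.flatnonzero(occupied)
    p = np.empty(len(obs_he))
    used = np.empty(len(obs_he), dtype=int)
    n_merged = 0
    for i, (he, th) in enumerate(zip(obs_he, obs_theta)):
        b = int(np.clip(he / width, 0, nbins - 1))
        if not occupied[b]:
            b = occ_ids[np.argmin(np.abs(occ_ids - b))]
            n_merged += 1
        sims = by_bin[b]
        n = len(sims)
        c_lo = np.searchsorted(sims, th, side="right")      # sims <= th
        c_hi = n - np.searchsorted(sims, th, side="left")   # sims >= th
        p[i] = min(1.0, 2.0 * (min(c_lo, c_hi) + 1) / (n + 1))
        used[i] = b
    if n_merged:
        logger.info("fdist_scan: %d observed loci used a merged He bin", n_merged)
    return p, used, by_bin


@dataclass
class OutlierTable:
    """Per-locus scan results plus the simulated null envelope per He bin."""

    table: pd.DataFrame   # locus_id, He, theta, p, q, direction
    envelope: pd.DataFrame  # he_bin, lower, upper, n_sims
    null_fst: float
    migration_rate: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def fdist_scan(g: GenotypeMatrix, pops: PopulationMap, n_sims: int = 50_000,
               ci: float = 0.99, seed: int = 0, deme_size: float = 1000.0,
               n_demes: int | None = None, he_bin_width: float = 0.02,
               trim: float = 0.05, fdr: float = 0.05,
               min_maf_pooled: float = 0.05) -> OutlierTable:
    """FDIST-style outlier scan of every locus in ``g``.

    The island null's migration rate is solved so its expected FST equals
    the trimmed mean of the observed per-locus theta; ``n_sims`` single-SNP
    island loci with the observed per-colony sample sizes provide the null
    (He, theta) cloud. ``ci`` sets the reported envelope quantiles.
    """
    idx = pops.indices(g, "colony")
    groups = list(idx.values())
    if len(groups) < 2:
        raise GenotypeError("fdist_scan needs >= 2 populations")
    d = n_demes or len(groups)
    theta, he = _per_locus_theta(g.calls, groups)
    ok = np.isfinite(theta)
    t_sorted = np.sort(theta[ok])
    k = int(trim * len(t_sorted))
    trimmed = t_sorted[k: len(t_sorted) - k] if len(t_sorted) > 2 * k else t_sorted
    target = max(float(trimmed.mean()), 1e-4)
    c = d / (d - 1.0)
    m = (1.0 / target - 1.0) / (4.0 * deme_size * c * c)

    sample_sizes = [len(r) for r in groups]
    if len(sample_sizes) != d:  # custom deme count: recycle observed sizes
        sample_sizes = [sample_sizes[i % len(sample_sizes)] for i in range(d)]
    # null loci carry the same pooled-MAF ascertainment as the filtered data,
    # so simulated He bins match the observable range
    sc = island_scenario(d, deme_size, m, sample_sizes)
    derived = simulate_derived(sc, SimConfig(n_sims, min_maf_pooled=min_maf_pooled, seed=seed))
    sim_calls = np.vstack([
        (derived[o: o + 2 * n: 2] + derived[o + 1: o + 2 * n: 2]).astype(np.int8)
        for o, n in zip(np.cumsum([0] + [2 * n for n in sample_sizes[:-1]]), sample_sizes)
    ])
    sim_groups = []
    start = 0
    for n in sample_sizes:
        sim_groups.append(np.arange(start, start + n))
        start += n
    sim_theta, sim_he = _per_locus_theta(sim_calls, sim_groups)
    sim_ok = np.isfinite(sim_theta)
    sim_theta, sim_he = sim_theta[sim_ok], sim_he[sim_ok]

    p = np.full(len(theta), np.nan)
    p[ok], used, by_bin = _bin_pvalues(he[ok], theta[ok], sim_he, sim_theta, he_bin_width)

    q = np.full(len(theta), np.nan)
    q[ok] = bh_qvalues(p[ok])

    direction = np.array(["none"] * len(theta), dtype=object)
    med = np.array([np.median(v) if len(v) else np.nan for v in by_bin])
    full_used = np.full(len(theta), -1, dtype=int)
    full_used[ok] = used
    hi = ok.copy()
    hi[ok] = theta[ok] > med[used]
    direction[hi] = "diversifying"
    direction[ok & ~hi] = "balancing"

    lo_q, hi_q = (1 - ci) / 2.0, 1 - (1 - ci) / 2.0
    env_lo = np.full(len(by_bin), np.nan)
    env_hi = np.full(len(by_bin), np.nan)
    env_rows = []
    for b, v in enumerate(by_bin):
        if len(v) == 0:
            continue
        env_lo[b], env_hi[b] = np.quantile(v, lo_q), np.quantile(v, hi_q)
        env_rows.append({"he_bin": b * he_bin_width, "lower": float(env_lo[b]),
                         "upper": float(env_hi[b]), "n_sims": len(v)})
    above = np.zeros(len(theta), dtype=bool)
    below = np.zeros(len(theta), dtype=bool)
    above[ok] = theta[ok] > env_hi[used]
    below[ok] = theta[ok] < env_lo[used]
    tab = pd.DataFrame({
        "locus_id": g.locus_ids, "He": he, "theta": theta, "p": p, "q": q,
        "outlier": q <= fdr, "direction": direction,
        "above_ci": above, "below_ci": below,
    })
    return OutlierTable(tab, pd.DataFrame(env_rows), target, m)


def call_outliers(t: OutlierTable, fdr: float = 0.05):
    """Locus-id lists (diversifying, balancing) with q-value at or below fdr."""
    tab = t.table
    if "q" not in tab:
        raise GenotypeError("OutlierTable lacks q-values")
    hit = tab.q <= fdr
    div = tab.locus_id[hit & (tab.direction == "diversifying")].tolist()
    bal = tab.locus_id[hit & (tab.direction == "balancing")].tolist()
    return div, bal


def envelope_outliers(t: OutlierTable):
    """Locus-id lists outside the simulated CI envelope (FDIST criterion).

    Returns (diversifying, balancing): loci whose theta falls above the upper
    or below the lower envelope quantile of their He bin.
    """
    tab = t.table
    return tab.locus_id[tab.above_ci.fillna(False)].tolist(), \
        tab.locus_id[tab.below_ci.fillna(False)].tolist()
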