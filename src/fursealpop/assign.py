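"""Leave-one-out frequency-based assignment of individuals to populations.

Each individual is treated as unknown in origin: its home population's
allele frequencies are recomputed with the individual excluded (leave-one-
out), zero and one frequencies are replaced by a small substitute (no
renormalization), and the individual's genotype log10-likelihood under
Hardy-Weinberg proportions is evaluated against every candidate population.
The best population is the likelihood argmax; a Monte-Carlo home p-value
positions the observed home likelihood within genotypes simulated from the
home frequencies. Missing calls are imputed once per analysis by drawing
allele pairs from the global allele pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, PopulationMap, MISSING, GenotypeError


@dataclass
class AssignConfig:
    """Assignment settings: zero-frequency substitute, null draws, seed."""

    zero_freq_substitute: float = 0.005
    alpha: float = 0.05
    n_null_draws: int = 10_000
    seed: int = 0
    compute_pvalues: bool = True

    def validate(self) -> None:
        if not 0.0 < self.zero_freq_substitute < 1.0:
            raise GenotypeError("zero_freq_substitute must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise GenotypeError("alpha must be in (0, 1)")


@dataclass
class AssignmentResult:
    """Per-individual log-likelihood table plus per-group accuracies."""

    loglik: pd.DataFrame        # individuals x populations, log10 L
    best: pd.Series             # argmax population per individual
    true_label: pd.Series
    home_p: pd.Series
    accuracy: dict              # group -> proportion correctly assigned
    overall_accuracy: float
    level: str
    excluded_groups: tuple = ()

    def accuracy_frame(self) -> pd.DataFrame:
        rows = [{"group": g, "accuracy": a} for g, a in self.accuracy.items()]
        rows.append({"group": "overall", "accuracy": self.overall_accuracy})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        out = self.loglik.copy()
        out["best"] = self.best
        out["true"] = self.true_label
        out["home_p"] = self.home_p
        out.to_csv(path, sep="\t", index_label="individual")


def _counts(calls: np.ndarray):
    """(alt-allele count, called-allele count) per locus for a block of rows."""
    ok = calls != MISSING
    alt = np.where(ok, calls, 0).sum(axis=0).astype(float)
    tot = 2.0 * ok.sum(axis=0)
    return alt, tot


def _substitute(freq: np.ndarray, sub: float) -> np.ndarray:
    """Replace frequencies of exactly 0 or 1 (no renormalization)."""
    out = freq.copy()
    out[~np.isfinite(out)] = 0.0  # no data: treat as absent allele
    out[out <= 0.0] = sub
    out[out >= 1.0] = 1.0 - sub
    return out


def loo_frequencies(g: GenotypeMatrix, pops: PopulationMap, focal: str,
                    level: str = "colony", cfg: AssignConfig | None = None) -> pd.DataFrame:
    """Per-population alternate-allele frequencies with the focal individual
    excluded from its home population (other populations are untouched)."""
    cfg = cfg or AssignConfig()
    cfg.validate()
    idx = pops.indices(g, level)
    grp = pops.group_of(level)
    home = grp[focal]
    if len(idx[home]) < 2:
        raise GenotypeError(f"home population {home!r} of size 1: cannot leave out {focal!r}")
    i_focal = g.individuals.index(focal)
    out = {}
    for pop, rows in idx.items():
        use = rows[rows != i_focal] if pop == home else rows
        alt, tot = _counts(g.calls[use])
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(tot > 0, alt / tot, np.nan)
        out[pop] = _substitute(f, cfg.zero_freq_substitute)
    return pd.DataFrame(out, index=g.locus_ids).T


def genotype_loglik(calls: np.ndarray, freqs: np.ndarray) -> float:
    """log10 likelihood of a dosage vector under HWE at the given frequencies.

    ``calls`` must be fully imputed (no missing values).
    """
    calls = np.asarray(calls)
    p = np.asarray(freqs, float)
    if ((p <= 0) | (p >= 1)).any():
        raise GenotypeError("frequencies must be strictly inside (0, 1)")
    ll = np.where(calls == 0, 2 * np.log10(1 - p),
                  np.where(calls == 1, np.log10(2 * p * (1 - p)), 2 * np.log10(p)))
    return float(ll.sum())


def _impute_global(g: GenotypeMatrix, rng: np.random.Generator) -> np.ndarray:
    """Fill missing calls by drawing allele pairs from the global pool (once)."""
    calls = g.calls.copy()
    alt, tot = _counts(g.calls)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / tot, 0.5)
    miss = calls == MISSING
    if miss.any():
        rows, cols = np.nonzero(miss)
        calls[rows, cols] = rng.binomial(2, p[cols]).astype(np.int8)
    return calls


def _loglik_tables(freqs: np.ndarray) -> np.ndarray:
    """(pops, loci, 3) log10 genotype probabilities for dosages 0/1/2."""
    q = 1.0 - freqs
    return np.stack([2 * np.log10(q), np.log10(2 * freqs * q), 2 * np.log10(freqs)], axis=-1)


def assign_individuals(g: GenotypeMatrix, pops: PopulationMap, level: str = "colony",
                       cfg: AssignConfig | None = None,
                       exclude_from_average=()) -> AssignmentResult:
    """Score every individual against every population at the chosen level.

    Home scores use leave-one-out frequencies; accuracy is the fraction of
    individuals whose likelihood argmax equals their true label, per group
    and overall (optionally excluding listed groups from the overall mean,
    mirroring the admixture-zone masks).
    """
    cfg = cfg or AssignConfig()
    cfg.validate()
    pops.validate_against(g)
    idx = pops.indices(g, level)
    for pop, rows in idx.items():
        if len(rows) < 2:
            raise GenotypeError(f"population {pop!r} has fewer than 2 individuals")
    grp = pops.group_of(level)
    rng = np.random.default_rng(cfg.seed)
    calls = _impute_global(g, rng)

    pop_names = list(idx)
    n_pop = len(pop_names)
    # per-population allele counts (for fast LOO subtraction)
    alt = np.empty((n_pop, g.n_loci))
    tot = np.empty((n_pop, g.n_loci))
    for k, pop in enumerate(pop_names):
        alt[k], tot[k] = _counts(g.calls[idx[pop]])
    with np.errstate(invalid="ignore", divide="ignore"):
        base_freq = np.where(tot > 0, alt / tot, np.nan)
    base_freq = np.vstack([_substitute(base_freq[k], cfg.zero_freq_substitute)
                           for k in range(n_pop)])
    base_tables = _loglik_tables(base_freq)

    loglik = np.empty((g.n_individuals, n_pop))
    home_p = np.full(g.n_individuals, np.nan)
    pop_pos = {p: k for k, p in enumerate(pop_names)}
    for i, ind in enumerate(g.individuals):
        home = grp[ind]
        k_home = pop_pos[home]
        dose = calls[i]
        # non-home populations: precomputed tables
        ll = base_tables[:, np.arange(g.n_loci), dose].sum(axis=1)
        # home: leave-one-out counts use only the individual's *observed* calls
        obs = g.calls[i]
        ok = obs != MISSING
        alt_loo = alt[k_home] - np.where(ok, obs, 0)
        tot_loo = tot[k_home] - 2.0 * ok
        with np.errstate(invalid="ignore", divide="ignore"):
            f_loo = np.where(tot_loo > 0, alt_loo / tot_loo, np.nan)
        f_loo = _substitute(f_loo, cfg.zero_freq_substitute)
        ll[k_home] = genotype_loglik(dose, f_loo)
        loglik[i] = ll
        if cfg.compute_pvalues:
            sims = rng.binomial(2, f_loo, size=(cfg.n_null_draws, g.n_loci))
            tab = _loglik_tables(f_loo[None, :])[0]
            sim_ll = tab[np.arange(g.n_loci), sims].sum(axis=1)
            home_p[i] = (1 + (sim_ll <= ll[k_home]).sum()) / (cfg.n_null_draws + 1)

    ll_df = pd.DataFrame(loglik, index=g.individuals, columns=pop_names)
    best = ll_df.idxmax(axis=1)
    truth = pd.Series({ind: grp[ind] for ind in g.individuals})
    correct = best == truth
    accuracy = {pop: float(correct[truth == pop].mean()) for pop in pop_names}
    mask = ~truth.isin(exclude_from_average)
    overall = float(correct[mask].mean())
    return AssignmentResult(ll_df, best, truth, pd.Series(home_p, index=g.individuals),
                            accuracy, overall, level, tuple(exclude_from_average))


def panel_assign(g: GenotypeMatrix, pops: PopulationMap, panels: dict,
                 level: str = "colony", cfg: AssignConfig | None = None) -> dict:
    """Run :func:`assign_individuals` on named locus panels.

    ``panels`` maps panel name -> iterable of locus ids (a dict or a list of
    (name, loci) pairs); returns name -> AssignmentResult.
    """
    if not isinstance(panels, dict):
        pairs = list(panels)
        names = [n for n, _ in pairs]
        if len(set(names)) != len(names):
            raise GenotypeError("duplicate panel names")
        panels = dict(pairs)
    names = list(panels)
    pos = {lid: j for j, lid in enumerate(g.locus_ids)}
    out = {}
    for name in names:
        loci = list(panels[name])
        if not loci:
            raise GenotypeError(f"panel {name!r} is empty")
        missing = [l for l in loci if l not in pos]
        if missing:
            raise GenotypeError(f"panel {name!r}: unknown loci {missing[:5]}")
        cols = np.asarray(sorted(pos[l] for l in loci))
        out[name] = assign_individuals(g.subset(loci=cols), pops, level=level, cfg=cfg)
    return out
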