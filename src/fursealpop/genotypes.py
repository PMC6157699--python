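"""SNP genotype matrices, PLINK/VCF I/O and the quality-control filter chain.

Genotypes are stored as alternate-allele dosages (0, 1, 2) with ``MISSING``
(-1) for no-calls, one row per individual and one column per biallelic locus.
The QC chain reproduces the standard reduced-representation filtering order:
individual missingness, locus missingness, minor-allele frequency, a
per-population Hardy-Weinberg exact test, and windowed LD pruning, with the
latter two applied only when flagged in a minimum number of populations.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

MISSING = -1


class GenotypeError(ValueError):
    """Malformed genotype data or an operation emptying the dataset."""


@dataclass(frozen=True)
class LocusInfo:
    """Metadata for one biallelic SNP locus.

    ``alleles`` is an ordered (reference-like, alternate-like) pair; dosages
    count copies of the alternate allele as written in the source file.
    """

    locus_id: str
    chrom: str = "0"
    position: int = 1
    alleles: tuple[str, str] = ("A", "G")

    def __post_init__(self) -> None:
        if self.position < 1:
            raise GenotypeError(f"locus {self.locus_id}: position must be >= 1")
        if self.alleles[0] == self.alleles[1]:
            raise GenotypeError(f"locus {self.locus_id}: alleles must be distinct")


class GenotypeMatrix:
    """Individuals x loci matrix of alternate-allele dosages.

    Parameters
    ----------
    individuals : sequence of str
        Unique individual identifiers (row order).
    loci : sequence of LocusInfo
        Unique loci (column order).
    calls : ndarray of int
        ``(n_individuals, n_loci)`` dosages in {0, 1, 2, MISSING}.
    """

    def __init__(self, individuals, loci, calls) -> None:
        self.individuals = list(individuals)
        self.loci = list(loci)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.ndim != 2 or calls.shape != (len(self.individuals), len(self.loci)):
            raise GenotypeError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        if len(self.individuals) < 1 or len(self.loci) < 1:
            raise GenotypeError("need at least one individual and one locus")
        if len(set(self.individuals)) != len(self.individuals):
            raise GenotypeError("duplicate individual IDs")
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise GenotypeError("duplicate locus IDs")
        bad = ~np.isin(calls, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeError(f"{bad.sum()} calls outside {{0,1,2,MISSING}}")
        self.calls = calls

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def dosage(self, missing_to_nan: bool = False) -> np.ndarray:
        """Calls as float with missing optionally mapped to NaN."""
        out = self.calls.astype(float)
        if missing_to_nan:
            out[self.calls == MISSING] = np.nan
        return out

    def subset(self, individuals=None, loci=None) -> "GenotypeMatrix":
        """Row/column subset by boolean mask or integer index array."""
        rows = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        cols = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        if cols.dtype == bool:
            cols = np.flatnonzero(cols)
        if rows.size == 0:
            raise GenotypeError("subset would remove every individual")
        if cols.size == 0:
            raise GenotypeError("subset would remove every locus")
        return GenotypeMatrix(
            [self.individuals[i] for i in rows],
            [self.loci[j] for j in cols],
            self.calls[np.ix_(rows, cols)],
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return f"<GenotypeMatrix {self.n_individuals} individuals x {self.n_loci} loci>"


class PopulationMap:
    """Colony membership, colony->cluster labels and optional coordinates.

    ``coords`` maps colony code to (latitude, longitude) in decimal degrees
    and is only required for isolation-by-distance analyses.
    """

    def __init__(self, colony_of: dict, cluster_of: dict, coords: dict | None = None) -> None:
        self.colony_of = dict(colony_of)
        self.cluster_of = dict(cluster_of)
        self.coords = dict(coords) if coords else {}
        missing = {c for c in self.colony_of.values() if c not in self.cluster_of}
        if missing:
            raise GenotypeError(f"colonies without a cluster label: {sorted(missing)}")

    def colonies(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.colony_of.values():
            seen.setdefault(c, None)
        return list(seen)

    def clusters(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.colonies():
            seen.setdefault(self.cluster_of[c], None)
        return list(seen)

    def group_of(self, level: str) -> dict:
        """individual -> group label at the requested level."""
        if level == "colony":
            return dict(self.colony_of)
        if level == "cluster":
            return {i: self.cluster_of[c] for i, c in self.colony_of.items()}
        if level == "global":
            return {i: "all" for i in self.colony_of}
        raise KeyError(f"unknown level {level!r}")

    def indices(self, g: GenotypeMatrix, level: str = "colony") -> dict:
        """group label -> integer row indices into ``g``."""
        grp = self.group_of(level)
        out: dict[str, list[int]] = {}
        for i, ind in enumerate(g.individuals):
            if ind not in grp:
                raise GenotypeError(f"individual {ind!r} missing from population map")
            out.setdefault(grp[ind], []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in out.items()}

    def validate_against(self, g: GenotypeMatrix) -> None:
        missing = [i for i in g.individuals if i not in self.colony_of]
        if missing:
            raise GenotypeError(f"{len(missing)} individuals have no colony assignment")

    @classmethod
    def from_tsv(cls, path) -> "PopulationMap":
        """Read a populations table: individual, colony, cluster[, lat, lon]."""
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str, 2: str})
        colony_of = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
        cluster_of = dict(zip(df.iloc[:, 1], df.iloc[:, 2]))
        coords = {}
        if df.shape[1] >= 5:
            for _, r in df.iterrows():
                coords[r.iloc[1]] = (float(r.iloc[3]), float(r.iloc[4]))
        return cls(colony_of, cluster_of, coords)

    def to_tsv(self, path) -> None:
        rows = []
        for ind, col in self.colony_of.items():
            row = [ind, col, self.cluster_of[col]]
            if col in self.coords:
                row += [self.coords[col][0], self.coords[col][1]]
            rows.append(row)
        ncol = max(len(r) for r in rows)
        names = ["individual", "colony", "cluster", "lat", "lon"][:ncol]
        pd.DataFrame(rows, columns=names).to_csv(path, sep="\t", index=False)


@dataclass
class QCConfig:
    """Thresholds for the five-step QC chain (fractions in [0, 1])."""

    max_individual_missing_fraction: float = 0.90
    max_locus_missing_fraction: float = 0.20
    min_maf: float = 0.05
    hwe_alpha: float = 0.01
    ld_r2_threshold: float = 0.8
    ld_window_loci: int = 50
    min_populations_flagged: int = 6
    n_populations_expected: int = 8

    def validate(self) -> None:
        for name in ("max_individual_missing_fraction", "max_locus_missing_fraction", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GenotypeError(f"QCConfig.{name}={v} outside [0,1]")
        if not 0.0 < self.hwe_alpha < 1.0:
            raise GenotypeError("hwe_alpha must be in (0,1)")
        if not 0.0 <= self.ld_r2_threshold <= 1.0:
            raise GenotypeError("ld_r2_threshold outside [0,1]")
        if self.min_populations_flagged > self.n_populations_expected:
            raise GenotypeError("min_populations_flagged > n_populations_expected")


@dataclass
class FilterStep:
    name: str
    n_individuals_removed: int
    n_loci_removed: int
    n_individuals_after: int
    n_loci_after: int


@dataclass
class FilterReport:
    """Ordered record of removals for each QC step."""

    steps: list = field(default_factory=list)

    def add(self, name, ind_removed, loci_removed, ind_after, loci_after) -> None:
        if ind_removed < 0 or loci_removed < 0:
            raise GenotypeError("negative removal count")
        self.steps.append(FilterStep(name, ind_removed, loci_removed, ind_after, loci_after))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path=None):
        payload = json.dumps([vars(s) for s in self.steps], indent=1)
        if path is None:
            return payload
        with open(path, "w") as fh:
            fh.write(payload)
        return None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str, map_path=None) -> GenotypeMatrix:
    """Read a genotype matrix from PLINK text PED/MAP or VCF.

    For ``ped_map`` the MAP file defaults to the PED path with a ``.map``
    suffix. VCF records that are not biallelic SNPs are skipped with a
    logged count.
    """
    if format == "ped_map":
        return read_ped(path, map_path)
    if format == "vcf":
        return read_vcf(path)
    raise GenotypeError(f"unknown format {format!r}")


def read_ped(ped_path, map_path=None) -> GenotypeMatrix:
    """Read PLINK text PED + MAP (allele-pair coding, '0' = missing)."""
    ped_path = str(ped_path)
    if map_path is None:
        map_path = ped_path[: -len(".ped")] + ".map" if ped_path.endswith(".ped") else ped_path + ".map"
    mp = pd.read_csv(map_path, sep=r"\s+", header=None, dtype=str)
    if mp.shape[1] < 4:
        raise GenotypeError(f"{map_path}: MAP needs 4 columns, found {mp.shape[1]}")
    n_loci = len(mp)

    individuals: list[str] = []
    rows: list[np.ndarray] = []
    allele_pairs: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_loci:
                raise GenotypeError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * n_loci} fields, got {len(parts)}"
                )
            individuals.append(parts[1])
            allele_pairs.append(parts[6:])
    if not individuals:
        raise GenotypeError(f"{ped_path}: no individuals")

    al = np.asarray(allele_pairs, dtype="U8").reshape(len(individuals), n_loci, 2)
    # per-locus allele inventory: first observed allele is reference-like
    loci: list[LocusInfo] = []
    calls = np.full((len(individuals), n_loci), MISSING, dtype=np.int8)
    for j in range(n_loci):
        col = al[:, j, :]
        obs = col[col != "0"]
        uniq = pd.unique(obs)
        if len(uniq) > 2:
            raise GenotypeError(f"locus {mp.iloc[j, 1]}: more than two alleles in PED")
        ref = uniq[0] if len(uniq) >= 1 else "A"
        alt = uniq[1] if len(uniq) == 2 else ("G" if ref != "G" else "A")
        miss = (col == "0").any(axis=1)
        dose = (col == alt).sum(axis=1).astype(np.int8)
        dose[miss] = MISSING
        calls[:, j] = dose
        loci.append(
            LocusInfo(str(mp.iloc[j, 1]), str(mp.iloc[j, 0]), max(1, int(mp.iloc[j, 3])), (str(ref), str(alt)))
        )
    return GenotypeMatrix(individuals, loci, calls)


def write_ped(g: GenotypeMatrix, ped_path, map_path=None) -> None:
    """Write PLINK text PED + MAP; missing calls become '0 0'."""
    ped_path = str(ped_path)
    if map_path is None:
        map_path = ped_path[: -len(".ped")] + ".map" if ped_path.endswith(".ped") else ped_path + ".map"
    with open(map_path, "w") as fh:
        for l in g.loci:
            fh.write(f"{l.chrom}\t{l.locus_id}\t0\t{l.position}\n")
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(g.individuals):
            fields = [ind, ind, "0", "0", "0", "-9"]
            for j, l in enumerate(g.loci):
                d = g.calls[i, j]
                ref, alt = l.alleles
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [ref, ref]
                elif d == 1:
                    fields += [ref, alt]
                else:
                    fields += [alt, alt]
            fh.write(" ".join(fields) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF via cyvcf2; others are skipped."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individuals = list(vcf.samples)
    loci: list[LocusInfo] = []
    cols: list[np.ndarray] = []
    skipped = 0
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1 or len(rec.REF) != 1 or len(alts[0]) != 1:
            skipped += 1
            continue
        gt = rec.gt_types.astype(np.int8)  # 0/1/2 alt dosage, 3 = unknown with gts012
        gt[gt == 3] = MISSING
        cols.append(gt.copy())
        locus_id = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        loci.append(LocusInfo(locus_id, rec.CHROM, rec.POS, (rec.REF, alts[0])))
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", skipped)
    if not loci:
        raise GenotypeError(f"{path}: no usable biallelic SNP records")
    return GenotypeMatrix(individuals, loci, np.column_stack(cols))


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write an uncompressed VCF v4.2 with GT-only genotypes."""
    with open(str(path), "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = {l.chrom: None for l in g.loci}
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.individuals) + "\n")
        code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, l in enumerate(g.loci):
            gts = "\t".join(code[int(d)] for d in g.calls[:, j])
            fh.write(f"{l.chrom}\t{l.position}\t{l.locus_id}\t{l.alleles[0]}\t{l.alleles[1]}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(genotype_counts) -> float:
    """Two-sided exact Hardy-Weinberg test for one biallelic locus.

    Enumerates every heterozygote count consistent with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one. A monomorphic locus returns 1.0.
    """
    n_aa, n_ab, n_bb = (int(x) for x in genotype_counts)
    if min(n_aa, n_ab, n_bb) < 0 or n_aa + n_ab + n_bb < 1:
        raise GenotypeError("genotype counts must be non-negative and sum to >= 1")
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    if na == 0 or nb == 0:
        return 1.0
    rare = min(na, nb)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(n_het = h | n, na) for the exact conditional distribution
    logp = (
        hets * math.log(2)
        + gammaln(n + 1)
        - gammaln((na - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((nb - hets) / 2 + 1)
        + gammaln(na + 1)
        + gammaln(nb + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hets == n_ab][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def ld_r2(g: GenotypeMatrix, locus_a, locus_b, within=None, pops: PopulationMap | None = None):
    """Squared Pearson correlation of dosages over pairwise-complete calls.

    Returns ``(r2, defined)``; ``defined`` is False (and r2 = 0.0) when either
    locus is monomorphic in the evaluated subset.
    """
    ids = g.locus_ids
    ja, jb = ids.index(locus_a), ids.index(locus_b)
    rows = np.arange(g.n_individuals)
    if within is not None and within != "all":
        if pops is None:
            raise GenotypeError("ld_r2 within a colony requires a PopulationMap")
        rows = pops.indices(g, "colony")[within]
    x = g.calls[rows, ja].astype(float)
    y = g.calls[rows, jb].astype(float)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        raise GenotypeError("ld_r2 needs >= 2 pairwise-complete individuals")
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        return 0.0, False
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r), True


def _window_r2(calls: np.ndarray, window: int) -> list:
    """All (j, k, r2) pairs with k - j <= window, pairwise-complete dosages."""
    X = calls.astype(float)
    M = calls != MISSING
    Xz = np.where(M, X, 0.0)
    n_loci = X.shape[1]
    out = []
    for off in range(1, window + 1):
        if off >= n_loci:
            break
        a, b = Xz[:, :-off], Xz[:, off:]
        ma, mb = M[:, :-off], M[:, off:]
        both = ma & mb
        n = both.sum(axis=0)
        sa = np.where(both, a, 0).sum(axis=0)
        sb = np.where(both, b, 0).sum(axis=0)
        saa = np.where(both, a * a, 0).sum(axis=0)
        sbb = np.where(both, b * b, 0).sum(axis=0)
        sab = np.where(both, a * b, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = sab - sa * sb / n
            va = saa - sa * sa / n
            vb = sbb - sb * sb / n
            r2 = np.where((va > 0) & (vb > 0) & (n >= 2), cov * cov / (va * vb), 0.0)
        for j in np.flatnonzero(r2 > 0):
            out.append((j, j + off, float(r2[j])))
    return out


# ---------------------------------------------------------------------------
# QC chain
# ---------------------------------------------------------------------------

def _alt_freq(calls: np.ndarray) -> np.ndarray:
    ok = calls != MISSING
    n = ok.sum(axis=0)
    s = np.where(ok, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, s / (2.0 * n), np.nan)


def apply_qc(g: GenotypeMatrix, pops: PopulationMap, cfg: QCConfig | None = None):
    """Run the five-step QC chain and return (filtered matrix, FilterReport).

    Order: (1) individual missingness, (2) locus missingness, (3) MAF on the
    post-(1,2) matrix, (4) per-population HWE exact test, (5) windowed LD
    pruning; HWE and LD removals require flagging in at least
    ``min_populations_flagged`` populations.
    """
    cfg = cfg or QCConfig()
    cfg.validate()
    pops.validate_against(g)
    report = FilterReport()
    cur = g

    # 1. individual missingness
    miss_ind = (cur.calls == MISSING).mean(axis=1)
    keep = miss_ind <= cfg.max_individual_missing_fraction
    if not keep.any():
        raise GenotypeError("individual-missingness filter removed every individual")
    removed = int((~keep).sum())
    if removed:
        cur = cur.subset(individuals=keep)
    report.add("individual_missingness", removed, 0, cur.n_individuals, cur.n_loci)

    # 2. locus missingness
    miss_loc = (cur.calls == MISSING).mean(axis=0)
    keep = miss_loc <= cfg.max_locus_missing_fraction
    removed = int((~keep).sum())
    if removed:
        cur = cur.subset(loci=keep)
    report.add("locus_missingness", 0, removed, cur.n_individuals, cur.n_loci)

    # 3. MAF (global, computed on the surviving matrix)
    p = _alt_freq(cur.calls)
    maf = np.minimum(p, 1.0 - p)
    keep = ~(maf < cfg.min_maf)  # NaN-frequency loci kept here (all-missing already filtered)
    removed = int((~keep).sum())
    if removed:
        cur = cur.subset(loci=keep)
    report.add("maf", 0, removed, cur.n_individuals, cur.n_loci)

    idx = pops.indices(cur, "colony")

    # 4. HWE exact test per population
    flags = np.zeros(cur.n_loci, dtype=int)
    for rows in idx.values():
        sub = cur.calls[rows]
        for j in range(cur.n_loci):
            col = sub[:, j]
            col = col[col != MISSING]
            if col.size == 0:
                continue
            counts = (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
            if hwe_exact_test(counts) < cfg.hwe_alpha:
                flags[j] += 1
        # early exit impossible: flags accumulated per population
    keep = flags < cfg.min_populations_flagged
    removed = int((~keep).sum())
    if removed:
        cur = cur.subset(loci=keep)
        idx = pops.indices(cur, "colony")
    report.add("hwe", 0, removed, cur.n_individuals, cur.n_loci)

    # 5. LD pruning: pair flagged per population; a pair flagged in enough
    # populations loses its lower-call-rate member (tie -> higher index).
    pair_flags: dict[tuple, int] = {}
    for rows in idx.values():
        for j, k, r2 in _window_r2(cur.calls[rows], cfg.ld_window_loci):
            if r2 > cfg.ld_r2_threshold:
                pair_flags[(j, k)] = pair_flags.get((j, k), 0) + 1
    call_rate = (cur.calls != MISSING).mean(axis=0)
    drop = np.zeros(cur.n_loci, dtype=bool)
    for (j, k), c in sorted(pair_flags.items()):
        if c < cfg.min_populations_flagged or drop[j] or drop[k]:
            continue
        if call_rate[j] > call_rate[k]:
            drop[k] = True
        elif call_rate[k] > call_rate[j]:
            drop[j] = True
        else:
            drop[k] = True  # tie: keep the lower locus index
    removed = int(drop.sum())
    if removed:
        cur = cur.subset(loci=~drop)
    report.add("ld", 0, removed, cur.n_individuals, cur.n_loci)

    return cur, report


def subset_loci(g: GenotypeMatrix, n: int, seed: int) -> GenotypeMatrix:
    """Uniform random locus subset without replacement, original order kept."""
    if not 1 <= n <= g.n_loci:
        raise GenotypeError(f"subset size {n} outside [1, {g.n_loci}]")
    rng = np.random.default_rng(seed)
    cols = np.sort(rng.choice(g.n_loci, size=n, replace=False))
    return g.subset(loci=cols)
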