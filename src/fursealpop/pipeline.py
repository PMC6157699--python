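"""End-to-end pipeline: QC -> structure stats -> ABC -> outliers -> assignment.

Configured by a single YAML document with one seed per stochastic stage, so
two runs with the same configuration produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .abc import DemographicABC, SimConfig, null_spec, summary_stats, two_decline_spec
from .assign import AssignConfig, assign_individuals
from .genotypes import GenotypeError, PopulationMap, QCConfig, apply_qc, read_genotypes, subset_loci
from .outliers import call_outliers, fdist_scan
from .popstats import amova, diversity_table, ibd_test, pairwise_fst_matrix

logger = logging.getLogger(__name__)

STAGES = ("qc", "stats", "ibd", "amova", "abc", "outliers", "assign")


@dataclass
class PipelineConfig:
    """Paths, per-stage toggles and seeds, and per-stage settings."""

    genotypes: str
    populations: str
    out_dir: str
    format: str = "ped_map"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    seeds: dict = field(default_factory=dict)
    qc: QCConfig = field(default_factory=QCConfig)
    n_perm: int = 999
    abc_samples: tuple = ("NZ-North-West", "NZ-South")  # cluster labels pooled N vs S
    abc_n_sims: int = 1000
    abc_n_loci: int = 1000
    abc_tolerance: float = 0.1
    outlier_sims: int = 50_000
    outlier_ci: float = 0.99
    outlier_fdr: float = 0.05
    assign_cfg: AssignConfig = field(default_factory=AssignConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        qc = QCConfig(**raw.pop("qc", {}))
        assign_cfg = AssignConfig(**raw.pop("assign", {}))
        stages = {s: True for s in STAGES}
        stages.update(raw.pop("stages", {}))
        cfg = cls(qc=qc, assign_cfg=assign_cfg, stages=stages, **raw)
        return cfg

    def seed_for(self, stage: str) -> int:
        return int(self.seeds.get(stage, 0))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in study order; returns the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "stages": [], "seeds": dict(cfg.seeds)}

    def stage(name):
        enabled = cfg.stages.get(name, True)
        if enabled:
            logger.info("stage %s: running", name)
        return enabled

    try:
        g = read_genotypes(cfg.genotypes, cfg.format)
        pops = PopulationMap.from_tsv(cfg.populations)

        if stage("qc"):
            g, report = apply_qc(g, pops, cfg.qc)
            report.to_tsv(out / "qc_report.tsv")
            report.to_json(out / "qc_report.json")
            for s in report.steps:
                logger.info("qc %-24s removed %d individuals, %d loci",
                            s.name, s.n_individuals_removed, s.n_loci_removed)
            manifest["stages"].append({"name": "qc", "n_individuals": g.n_individuals,
                                       "n_loci": g.n_loci})

        if stage("stats"):
            div = diversity_table(g, pops, n_perm=0)
            div.to_csv(out / "diversity.tsv", sep="\t", index=False)
            theta, lin, pmat = pairwise_fst_matrix(g, pops)
            theta.to_csv(out / "fst_theta.tsv", sep="\t")
            lin.to_csv(out / "fst_linearized.tsv", sep="\t")
            manifest["stages"].append({"name": "stats", "mean_He": float(div.He.mean())})

        if stage("ibd"):
            m = ibd_test(g, pops, n_perm=cfg.n_perm, seed=cfg.seed_for("ibd"))
            (out / "ibd.json").write_text(json.dumps(
                {"r": m.r, "p": m.p, "n_permutations": m.n_permutations}, indent=1))
            manifest["stages"].append({"name": "ibd", "r": m.r, "p": m.p})

        if stage("amova"):
            res = amova(g, pops, n_perm=cfg.n_perm, seed=cfg.seed_for("amova"))
            res.to_frame().to_csv(out / "amova.tsv", sep="\t", index=False)
            manifest["stages"].append({"name": "amova", "phi_st": res.phi_st})

        if stage("abc"):
            # pool colonies into the two clusters named in abc_samples
            north, south = cfg.abc_samples
            cl = pops.cluster_of
            lumped = PopulationMap(
                {i: ("NZ-N" if cl[c] != south else "NZ-S") for i, c in pops.colony_of.items()},
                {"NZ-N": "NZ-N", "NZ-S": "NZ-S"},
            )
            g_abc = subset_loci(g, min(cfg.abc_n_loci, g.n_loci), cfg.seed_for("abc"))
            model = DemographicABC.from_genotypes(
                g_abc, lumped, ("NZ-N", "NZ-S"),
                sim_config=SimConfig(n_loci=g_abc.n_loci))
            res = model.fit(n_sims_per_scenario=cfg.abc_n_sims,
                            tolerance=cfg.abc_tolerance, seed=cfg.seed_for("abc"))
            res.reference_table.to_tsv(out / "abc_reference_table.tsv")
            (out / "abc_model_choice.tsv").write_text(
                res.model_probabilities.to_frame().to_csv(sep="\t"))
            if res.posterior is not None:
                res.posterior.summary().to_csv(out / "abc_posterior.tsv", sep="\t")
            (out / "abc_summary.txt").write_text(res.summary() + "\n")
            manifest["stages"].append({"name": "abc", "best": res.best_scenario})

        outlier_panel = None
        if stage("outliers"):
            scan = fdist_scan(g, pops, n_sims=cfg.outlier_sims, ci=cfg.outlier_ci,
                              seed=cfg.seed_for("outliers"), fdr=cfg.outlier_fdr)
            scan.to_tsv(out / "outliers.tsv")
            scan.envelope.to_csv(out / "outlier_envelope.tsv", sep="\t", index=False)
            div_loci, bal_loci = call_outliers(scan, cfg.outlier_fdr)
            outlier_panel = div_loci
            manifest["stages"].append({"name": "outliers",
                                       "diversifying": len(div_loci),
                                       "balancing": len(bal_loci)})

        if stage("assign"):
            acfg = cfg.assign_cfg
            acfg.seed = cfg.seed_for("assign")
            res = assign_individuals(g, pops, level="colony", cfg=acfg)
            res.to_tsv(out / "assign_colony.tsv")
            res.accuracy_frame().to_csv(out / "assign_colony_accuracy.tsv",
                                        sep="\t", index=False)
            res_cl = assign_individuals(g, pops, level="cluster", cfg=acfg)
            res_cl.accuracy_frame().to_csv(out / "assign_cluster_accuracy.tsv",
                                           sep="\t", index=False)
            manifest["stages"].append({"name": "assign",
                                       "colony_accuracy": res.overall_accuracy,
                                       "cluster_accuracy": res_cl.overall_accuracy})
    except Exception as exc:  # annotate failures with the stage context
        done = [s["name"] for s in manifest["stages"]]
        raise RuntimeError(f"pipeline failed after stages {done}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
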