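"""End-to-end pipeline: simulate -> classify -> benchmark -> variability -> thresholds.

All randomness flows from explicit per-stage seeds derived deterministically
from the config's master seed, so re-running an identical config reproduces
identical outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mitovar import benchmark as bm
from mitovar import classify as cl
from mitovar import cohort as ch
from mitovar import io as mio
from mitovar import qpcr as qp
from mitovar import variability as vb

logger = logging.getLogger("mitovar")

OXPHOS_STRATEGIES = vb.STRATEGIES
DNA_STRATEGIES = ("intra_muscle", "intra_QD", "intra_TA", "inter_muscle")


@dataclass
class PipelineConfig:
    """Configuration of a full simulate-to-thresholds run.

    Iteration counts default to desk-scale values; the study-scale counts
    (10,000 classification models, 1,000,000 OXPHOS pairing iterations,
    100,000 mtDNA iterations) are reachable through the same fields.
    """

    seed: int = 0
    fibres_per_section: int = 200
    design_overrides: dict = field(default_factory=dict)
    methods: tuple[str, ...] = ("frequentist", "mitoplot")
    n_investigators: int = 3
    annotation_jitter_sd: float = 15.0
    n_classifier_models: int = 1000
    n_consensus_resamples: int = 10_000
    certainty_threshold: float = 0.95
    n_benchmark_bootstrap: int = 10_000
    n_section_draws: int = 2000
    n_oxphos_iterations: int = 100_000
    n_dna_iterations: int = 100_000
    n_curve_models: int = 10_000
    mtdnacn_mean: float = 1476.0
    mtdnacn_sd: float = 517.0
    cq_noise_sd: float = 0.2
    het_between_biopsy_sd: float = 2.9
    het_replicate_sd: float = 1.0

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2**31 derived from the master seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2 ** 31)

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if "methods" in data:
            data["methods"] = tuple(data["methods"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


#: Table 1-style per-patient/muscle homogenate heteroplasmy means (percent)
STUDY_HETEROPLASMY = {
    ("P1", "QD"): 52.0, ("P1", "TA"): 52.0,
    ("P2", "QD"): 83.0, ("P2", "TA"): 85.0,
    ("P3", "QD"): 72.0, ("P3", "TA"): 64.0,
    ("P4", "QD"): 77.0, ("P4", "TA"): 86.0,
}


def simulate(config: PipelineConfig):
    """Generate the cohort, annotations, qPCR plate and pyrosequencing records."""
    design = ch.study_design(
        fibres_per_section=config.fibres_per_section,
        seed=config.stage_seed("cohort"),
        **config.design_overrides,
    )
    cohort = ch.generate_cohort(design)
    annotations = ch.generate_annotations(
        cohort, n_investigators=config.n_investigators,
        boundary_jitter_sd=config.annotation_jitter_sd,
        seed=config.stage_seed("annotations"),
    )
    rng = np.random.default_rng(config.stage_seed("mtdnacn_truth"))
    biopsy_ids = list(cohort.biopsies["biopsy"])
    true_mcn = {
        b: float(np.clip(rng.normal(config.mtdnacn_mean, config.mtdnacn_sd), 300.0, 3500.0))
        for b in biopsy_ids
    }
    plate = ch.generate_qpcr(
        biopsy_ids, true_mcn, cq_noise_sd=config.cq_noise_sd,
        seed=config.stage_seed("qpcr"),
    )
    pyroseq = ch.generate_pyroseq(
        cohort.biopsies, STUDY_HETEROPLASMY,
        between_biopsy_sd=config.het_between_biopsy_sd,
        replicate_sd=config.het_replicate_sd,
        seed=config.stage_seed("pyroseq"),
    )
    return cohort, annotations, plate, pyroseq


def classify_cohort(config: PipelineConfig, cohort, annotations) -> dict[str, dict[str, pd.DataFrame]]:
    """Run the selected classifiers; returns calls[method][protein]."""
    calls: dict[str, dict[str, pd.DataFrame]] = {}
    if "frequentist" in config.methods:
        calls["frequentist"] = {
            protein: cl.classify_frequentist(
                cohort.fibres, cohort.controls, protein,
                n_models=config.n_classifier_models,
                certainty_threshold=config.certainty_threshold,
                seed=config.stage_seed(f"frequentist:{protein}"),
            )
            for protein in cohort.design.proteins
        }
    if "mitoplot" in config.methods:
        investigators = sorted({a.investigator for a in annotations})
        calls["mitoplot"] = {}
        for protein in cohort.design.proteins:
            tables = [
                cl.classify_by_polygons(
                    cohort.fibres, [a for a in annotations if a.investigator == inv], protein,
                )
                for inv in investigators
            ]
            calls["mitoplot"][protein] = cl.consensus_certainty(
                tables, n_resamples=config.n_consensus_resamples,
                certainty_threshold=config.certainty_threshold,
                seed=config.stage_seed(f"consensus:{protein}"),
            )
    return calls


def benchmark_calls(config: PipelineConfig, cohort, calls) -> dict:
    """Per-section benchmark tables plus weighted bootstrap summaries.

    Sections whose kappa is degenerate (a single category, perfect
    agreement) are excluded from the weighted averages.
    """
    out = {"per_section": {}, "summaries": {}}
    for method, per_protein in calls.items():
        for protein, table in per_protein.items():
            sect = bm.benchmark_sections(table, cohort.fibres, protein)
            out["per_section"][(method, protein)] = sect
            usable = sect.copy()
            usable.loc[usable["kappa_degenerate"], "kappa"] = np.nan
            weights = dict(zip(sect["section"], sect["n_fibres"].astype(float)))
            summaries = {}
            for stat in ("kappa", "fpr", "fnr", "ppv", "sensitivity", "f1"):
                stats_map = dict(zip(usable["section"], usable[stat]))
                try:
                    agg = bm.weighted_bootstrap_summary(
                        stats_map, weights, n_bootstrap=config.n_benchmark_bootstrap,
                        seed=config.stage_seed(f"benchmark:{method}:{protein}:{stat}"),
                    )
                except ValueError:
                    continue
                summaries[stat] = {
                    "weighted_mean": agg.weighted_mean,
                    "ci_low": agg.ci_low, "ci_high": agg.ci_high,
                    "n_excluded": agg.n_excluded,
                }
            out["summaries"][(method, protein)] = summaries
    return out


def oxphos_variability(config: PipelineConfig, cohort, calls) -> dict:
    """Difference distributions and summaries per method/protein/strategy."""
    meta = cohort.sections
    summaries: dict[tuple[str, str], vb.VariabilitySummary] = {}
    for method, per_protein in calls.items():
        for protein, table in per_protein.items():
            deficient = (table["final_call"] == "deficient").to_numpy()
            sections = cohort.fibres["section"].to_numpy()
            dists = {}
            for section in meta["section"]:
                flags = deficient[sections == section]
                spd = vb.bootstrap_section_proportions(
                    flags, section=section, protein=protein,
                    n_draws=config.n_section_draws,
                    seed=config.stage_seed(f"propboot:{method}:{protein}:{section}"),
                )
                dists[section] = spd.draws
            for strategy in OXPHOS_STRATEGIES:
                pairs = vb.enumerate_pairs(
                    meta, strategy, unit="section",
                    l_split_pairs=cohort.design.l_split_pairs,
                )
                diff = vb.sample_abs_differences(
                    dists, pairs, n_iterations=config.n_oxphos_iterations,
                    seed=config.stage_seed(f"diffs:{method}:{protein}:{strategy}"),
                    strategy=strategy, metric=f"oxphos_prop:{method}:{protein}",
                )
                summaries[(f"oxphos_prop:{method}:{protein}", strategy)] = vb.summarize_distribution(diff)
    return summaries


def dna_variability(config: PipelineConfig, cohort, plate, pyroseq) -> tuple[dict, dict]:
    """mtDNAcn and heteroplasmy difference summaries plus per-assay extras."""
    curves = {
        target: qp.bootstrap_standard_curves(
            series, target=target, n_models=config.n_curve_models,
            seed=config.stage_seed(f"curves:{target}"),
        )
        for target, series in plate.dilution_series.items()
    }
    mcn = {
        biopsy: qp.estimate_mtdnacn(
            cqs, curves, biopsy=biopsy, n_iterations=config.n_dna_iterations,
            seed=config.stage_seed(f"mcn:{biopsy}"),
        )
        for biopsy, cqs in plate.biopsy_cq.items()
    }
    het = {
        r.biopsy: qp.heteroplasmy_mean(r)
        for r in pyroseq if not r.is_standard
    }

    meta = cohort.biopsies[["patient", "muscle", "biopsy"]]
    summaries: dict[tuple[str, str], vb.VariabilitySummary] = {}
    mcn_dists = {b: d.values for b, d in mcn.items()}
    # heteroplasmy pairs replicate triplets directly between biopsies
    het_dists = {
        r.biopsy: np.asarray(r.replicates, dtype=float)
        for r in pyroseq if not r.is_standard
    }
    for metric, dists in (("mtdnacn", mcn_dists), ("heteroplasmy", het_dists)):
        for strategy in DNA_STRATEGIES:
            pairs = vb.enumerate_pairs(meta, strategy, unit="biopsy",
                                       l_split_pairs=cohort.design.l_split_pairs)
            diff = vb.sample_abs_differences(
                dists, pairs, n_iterations=config.n_dna_iterations,
                seed=config.stage_seed(f"diffs:{metric}:{strategy}"),
                strategy=strategy, metric=metric,
            )
            summaries[(metric, strategy)] = vb.summarize_distribution(diff)

    per_patient_means = {}
    for r in pyroseq:
        if r.is_standard:
            continue
        patient = r.biopsy.split("_")[0]
        per_patient_means.setdefault(patient, []).append(het[r.biopsy].mean)
    extras = {
        "mtdnacn_medians": {b: d.median for b, d in mcn.items()},
        "mtdnacn_mean_of_medians": float(np.mean([d.median for d in mcn.values()])),
        "mtdnacn_sd_of_medians": float(np.std([d.median for d in mcn.values()], ddof=1)),
        "heteroplasmy_means": {b: e.mean for b, e in het.items()},
        "heteroplasmy_pooled_sd": qp.pooled_sd(list(per_patient_means.values())),
        "amplification_efficiency": {
            t: float(np.median(10.0 ** (-1.0 / c.slopes) - 1.0)) for t, c in curves.items()
        },
    }
    return summaries, extras


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Execute every stage in order; optionally write tables/JSON to ``outdir``.

    Returns a result bundle with the cohort, per-method calls, benchmark
    stats, variability summaries and the threshold table.  Stage failures
    propagate with the failing stage named.
    """
    t0 = time.time()
    results: dict = {"config": dataclasses.asdict(config)}
    stage = "simulate"
    try:
        cohort, annotations, plate, pyroseq = simulate(config)
        results["cohort"] = cohort
        logger.info("simulate: %d fibres, %d sections", len(cohort.fibres), len(cohort.sections))
        stage = "classify"
        calls = classify_cohort(config, cohort, annotations)
        results["calls"] = calls
        stage = "benchmark"
        results["benchmark"] = benchmark_calls(config, cohort, calls)
        stage = "variability"
        ox = oxphos_variability(config, cohort, calls)
        stage = "mtdna"
        dna, extras = dna_variability(config, cohort, plate, pyroseq)
        results["dna_extras"] = extras
        summaries = {**ox, **dna}
        results["summaries"] = summaries
        stage = "thresholds"
        results["thresholds"] = vb.threshold_report(summaries)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    results["runtime_s"] = time.time() - t0
    if outdir is not None:
        _write_bundle(results, cohort, annotations, plate, pyroseq, Path(outdir))
    return results


def _write_bundle(results, cohort, annotations, plate, pyroseq, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_table(cohort.fibres, outdir / "fibres.csv", "fibre_table")
    mio.write_table(cohort.controls, outdir / "controls.csv", "control_table")
    mio.write_annotations(annotations, outdir / "annotations.json")
    mio.write_qpcr_plate(plate, outdir / "qpcr_plate.csv")
    mio.write_pyroseq(pyroseq, outdir / "pyroseq.csv")
    for method, per_protein in results["calls"].items():
        for protein, table in per_protein.items():
            safe = protein.replace("/", "_")
            mio.write_table(table, outdir / f"calls_{method}_{safe}.csv", "certainty_table")
    mio.write_table(results["thresholds"], outdir / "thresholds.csv", "summary_table")
    report = {
        "config": results["config"],
        "benchmark": {
            f"{m}:{p}": s for (m, p), s in results["benchmark"]["summaries"].items()
        },
        "variability": {
            f"{metric}|{strategy}": summary.as_dict()
            for (metric, strategy), summary in results["summaries"].items()
        },
        "dna_extras": results["dna_extras"],
        "runtime_s": results["runtime_s"],
    }
    mio.write_json(report, outdir / "report.json")
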