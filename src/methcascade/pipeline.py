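"""End-to-end study driver: simulate -> quantify -> select markers ->
train the screening (S) and diagnostic (D) classifiers -> evaluate on a
held-out validation split, including the sequential S->D cascade,
prevalence-adjusted predictive values, covariate association, and the
CEA combination.

One global seed drives every stochastic stage (simulation, CV fold
assignment, bootstrap); rerunning with the same configuration yields a
byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .evaluate import (
    cascade_classify,
    cascade_stage_counts,
    combine_with_cea,
    covariate_association,
    pct,
    performance_report,
    prevalence_adjust,
)
from .markers import compute_marker_stats, select_discovery_markers, verify_markers
from .quantify import coverage_filter
from .synthetic import PLASMA_GROUPS, SimulationConfig, simulate_cohort
from .training import CVConfig, score_samples, train_classifier

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "demo_config"]

REPORT_VERSION = 1


@dataclass
class PipelineConfig:
    """Configuration for one full synthetic study.

    Cohort sizes in ``simulation`` are study totals; ``n_validation_*``
    samples per plasma group are held out from every training stage
    (marker selection, model fitting, cutoff calibration).  Defaults
    mirror a development study of 254/180/251 cancer/benign/healthy
    plasma samples with a 64/45/63 validation split and 20+20
    tumor/WBC tissue references.
    """

    simulation: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(
            n_cancer=254, n_benign=180, n_healthy=251
        )
    )
    n_validation_cancer: int = 64
    n_validation_benign: int = 45
    n_validation_healthy: int = 63
    min_coverage: int = 100
    top_k: int = 50
    p_max: float = 0.05
    max_healthy_background: float = 0.05
    allowlist: list | None = None
    cv: CVConfig = field(default_factory=CVConfig)
    target_sens: float = 0.90
    target_spec: float = 0.95
    prevalences: tuple = (0.10,)
    n_bootstrap: int = 1000
    seed: int = 0

    def __post_init__(self):
        sim = self.simulation
        for grp, n_val, n_tot in (
            ("cancer", self.n_validation_cancer, sim.n_cancer),
            ("benign", self.n_validation_benign, sim.n_benign),
            ("healthy", self.n_validation_healthy, sim.n_healthy),
        ):
            if not 0 <= n_val < n_tot:
                raise ValueError(
                    f"n_validation_{grp} ({n_val}) must be in [0, {grp} total {n_tot})"
                )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = mio.load_yaml(path)
        sim = SimulationConfig(**raw.pop("simulation", {}))
        cv = CVConfig(**raw.pop("cv", {}))
        if "prevalences" in raw:
            raw["prevalences"] = tuple(raw["prevalences"])
        return cls(simulation=sim, cv=cv, **raw)


def demo_config(seed: int = 0) -> PipelineConfig:
    """Small, fast study for demos and smoke tests (~2 s end to end)."""
    sim = SimulationConfig(
        n_cancer=60, n_benign=40, n_healthy=60,
        n_tumor_tissue=10, n_wbc=10,
        n_regions=40, n_true_dmr=6,
        tumor_fraction_range=(0.05, 0.25),
        seed=seed,
    )
    return PipelineConfig(
        simulation=sim,
        n_validation_cancer=20, n_validation_benign=14, n_validation_healthy=20,
        cv=CVConfig(n_repeats=3, n_folds=4, seed=seed),
        n_bootstrap=200,
        seed=seed,
    )


def _split_cohort(cohort, config):
    """Per plasma group, hold out the last n_validation samples."""
    train_ids, val_ids = [], []
    n_val = {
        "cancer": config.n_validation_cancer,
        "benign": config.n_validation_benign,
        "healthy": config.n_validation_healthy,
    }
    for grp in PLASMA_GROUPS:
        ids = list(cohort.samples.index[cohort.samples["group"] == grp])
        k = n_val[grp]
        train_ids += ids[: len(ids) - k]
        val_ids += ids[len(ids) - k:]
    tissue_ids = list(cohort.tissue_samples)
    return train_ids, val_ids, tissue_ids


def _subgroup_frame(samples: pd.DataFrame) -> pd.DataFrame:
    sub = pd.DataFrame(index=samples.index)
    sub["stage"] = samples["stage"].fillna("")
    size = samples["tumor_size_cm"]
    sub["size_bin"] = np.where(
        size.isna(), "", np.where(size < 1.2, "<1.2cm", ">=1.2cm")
    )
    sub["histology"] = samples["histology"].fillna("")
    return sub


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Run the whole study; returns (and optionally writes) the report."""
    sim = replace(config.simulation, seed=config.seed)
    logger.info("pipeline: simulating cohort (seed=%d)", config.seed)
    cohort = simulate_cohort(sim)

    train_ids, val_ids, tissue_ids = _split_cohort(cohort, config)
    logger.info(
        "pipeline: %d training / %d validation plasma samples, %d tissue",
        len(train_ids), len(val_ids), len(tissue_ids),
    )

    counts = coverage_filter(cohort.counts, config.min_coverage)
    samples = cohort.samples

    # Marker funnel uses training plasma plus tissue references only.
    stats = compute_marker_stats(
        counts.subset_samples(train_ids + tissue_ids), samples
    )
    discovery = select_discovery_markers(
        stats,
        top_k=config.top_k,
        p_max=config.p_max,
        max_healthy_background=config.max_healthy_background,
    )
    verified = verify_markers(discovery, stats, allowlist=config.allowlist)
    logger.info(
        "pipeline: %d discovery -> %d verified markers", len(discovery), len(verified)
    )

    amf = counts.amf
    train_samples = samples.loc[train_ids]
    val_samples = samples.loc[val_ids]

    def contrast(ids, meta, pos, neg):
        mask = meta["group"].isin([pos, neg])
        sel = [i for i, m in zip(ids, mask.loc[ids]) if m]
        labels = (samples.loc[sel, "group"] == pos).to_numpy()
        return sel, labels

    s_ids, s_labels = contrast(train_ids, train_samples, "cancer", "healthy")
    d_ids, d_labels = contrast(train_ids, train_samples, "cancer", "benign")

    logger.info("pipeline: training screening (S) model, cancer vs healthy")
    s_model = train_classifier(
        verified, amf.loc[s_ids], s_labels,
        replace(config.cv, seed=config.seed + 100),
        mode="S", target_sens=config.target_sens,
    )
    logger.info("pipeline: training diagnostic (D) model, cancer vs benign")
    d_model = train_classifier(
        verified, amf.loc[d_ids], d_labels,
        replace(config.cv, seed=config.seed + 200),
        mode="D", target_spec=config.target_spec,
    )

    # ------------------------------------------------------- validation
    val_amf = amf.loc[val_ids]
    val_groups = val_samples["group"]
    s_val_ids = [i for i in val_ids if val_groups[i] in ("cancer", "healthy")]
    d_val_ids = [i for i in val_ids if val_groups[i] in ("cancer", "benign")]

    s_scores_val = score_samples(s_model, val_amf)
    d_scores_val = score_samples(d_model, val_amf)

    s_report = performance_report(
        s_scores_val.loc[s_val_ids],
        (val_groups.loc[s_val_ids] == "cancer").to_numpy(),
        s_model.cutoff,
        n_bootstrap=config.n_bootstrap,
        seed=config.seed + 300,
        subgroups=_subgroup_frame(val_samples.loc[s_val_ids]),
    )
    d_report = performance_report(
        d_scores_val.loc[d_val_ids],
        (val_groups.loc[d_val_ids] == "cancer").to_numpy(),
        d_model.cutoff,
        n_bootstrap=config.n_bootstrap,
        seed=config.seed + 400,
        subgroups=_subgroup_frame(val_samples.loc[d_val_ids]),
    )
    # Off-contrast specificities: the group each model never trained on.
    benign_val = val_groups.index[val_groups == "benign"]
    healthy_val = val_groups.index[val_groups == "healthy"]
    s_benign_spec = float((s_scores_val.loc[benign_val] < s_model.cutoff).mean()) \
        if len(benign_val) else None
    d_healthy_spec = float((d_scores_val.loc[healthy_val] < d_model.cutoff).mean()) \
        if len(healthy_val) else None

    cascade = cascade_classify(s_model, d_model, val_amf)
    cascade_counts = cascade.confusion((val_groups == "cancer").to_numpy())
    from .evaluate import confusion_metrics
    cascade_metrics = confusion_metrics(cascade_counts)
    cascade.stage_counts = cascade_stage_counts(cascade, val_groups)

    prevalence_block = {}
    for prev in config.prevalences:
        entries = {}
        if cascade_metrics["sensitivity"] is not None and cascade_metrics["specificity"] is not None:
            ppv, npv = prevalence_adjust(
                cascade_metrics["sensitivity"], cascade_metrics["specificity"], prev
            )
            entries["cascade"] = {"ppv": ppv, "npv": npv}
        if d_report.metrics["sensitivity"] is not None and d_report.metrics["specificity"] is not None:
            ppv, npv = prevalence_adjust(
                d_report.metrics["sensitivity"], d_report.metrics["specificity"], prev
            )
            entries["d_model"] = {"ppv": ppv, "npv": npv}
        prevalence_block[str(prev)] = entries

    covariates = {}
    cancer_val = val_groups.index[val_groups == "cancer"]
    stage_groups = val_samples.loc[cancer_val, "stage"]
    if stage_groups.nunique() >= 2:
        covariates["stage_s_scores"] = covariate_association(
            s_scores_val.loc[cancer_val].to_numpy(), stage_groups.to_numpy()
        ).to_dict(orient="records")
    for col in ("sex", "smoking"):
        covariates[f"{col}_s_scores"] = covariate_association(
            s_scores_val.to_numpy(), val_samples[col].to_numpy()
        ).to_dict(orient="records")

    cea_ids = list(d_val_ids)
    cea_res = combine_with_cea(
        d_scores_val.loc[cea_ids].to_numpy(),
        val_samples.loc[cea_ids, "cea"].to_numpy(),
        (val_groups.loc[cea_ids] == "cancer").to_numpy(),
        seed=config.seed + 500,
    )

    report = {
        "version": REPORT_VERSION,
        "seed": config.seed,
        "cohort": {
            "n_train": len(train_ids),
            "n_validation": len(val_ids),
            "n_tissue": len(tissue_ids),
            "n_regions": int(len(counts.regions)),
            "n_true_dmr": int(cohort.truth.sum()),
        },
        "markers": {
            "n_discovery": len(discovery),
            "n_verified": len(verified),
            "verified": list(verified.regions),
            "true_positives_in_verified": int(
                cohort.truth.reindex(verified.regions).fillna(False).sum()
            ),
        },
        "s_model": {
            "markers": s_model.markers,
            "cutoff": s_model.cutoff,
            "cv_auc": s_model.cv_auc_mean,
            "validation": s_report.as_dict(),
            "validation_benign_specificity": s_benign_spec,
        },
        "d_model": {
            "markers": d_model.markers,
            "cutoff": d_model.cutoff,
            "cv_auc": d_model.cv_auc_mean,
            "validation": d_report.as_dict(),
            "validation_healthy_specificity": d_healthy_spec,
        },
        "cascade": {
            "counts": dataclasses.asdict(cascade_counts),
            "sensitivity": cascade_metrics["sensitivity"],
            "specificity": cascade_metrics["specificity"],
            "ppv": cascade_metrics["ppv"],
            "npv": cascade_metrics["npv"],
            "stage_counts": cascade.stage_counts.reset_index().to_dict(orient="records"),
        },
        "prevalence_adjusted": prevalence_block,
        "covariates": covariates,
        "cea_combination": dataclasses.asdict(cea_res),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_count_matrix(cohort.counts, outdir / "counts.tsv")
        mio.write_sample_sheet(cohort.samples, outdir / "samples.csv")
        mio.write_bed(cohort.regions_bed, outdir / "regions.bed")
        mio.write_truth(cohort.truth, outdir / "truth.tsv")
        verified.stats.to_csv(outdir / "panel.tsv", sep="\t")
        s_model.to_json(outdir / "model_S.json")
        d_model.to_json(outdir / "model_D.json")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        _write_summary_table(report, outdir / "summary.tsv")
        logger.info("pipeline: report written to %s", outdir / "report.json")
    return report


def _write_summary_table(report: dict, path) -> None:
    """Human-readable table: one row per model/cohort block, percentages
    with bootstrap CIs."""
    rows = []

    def fmt_ci(block, metric):
        lo_hi = block.get(f"{metric}_ci")
        if block.get(metric) is None:
            return ""
        base = f"{pct(block[metric])}%"
        if lo_hi:
            base += f" ({pct(lo_hi[0])}-{pct(lo_hi[1])}%)"
        return base

    for model in ("s_model", "d_model"):
        block = report[model]["validation"]
        rows.append(
            {
                "block": f"{model}_validation",
                "n": block["counts"]["tp"] + block["counts"]["fp"]
                + block["counts"]["tn"] + block["counts"]["fn"],
                "positive": block["counts"]["tp"] + block["counts"]["fp"],
                "negative": block["counts"]["tn"] + block["counts"]["fn"],
                "sensitivity": fmt_ci(block, "sensitivity"),
                "specificity": fmt_ci(block, "specificity"),
                "auc": f"{block['auc']:.3f} ({block['auc_ci'][0]:.3f}-{block['auc_ci'][1]:.3f})",
            }
        )
    casc = report["cascade"]
    rows.append(
        {
            "block": "cascade_validation",
            "n": sum(casc["counts"].values()),
            "positive": casc["counts"]["tp"] + casc["counts"]["fp"],
            "negative": casc["counts"]["tn"] + casc["counts"]["fn"],
            "sensitivity": f"{pct(casc['sensitivity'])}%" if casc["sensitivity"] is not None else "",
            "specificity": f"{pct(casc['specificity'])}%" if casc["specificity"] is not None else "",
            "auc": "",
        }
    )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
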