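"""Two-stage differentially-methylated-region (DMR) marker funnel.

Stage 1 (plasma discovery): per-region statistics contrasting cancer and
healthy plasma AMF — group means, fold change, two-sided Mann-Whitney p
with Benjamini-Hochberg adjustment across regions, single-marker AUC —
then a filter (q <= 0.05, fold change > 1, low healthy background) and a
ranking by (AUC desc, fold change desc) keeps the top K regions.

Stage 2 (verification): candidates, optionally intersected with a
user-supplied allowlist standing in for manual gene-function curation, must
show log2 plasma fold change > 1 with p < 0.05 and a tumor-vs-WBC tissue
signal ratio above 10x (log10 > 1) to enter the final panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .quantify import MethylationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerSelectionError",
    "MarkerPanel",
    "compute_marker_stats",
    "select_discovery_markers",
    "verify_markers",
    "PSEUDOCOUNT",
]

# Added to AMF group means before ratios to keep fold changes finite.
PSEUDOCOUNT = 1e-4


class MarkerSelectionError(ValueError):
    pass


@dataclass
class MarkerPanel:
    """An ordered marker panel with its selection statistics."""

    regions: list
    stats: pd.DataFrame
    stage: str  # discovery | curated | verified
    allowlist_applied: bool = False

    def __len__(self) -> int:
        return len(self.regions)


def _group_values(amf: pd.DataFrame, groups: pd.Series, name: str) -> pd.DataFrame:
    ids = groups.index[groups == name]
    return amf.loc[amf.index.intersection(ids)]


def compute_marker_stats(
    matrix: MethylationMatrix,
    samples: pd.DataFrame,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-region discrimination statistics from AMF values.

    ``samples`` must carry a ``group`` column over at least the matrix's
    samples; recognised groups are cancer/benign/healthy (plasma) and
    tumor/wbc (tissue).  Requires >= 2 cancer and >= 2 healthy samples.

    Returns a DataFrame indexed by region with columns: per-group mean AMF,
    ``fold_change`` (cancer/healthy means with pseudocount), its log2,
    ``log10_fc_tissue`` (tumor/WBC means, NaN when tissue absent),
    ``p_value`` (two-sided Mann-Whitney, tie-corrected), ``q_value``
    (Benjamini-Hochberg across regions), ``auc_single`` (cancer-vs-healthy
    rank AUC, ties counting half), ``healthy_background`` and a
    ``degenerate`` flag for all-identical regions (AUC 0.5, p 1).
    """
    if "group" not in samples.columns:
        raise MarkerSelectionError("sample sheet lacks required 'group' column")
    groups = samples["group"].reindex(matrix.samples)
    amf = matrix.amf

    by_group = {g: _group_values(amf, groups, g) for g in
                ("cancer", "benign", "healthy", "tumor", "wbc")}
    for g in ("cancer", "healthy"):
        if len(by_group[g]) < 2:
            raise MarkerSelectionError(
                f"need >= 2 '{g}' samples to compute marker statistics, got {len(by_group[g])}"
            )

    means = {f"mean_{g}": v.mean(axis=0, skipna=True) for g, v in by_group.items()}
    out = pd.DataFrame(means, index=matrix.regions)

    fc = (out["mean_cancer"] + pseudocount) / (out["mean_healthy"] + pseudocount)
    out["fold_change"] = fc
    out["log2_fc_plasma"] = np.log2(fc)
    out["log10_fc_tissue"] = np.log10(
        (out["mean_tumor"] + pseudocount) / (out["mean_wbc"] + pseudocount)
    )
    out["healthy_background"] = out["mean_healthy"]

    pvals = np.ones(len(matrix.regions))
    aucs = np.full(len(matrix.regions), 0.5)
    degenerate = np.zeros(len(matrix.regions), dtype=bool)
    cancer_amf = by_group["cancer"]
    healthy_amf = by_group["healthy"]
    for j, region in enumerate(matrix.regions):
        x = cancer_amf[region].dropna().to_numpy()
        y = healthy_amf[region].dropna().to_numpy()
        if len(x) < 1 or len(y) < 1 or len(np.unique(np.concatenate([x, y]))) == 1:
            degenerate[j] = True
            continue
        res = mannwhitneyu(x, y, alternative="two-sided")
        pvals[j] = res.pvalue
        aucs[j] = res.statistic / (len(x) * len(y))
    out["p_value"] = pvals
    out["auc_single"] = aucs
    out["degenerate"] = degenerate
    out["q_value"] = multipletests(pvals, method="fdr_bh")[1]
    out.index.name = "region"
    return out


def select_discovery_markers(
    stats: pd.DataFrame,
    top_k: int = 50,
    p_max: float = 0.05,
    max_healthy_background: float = 0.05,
) -> MarkerPanel:
    """Stage-1 filter and ranking of hypermethylated plasma markers.

    Keeps regions with BH-adjusted q <= ``p_max``, cancer/healthy fold
    change > 1, and mean healthy AMF <= ``max_healthy_background``; ranks
    survivors by (single-marker AUC desc, fold change desc, region id) and
    returns the first ``top_k``.  Fewer than ``top_k`` survivors is a
    warning, not an error.
    """
    if top_k < 1:
        raise MarkerSelectionError("top_k must be >= 1")
    keep = stats[
        (stats["q_value"] <= p_max)
        & (stats["fold_change"] > 1.0)
        & (stats["healthy_background"] <= max_healthy_background)
    ]
    # Rank by AUC, then fold change; region id as deterministic tie-break.
    ranked = keep.iloc[
        np.lexsort(
            (keep.index.to_numpy(), -keep["fold_change"].to_numpy(),
             -keep["auc_single"].to_numpy())
        )
    ]
    if len(ranked) < top_k:
        logger.warning(
            "select_discovery_markers: only %d regions pass the filters (top_k=%d)",
            len(ranked), top_k,
        )
    chosen = ranked.iloc[:top_k]
    return MarkerPanel(list(chosen.index), chosen.copy(), stage="discovery")


def verify_markers(
    panel: MarkerPanel,
    plasma_stats: pd.DataFrame,
    tissue_stats: pd.DataFrame | None = None,
    allowlist=None,
    log2_fc_min: float = 1.0,
    p_max: float = 0.05,
    log10_fc_tissue_min: float = 1.0,
) -> MarkerPanel:
    """Stage-2 verification against independent plasma and tissue evidence.

    An optional ``allowlist`` (iterable of region ids, standing in for
    manual curation of the discovery panel) is intersected first.  A marker
    survives when its verification-plasma log2 fold change exceeds
    ``log2_fc_min`` with unadjusted p < ``p_max`` and its tumor-vs-WBC
    log10 signal ratio exceeds ``log10_fc_tissue_min``.  The three filters
    are a conjunction: order-independent and idempotent.
    """
    if len(panel) == 0:
        raise MarkerSelectionError("cannot verify an empty panel")
    candidates = list(panel.regions)
    applied = False
    if allowlist is not None:
        allow = set(allowlist)
        candidates = [r for r in candidates if r in allow]
        applied = True
    if tissue_stats is None:
        tissue_stats = plasma_stats
    if "log10_fc_tissue" not in tissue_stats.columns:
        raise MarkerSelectionError("tissue statistics lack 'log10_fc_tissue'")

    survivors = []
    for r in candidates:
        if r not in plasma_stats.index or r not in tissue_stats.index:
            continue
        row_p = plasma_stats.loc[r]
        if (
            row_p["log2_fc_plasma"] > log2_fc_min
            and row_p["p_value"] < p_max
            and tissue_stats.loc[r, "log10_fc_tissue"] > log10_fc_tissue_min
        ):
            survivors.append(r)
    if not survivors:
        raise MarkerSelectionError(
            "no markers pass verification; consider relaxing log2_fc_min, "
            "p_max or log10_fc_tissue_min"
        )
    stats = plasma_stats.loc[survivors].copy()
    stats["log10_fc_tissue"] = tissue_stats.loc[survivors, "log10_fc_tissue"]
    logger.info("verify_markers: %d/%d candidates verified", len(survivors), len(candidates))
    return MarkerPanel(survivors, stats, stage="verified", allowlist_applied=applied)
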