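"""Diagnostic-accuracy engine.

Confusion-matrix metrics (sensitivity, specificity, PPV, NPV) in exact
rational arithmetic; tie-corrected rank AUC with stratified-bootstrap
percentile confidence intervals (1000 resamples); the sequential
screening-then-triage cascade (final positive requires both models);
prevalence-adjusted predictive values via Bayes' rule; Mann-Whitney
covariate association; and combination of the diagnostic model score with
serum CEA in a bivariate logistic model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "confusion_metrics",
    "pct",
    "rank_auc",
    "auc",
    "AucResult",
    "cascade_classify",
    "CascadeResult",
    "prevalence_adjust",
    "covariate_association",
    "combine_with_cea",
    "performance_report",
    "PerformanceReport",
    "N_BOOTSTRAP",
]

N_BOOTSTRAP = 1000


# ---------------------------------------------------------------- confusion

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_calls(cls, calls, labels) -> "ConfusionCounts":
        calls = np.asarray(calls, dtype=bool)
        labels = np.asarray(labels, dtype=bool)
        return cls(
            tp=int((calls & labels).sum()),
            fp=int((calls & ~labels).sum()),
            tn=int((~calls & ~labels).sum()),
            fn=int((~calls & labels).sum()),
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_metrics(counts: ConfusionCounts) -> dict:
    """Sensitivity, specificity, PPV and NPV as exact ratios.

    A metric whose denominator is zero is reported as None, with the
    reason under ``reasons``; no exception is raised.
    """
    out: dict = {"reasons": {}}

    def ratio(num, den, name, what):
        if den == 0:
            out[name] = None
            out["reasons"][name] = f"undefined: no {what}"
        else:
            out[name] = float(Fraction(num, den))

    ratio(counts.tp, counts.tp + counts.fn, "sensitivity", "diseased subjects")
    ratio(counts.tn, counts.tn + counts.fp, "specificity", "non-diseased subjects")
    ratio(counts.tp, counts.tp + counts.fp, "ppv", "positive test results")
    ratio(counts.tn, counts.tn + counts.fn, "npv", "negative test results")
    return out


def pct(x: float | None, decimals: int = 1) -> float | None:
    """Fraction -> percentage, rounded half-up to ``decimals`` places."""
    if x is None:
        return None
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x) * 100)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------- AUC

def rank_auc(scores, labels) -> float:
    """Tie-corrected rank AUC: P(random positive outscores a random
    negative), ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass(frozen=True)
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    n_bootstrap: int


def auc(scores, labels, n_bootstrap: int = N_BOOTSTRAP, seed: int = 0) -> AucResult:
    """Rank AUC with a class-stratified bootstrap percentile 95% CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    point = rank_auc(scores, labels)
    pos = scores[labels]
    neg = scores[~labels]
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    ones = np.ones(len(pos), dtype=bool)
    zeros = np.zeros(len(neg), dtype=bool)
    lab = np.concatenate([ones, zeros])
    for b in range(n_bootstrap):
        s = np.concatenate(
            [rng.choice(pos, size=len(pos)), rng.choice(neg, size=len(neg))]
        )
        boots[b] = rank_auc(s, lab)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return AucResult(point, float(lo), float(hi), n_bootstrap)


# ------------------------------------------------------------------ cascade

@dataclass
class CascadeResult:
    """Per-sample calls from the sequential S -> D cascade.

    ``calls`` has columns s_score, d_score, s_call, d_call (pd.NA where the
    screening model was negative — the triage model is only consulted for
    screening positives), final_call.  The final call is positive iff both
    models call positive.
    """

    calls: pd.DataFrame
    stage_counts: pd.DataFrame | None = None

    def confusion(self, labels) -> ConfusionCounts:
        return ConfusionCounts.from_calls(
            self.calls["final_call"].to_numpy(dtype=bool), labels
        )


def cascade_classify(s_model, d_model, matrix) -> CascadeResult:
    """Apply the screening model, then the triage model to its positives."""
    from .training import score_samples  # local import avoids a cycle

    s_scores = score_samples(s_model, matrix)
    d_scores = score_samples(d_model, matrix)
    s_call = s_scores >= s_model.cutoff
    d_call_raw = d_scores >= d_model.cutoff
    final = s_call & d_call_raw
    calls = pd.DataFrame(
        {
            "s_score": s_scores,
            "d_score": d_scores,
            "s_call": s_call,
            "d_call": pd.array(
                [bool(d) if s else pd.NA for s, d in zip(s_call, d_call_raw)],
                dtype="boolean",
            ),
            "final_call": final,
        },
        index=s_scores.index,
    )
    return CascadeResult(calls)


def cascade_stage_counts(result: CascadeResult, groups: pd.Series) -> pd.DataFrame:
    """Audit table: per group, screening positives and triage reversals."""
    g = groups.reindex(result.calls.index)
    rows = []
    for name, sub in result.calls.groupby(g):
        s_pos = int(sub["s_call"].sum())
        reclassified = int((sub["s_call"] & ~sub["final_call"]).sum())
        rows.append(
            {
                "group": name,
                "n": len(sub),
                "s_positive": s_pos,
                "d_reclassified_negative": reclassified,
                "final_positive": int(sub["final_call"].sum()),
            }
        )
    return pd.DataFrame(rows).set_index("group")


# ------------------------------------------------------- prevalence adjust

def prevalence_adjust(sensitivity: float, specificity: float, prevalence: float):
    """Predictive values at an intended-use prevalence, by Bayes' rule.

    ppv = sens*prev / (sens*prev + (1-spec)(1-prev));
    npv = spec*(1-prev) / (spec*(1-prev) + (1-sens)*prev).
    Returns (ppv, npv); a zero denominator yields None for that value.
    """
    for name, v in (
        ("sensitivity", sensitivity),
        ("specificity", specificity),
        ("prevalence", prevalence),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
    ppv_den = sensitivity * prevalence + (1.0 - specificity) * (1.0 - prevalence)
    npv_den = specificity * (1.0 - prevalence) + (1.0 - sensitivity) * prevalence
    ppv = sensitivity * prevalence / ppv_den if ppv_den > 0 else None
    npv = specificity * (1.0 - prevalence) / npv_den if npv_den > 0 else None
    return ppv, npv


# ------------------------------------------------------- covariate testing

def covariate_association(scores, groups) -> pd.DataFrame:
    """Two-sided Mann-Whitney comparison of model scores between covariate
    groups; more than two groups are compared pairwise with BH adjustment.

    Groups with fewer than 2 observations are skipped with a warning.
    Returns a table (group_a, group_b, n_a, n_b, p_value, q_value).
    """
    scores = pd.Series(np.asarray(scores, dtype=float))
    groups = pd.Series(np.asarray(groups, dtype=object))
    level_values = {}
    for level in pd.unique(groups.dropna()):
        vals = scores[(groups == level).to_numpy()].dropna()
        if len(vals) < 2:
            logger.warning(
                "covariate_association: skipping group %r with %d sample(s)",
                level, len(vals),
            )
            continue
        level_values[level] = vals.to_numpy()
    levels = sorted(level_values)
    if len(levels) < 2:
        raise ValueError("need at least two covariate groups with >= 2 samples")
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = levels[i], levels[j]
            p = mannwhitneyu(
                level_values[a], level_values[b], alternative="two-sided"
            ).pvalue
            rows.append((a, b, len(level_values[a]), len(level_values[b]), float(p)))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b", "p_value"])
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


# ------------------------------------------------------------ CEA combiner

@dataclass(frozen=True)
class CeaCombination:
    auc_cea: float
    auc_model: float
    auc_combined: float
    coef_model: float
    coef_cea: float
    intercept: float
    n_used: int
    fallback: bool = False


def combine_with_cea(d_scores, cea_values, labels, seed: int = 0) -> CeaCombination:
    """Bivariate logistic combination of the triage-model score with serum
    CEA (entered as log10(value + 1) to tame its right skew).

    Pairwise-complete: samples missing either value are dropped, with the
    used count reported.  A constant CEA column degrades gracefully to the
    model score alone (fallback flag set).
    """
    d = np.asarray(d_scores, dtype=float)
    c = np.asarray(cea_values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    ok = ~(np.isnan(d) | np.isnan(c))
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("combine_with_cea: dropping %d incomplete pair(s)", n_dropped)
    d, c, y = d[ok], c[ok], y[ok]
    log_cea = np.log10(c + 1.0)
    auc_model = rank_auc(d, y)
    auc_cea = rank_auc(log_cea, y)
    if np.allclose(log_cea, log_cea[0]):
        logger.warning("combine_with_cea: CEA is constant; falling back to model alone")
        return CeaCombination(
            auc_cea=0.5, auc_model=auc_model, auc_combined=auc_model,
            coef_model=float("nan"), coef_cea=0.0, intercept=float("nan"),
            n_used=len(d), fallback=True,
        )
    X = np.column_stack([d, log_cea])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    lr = LogisticRegression(C=1.0, max_iter=1000)
    lr.fit((X - mu) / sd, y)
    combined = lr.predict_proba((X - mu) / sd)[:, 1]
    return CeaCombination(
        auc_cea=auc_cea,
        auc_model=auc_model,
        auc_combined=rank_auc(combined, y),
        coef_model=float(lr.coef_[0, 0]),
        coef_cea=float(lr.coef_[0, 1]),
        intercept=float(lr.intercept_[0]),
        n_used=len(d),
    )


# -------------------------------------------------------------- reporting

@dataclass
class PerformanceReport:
    """Point metrics with stratified-bootstrap percentile CIs."""

    counts: ConfusionCounts
    metrics: dict                       # sensitivity/specificity/ppv/npv
    auc: AucResult | None
    ci: dict                            # metric -> (low, high)
    n_bootstrap: int
    subgroups: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "counts": vars(self.counts),
            "n_bootstrap": self.n_bootstrap,
        }
        for m in ("sensitivity", "specificity", "ppv", "npv"):
            d[m] = self.metrics.get(m)
            if m in self.ci:
                d[f"{m}_ci"] = list(self.ci[m])
        if self.auc is not None:
            d["auc"] = self.auc.auc
            d["auc_ci"] = [self.auc.ci_low, self.auc.ci_high]
        if self.subgroups:
            d["subgroups"] = self.subgroups
        return d


def performance_report(
    scores,
    labels,
    cutoff: float,
    n_bootstrap: int = N_BOOTSTRAP,
    seed: int = 0,
    subgroups: pd.DataFrame | None = None,
) -> PerformanceReport:
    """Evaluate thresholded scores against binary labels.

    Point sensitivity/specificity/PPV/NPV from the confusion table, rank
    AUC, and percentile CIs from ``n_bootstrap`` class-stratified resamples.
    ``subgroups`` (optional, aligned with scores) yields per-level
    sensitivity breakdowns per column (e.g. stage, size bin, histology).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    calls = scores >= cutoff
    counts = ConfusionCounts.from_calls(calls, labels)
    metrics = confusion_metrics(counts)
    auc_res = auc(scores, labels, n_bootstrap=n_bootstrap, seed=seed)

    rng = np.random.default_rng(seed + 1)
    pos_idx = np.flatnonzero(labels)
    neg_idx = np.flatnonzero(~labels)
    boot = {m: [] for m in ("sensitivity", "specificity", "ppv", "npv")}
    for _ in range(n_bootstrap):
        idx = np.concatenate(
            [rng.choice(pos_idx, size=len(pos_idx)), rng.choice(neg_idx, size=len(neg_idx))]
        )
        m = confusion_metrics(ConfusionCounts.from_calls(calls[idx], labels[idx]))
        for k in boot:
            if m[k] is not None:
                boot[k].append(m[k])
    ci = {
        k: tuple(np.percentile(v, [2.5, 97.5])) for k, v in boot.items() if v
    }

    sub: dict = {}
    if subgroups is not None:
        for col in subgroups.columns:
            levels = {}
            vals = subgroups[col].to_numpy(dtype=object)
            for level in pd.unique(vals):
                if level is None or (isinstance(level, float) and np.isnan(level)) or level == "":
                    continue
                mask = vals == level
                cc = ConfusionCounts.from_calls(calls[mask], labels[mask])
                levels[str(level)] = {
                    "n": int(mask.sum()),
                    **{k: v for k, v in confusion_metrics(cc).items() if k != "reasons"},
                }
            if levels:
                sub[col] = levels
    return PerformanceReport(counts, metrics, auc_res, ci, n_bootstrap, sub)
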