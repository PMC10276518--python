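"""Panel classifier construction by anchor-based forward selection.

Two differently tuned linear log-odds (logistic) classifiers are built over
a verified marker panel:

* mode "S" (screening): trained cancer-vs-healthy, cutoff calibrated to a
  target sensitivity (default 0.90);
* mode "D" (diagnostic/triage): trained cancer-vs-benign, cutoff calibrated
  to a target specificity against the benign contrast group (default 0.95).

Marker subsets are chosen greedily: the single marker with the highest
repeated-cross-validation AUC anchors the model, candidate markers are
added one at a time, each addition scored by 10 x 4-fold stratified
cross-validation (fold assignment re-randomized per repeat), and the final
subset is the global AUC argmax along the greedy path — ties prefer the
smaller subset, then panel order.  Imputation (training-fold medians) and
standardization are fit strictly within training folds; each training
sample also receives an out-of-fold score averaged over the 10 repeats,
which is what cutoff calibration uses.  A light ridge penalty (strength
1.0 on standardized features) stabilizes the fits at small n.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold

from .evaluate import rank_auc
from .markers import MarkerPanel
from .quantify import MethylationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfig",
    "CVResult",
    "PanelClassifier",
    "cv_auc",
    "forward_select",
    "calibrate_cutoff",
    "score_samples",
    "train_classifier",
    "RIDGE_STRENGTH",
]

# Inverse regularization C = 1/strength for the logistic fits.
RIDGE_STRENGTH = 1.0


@dataclass(frozen=True)
class CVConfig:
    n_repeats: int = 10
    n_folds: int = 4
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class CVResult:
    mean_auc: float
    repeat_aucs: list
    oof_scores: np.ndarray  # per-sample out-of-fold score, mean over repeats


@dataclass
class PanelClassifier:
    """A fitted linear log-odds model over a marker subset.

    ``oof_scores`` are the training samples' out-of-fold cross-validation
    scores (averaged over repeats) — the scores used for cutoff
    calibration; ``score_samples`` uses the final refit model.  The two are
    deliberately kept distinct.
    """

    mode: str                       # "S" or "D"
    markers: list
    coef: list
    intercept: float
    medians: list                   # per-marker imputation values
    means: list                     # standardization centers
    stds: list                      # standardization scales
    cutoff: float = 0.5
    cv_auc_mean: float = float("nan")
    cv_config: dict = field(default_factory=dict)
    oof_scores: dict = field(default_factory=dict)   # sample id -> score
    selection_path: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "mode": self.mode,
            "markers": list(self.markers),
            "coef": [float(c) for c in self.coef],
            "intercept": float(self.intercept),
            "medians": [float(v) for v in self.medians],
            "means": [float(v) for v in self.means],
            "stds": [float(v) for v in self.stds],
            "cutoff": float(self.cutoff),
            "cv_auc_mean": float(self.cv_auc_mean),
            "cv_config": self.cv_config,
            "oof_scores": {k: float(v) for k, v in self.oof_scores.items()},
            "selection_path": self.selection_path,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "PanelClassifier":
        if isinstance(source, (str, bytes)) and "{" in str(source):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(**payload)


def _amf_frame(data) -> pd.DataFrame:
    if isinstance(data, MethylationMatrix):
        return data.amf
    return data


def _fit_fold(X_tr, y_tr):
    """Impute (median), standardize, ridge-logistic fit; returns the pieces."""
    med = np.nanmedian(X_tr, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    X = np.where(np.isnan(X_tr), med, X_tr)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    lr = LogisticRegression(C=1.0 / RIDGE_STRENGTH, max_iter=1000)
    lr.fit((X - mu) / sd, y_tr)
    return med, mu, sd, lr


def _apply_fold(X_te, med, mu, sd, lr):
    X = np.where(np.isnan(X_te), med, X_te)
    return lr.predict_proba((X - mu) / sd)[:, 1]


def cv_auc(markers, amf, labels, cv: CVConfig) -> CVResult:
    """Mean out-of-fold AUC of a marker subset over repeated CV.

    For repeat ``r`` folds are drawn with seed ``cv.seed + r``; the model
    is fit on ``n_folds - 1`` folds and scores the held-out fold, the AUC
    of the pooled out-of-fold scores is recorded per repeat, and the mean
    over repeats is returned together with per-repeat values and each
    sample's repeat-averaged out-of-fold score.
    """
    markers = list(markers)
    if not markers:
        raise ValueError("marker subset is empty")
    amf = _amf_frame(amf)
    missing = [m for m in markers if m not in amf.columns]
    if missing:
        raise KeyError(f"markers absent from matrix: {missing}")
    X = amf[markers].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")

    repeat_aucs = []
    oof_sum = np.zeros(len(y))
    for r in range(cv.n_repeats):
        seed_r = cv.seed + r
        if cv.stratified:
            splitter = StratifiedKFold(cv.n_folds, shuffle=True, random_state=seed_r)
            split = splitter.split(X, y)
        else:
            splitter = KFold(cv.n_folds, shuffle=True, random_state=seed_r)
            split = splitter.split(X)
        oof = np.empty(len(y))
        for tr, te in split:
            if len(np.unique(y[tr])) < 2:
                raise ValueError(
                    "a training fold lacks both classes; use stratified folds"
                )
            med, mu, sd, lr = _fit_fold(X[tr], y[tr])
            oof[te] = _apply_fold(X[te], med, mu, sd, lr)
        repeat_aucs.append(rank_auc(oof, y))
        oof_sum += oof
    return CVResult(
        mean_auc=float(np.mean(repeat_aucs)),
        repeat_aucs=[float(a) for a in repeat_aucs],
        oof_scores=oof_sum / cv.n_repeats,
    )


def forward_select(panel, amf, labels, cv: CVConfig, mode: str = "S") -> PanelClassifier:
    """Greedy anchor-based forward marker selection.

    The anchor is the marker with the highest single-marker CV AUC.  Each
    step adds the marker maximizing the combined CV AUC (ties: earlier
    panel order).  The returned model uses the globally best subset along
    the path (ties: smaller subset), refit on all training data, and
    carries the winning subset's repeat-averaged out-of-fold scores.
    """
    if isinstance(panel, MarkerPanel):
        candidates = list(panel.regions)
    else:
        candidates = list(panel)
    if not candidates:
        raise ValueError("panel is empty")
    amf = _amf_frame(amf)
    y = np.asarray(labels, dtype=int)

    order = {m: i for i, m in enumerate(candidates)}
    results = {}

    def eval_subset(subset):
        key = tuple(subset)
        if key not in results:
            results[key] = cv_auc(subset, amf, y, cv)
        return results[key]

    singles = {m: eval_subset([m]).mean_auc for m in candidates}
    anchor = max(candidates, key=lambda m: (singles[m], -order[m]))
    current = [anchor]
    path = [(list(current), eval_subset(current))]
    remaining = [m for m in candidates if m != anchor]
    while remaining:
        scored = [(eval_subset(current + [m]).mean_auc, -order[m], m) for m in remaining]
        best_auc, _, best_m = max(scored)
        current = current + [best_m]
        remaining.remove(best_m)
        path.append((list(current), eval_subset(current)))

    # Global argmax over the greedy path; strict ">" keeps the smaller
    # subset on ties (sizes are visited in increasing order).
    best_subset, best_res = path[0]
    for subset, res in path[1:]:
        if res.mean_auc > best_res.mean_auc + 1e-12:
            best_subset, best_res = subset, res

    X = amf[best_subset].to_numpy(dtype=float)
    med, mu, sd, lr = _fit_fold(X, y)
    model = PanelClassifier(
        mode=mode,
        markers=best_subset,
        coef=lr.coef_[0].tolist(),
        intercept=float(lr.intercept_[0]),
        medians=med.tolist(),
        means=mu.tolist(),
        stds=sd.tolist(),
        cv_auc_mean=best_res.mean_auc,
        cv_config={
            "n_repeats": cv.n_repeats,
            "n_folds": cv.n_folds,
            "stratified": cv.stratified,
            "seed": cv.seed,
        },
        oof_scores=dict(zip(amf.index.astype(str), best_res.oof_scores)),
        selection_path=[
            {"markers": s, "cv_auc": r.mean_auc} for s, r in path
        ],
    )
    logger.info(
        "forward_select(mode=%s): %d/%d markers, CV AUC %.4f",
        mode, len(best_subset), len(candidates), best_res.mean_auc,
    )
    return model


def calibrate_cutoff(
    scores,
    labels,
    mode: str,
    target_sens: float = 0.90,
    target_spec: float = 0.95,
) -> float:
    """Choose a probability cutoff from training out-of-fold scores.

    Mode "S": the *largest* cutoff whose training sensitivity still meets
    ``target_sens`` (favoring specificity subject to the sensitivity
    floor).  Mode "D": the *smallest* cutoff whose specificity against the
    contrast group (labels == 0) meets ``target_spec``.  An unattainable
    target returns the boundary cutoff with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    candidates = np.unique(scores)
    if mode == "S":
        pos = scores[labels]
        if len(pos) == 0:
            raise ValueError("no positive-class samples to calibrate sensitivity")
        ok = [c for c in candidates if np.mean(pos >= c) >= target_sens]
        if not ok:
            logger.warning(
                "calibrate_cutoff(S): target sensitivity %.2f unattainable; "
                "using minimum score", target_sens,
            )
            return float(candidates[0])
        return float(max(ok))
    if mode == "D":
        neg = scores[~labels]
        if len(neg) == 0:
            raise ValueError("no contrast-class samples to calibrate specificity")
        ok = [c for c in candidates if np.mean(neg < c) >= target_spec]
        if not ok:
            hi = float(np.nextafter(candidates[-1], np.inf))
            logger.warning(
                "calibrate_cutoff(D): target specificity %.2f unattainable; "
                "using cutoff above maximum score", target_spec,
            )
            return hi
        return float(min(ok))
    raise ValueError(f"mode must be 'S' or 'D', got {mode!r}")


def score_samples(model: PanelClassifier, data) -> pd.Series:
    """Deployment scores from the final refit model.

    Missing marker *values* are imputed by the stored training medians;
    a marker column absent from the matrix entirely is a hard error.
    """
    amf = _amf_frame(data)
    missing = [m for m in model.markers if m not in amf.columns]
    if missing:
        raise KeyError(f"matrix lacks model markers: {missing}")
    X = amf[model.markers].to_numpy(dtype=float)
    med = np.asarray(model.medians)
    mu = np.asarray(model.means)
    sd = np.asarray(model.stds)
    X = np.where(np.isnan(X), med, X)
    z = (X - mu) / sd
    logit = z @ np.asarray(model.coef) + model.intercept
    return pd.Series(1.0 / (1.0 + np.exp(-logit)), index=amf.index, name="score")


def train_classifier(
    panel,
    amf,
    labels,
    cv: CVConfig,
    mode: str = "S",
    target_sens: float = 0.90,
    target_spec: float = 0.95,
) -> PanelClassifier:
    """Forward-select a subset, then calibrate the cutoff on the training
    out-of-fold scores (never on refit in-sample scores)."""
    model = forward_select(panel, amf, labels, cv, mode=mode)
    frame = _amf_frame(amf)
    oof = np.array([model.oof_scores[str(s)] for s in frame.index])
    model.cutoff = calibrate_cutoff(
        oof, labels, mode, target_sens=target_sens, target_spec=target_spec
    )
    return model
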