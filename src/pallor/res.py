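"""Risk evaluation scheme (RES) for anemia screening.

A two-class anemic/nonanemic call at a hard hemoglobin threshold (default
11 g/dL) overstates certainty for estimates near the cutoff. RES attaches an
error tolerance range (ETR) to every Hb estimate and to the threshold
itself: the threshold's interval [T - ETR, T + ETR] defines the *doubtful*
zone, and a sample whose own interval [est - ETR, est + ETR] touches it —
equivalently |est - T| <= 2*ETR, boundary contact included — is a *suspect*
sample that needs a confirmatory blood test. The remaining samples are
confidently called: *high risk* (anemic) below the zone, *low risk* above.

Aggregate quality is measured by three indices on a labeled test set:

    high-risk index = anemic-labeled / all samples in the high-risk level
    low-risk index  = nonanemic-labeled / all samples in the low-risk level
    doubtful index  = nonsuspect samples / all samples

plus sensitivity and specificity computed on the nonsuspect samples only.
Empty denominators (e.g. every sample suspect) are reported as NaN with an
explicit flag rather than as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RESConfig",
    "LEVELS",
    "classify_sample",
    "classify_samples",
    "compute_etr",
    "compute_indices",
    "nonsuspect_confusion",
    "evaluate",
]

LEVELS = ("high_risk", "doubtful", "low_risk")


@dataclass
class RESConfig:
    """Threshold and error-tolerance settings.

    ``etr_mode``: "train_sd" derives ETR from the sample standard deviation
    of the training Hb values (recomputed per training set); "fixed" uses
    ``etr`` as given, in g/dL; "train_feature_sd" takes the standard
    deviation of the (smoothed) training feature values and maps it to Hb
    units through the fitted curve's local slope at the threshold.
    """

    threshold: float = 11.0
    etr_mode: str = "train_sd"
    etr: float = 0.0

    def validate(self) -> None:
        if self.threshold <= 0:
            raise ValueError(f"threshold must be positive, got {self.threshold}")
        if self.etr_mode not in ("train_sd", "fixed", "train_feature_sd"):
            raise ValueError(f"unknown etr_mode {self.etr_mode!r}")
        if self.etr < 0:
            raise ValueError(f"ETR must be >= 0, got {self.etr}")


def compute_etr(
    train_hb,
    mode: str = "train_sd",
    fixed: float = 0.0,
    features=None,
    slope_at_threshold: float | None = None,
) -> float:
    """ETR in g/dL.

    "train_sd": sample standard deviation (N-1) of the training Hb values.
    "fixed": the configured constant.
    "train_feature_sd": sd of the training feature values divided by the
    magnitude of the fitted curve's slope at the threshold (feature units per
    g/dL); a flat curve gives an infinite ETR, i.e. everything suspect.
    """
    if mode == "fixed":
        if fixed < 0:
            raise ValueError("fixed ETR must be >= 0")
        return float(fixed)
    if mode == "train_sd":
        hb = np.asarray(train_hb, dtype=float)
        if len(hb) < 2:
            raise ValueError("train_sd mode needs at least 2 training Hb values")
        return float(np.std(hb, ddof=1))
    if mode == "train_feature_sd":
        if features is None or slope_at_threshold is None:
            raise ValueError(
                "train_feature_sd mode needs the training features and the "
                "curve slope at the threshold"
            )
        feats = np.asarray(features, dtype=float)
        if len(feats) < 2:
            raise ValueError("train_feature_sd mode needs >= 2 feature values")
        sd = float(np.std(feats, ddof=1))
        return sd / abs(slope_at_threshold) if slope_at_threshold else math.inf
    raise ValueError(f"unknown ETR mode {mode!r}")


def classify_sample(est_hb: float, etr: float, cfg: RESConfig | None = None) -> tuple[str, bool]:
    """Assign a risk level and suspect flag to one Hb estimate.

    The sample's interval touches the doubtful interval iff
    |est - threshold| <= 2*ETR (closed comparison: boundary contact counts,
    the conservative screening choice). Returns ``(level, suspect)`` where
    suspect is True exactly for the doubtful level.
    """
    if cfg is None:
        cfg = RESConfig()
    cfg.validate()
    if etr < 0:
        raise ValueError(f"ETR must be >= 0, got {etr}")
    T = cfg.threshold
    if abs(est_hb - T) <= 2.0 * etr:
        return "doubtful", True
    return ("high_risk", False) if est_hb < T else ("low_risk", False)


def classify_samples(outcomes: pd.DataFrame, etr: float, cfg: RESConfig | None = None) -> pd.DataFrame:
    """Vectorized :func:`classify_sample` over an ``est_hb`` column."""
    levels, suspects = zip(
        *(classify_sample(e, etr, cfg) for e in outcomes["est_hb"])
    ) if len(outcomes) else ((), ())
    out = outcomes.copy()
    out["level"] = list(levels)
    out["suspect"] = list(suspects)
    out["etr"] = etr
    return out


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


def compute_indices(outcomes: pd.DataFrame) -> dict:
    """Aggregate RES indices from per-sample results.

    Expects columns ``level``, ``suspect`` and ``label`` (values "anemic" /
    "nonanemic"). A level with no samples yields a NaN index and an entry in
    ``undefined`` — all test samples being suspect is the canonical case.
    """
    _require(outcomes, ("level", "suspect", "label"))
    total = len(outcomes)
    high = outcomes[outcomes["level"] == "high_risk"]
    low = outcomes[outcomes["level"] == "low_risk"]
    n_suspect = int(outcomes["suspect"].sum())

    high_idx = _ratio(int((high["label"] == "anemic").sum()), len(high))
    low_idx = _ratio(int((low["label"] == "nonanemic").sum()), len(low))
    undefined = [
        name
        for name, den in (("high_risk_index", len(high)), ("low_risk_index", len(low)))
        if den == 0
    ]
    return {
        "high_risk_index": high_idx,
        "low_risk_index": low_idx,
        "doubtful_index": (total - n_suspect) / total,
        "n_suspect": n_suspect,
        "n_total": total,
        "undefined": undefined,
    }


def nonsuspect_confusion(outcomes: pd.DataFrame) -> dict:
    """Sensitivity and specificity restricted to nonsuspect samples.

    Among nonsuspect samples the predicted class is anemic iff the level is
    high_risk. Undefined denominators (no nonsuspect anemic, or no nonsuspect
    nonanemic samples) are NaN and flagged.
    """
    _require(outcomes, ("level", "suspect", "label"))
    ns = outcomes[~outcomes["suspect"].astype(bool)]
    pred_anemic = ns["level"] == "high_risk"
    true_anemic = ns["label"] == "anemic"
    tp = int((pred_anemic & true_anemic).sum())
    fn = int((~pred_anemic & true_anemic).sum())
    tn = int((~pred_anemic & ~true_anemic).sum())
    fp = int((pred_anemic & ~true_anemic).sum())
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    undefined = [
        name
        for name, den in (("sensitivity", tp + fn), ("specificity", tn + fp))
        if den == 0
    ]
    return {
        "sensitivity": sens,
        "specificity": spec,
        "tp": tp,
        "fn": fn,
        "tn": tn,
        "fp": fp,
        "n_nonsuspect": len(ns),
        "undefined": undefined,
    }


def evaluate(outcomes: pd.DataFrame) -> dict:
    """Indices plus nonsuspect confusion in one aggregate report."""
    report = compute_indices(outcomes)
    conf = nonsuspect_confusion(outcomes)
    report["undefined"] = report["undefined"] + conf.pop("undefined")
    report.update(conf)
    return report


def _require(outcomes: pd.DataFrame, cols) -> None:
    if len(outcomes) == 0:
        raise ValueError("outcome table is empty")
    missing = [c for c in cols if c not in outcomes.columns]
    if missing:
        raise ValueError(f"outcome table is missing columns {missing}")
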