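"""End-to-end screening pipeline under k-fold cross-validation.

One fold: extract the chosen color feature for train and test subjects,
sort the training pairs by Hb and collapse duplicates, optionally smooth the
series with the scalar Kalman filter, fit the regressor (penalized quartic
or closed-form line), compute the fold's ETR from the training Hb values,
invert the fitted curve for every test feature over the training Hb range,
and classify each estimate with the risk evaluation scheme.

Cross-validation pools the per-fold test outcomes (every subject is tested
exactly once) and computes the aggregate indices on the pooled set, so no
per-fold denominator can be empty merely because a fold is small.

`run_comparison` evaluates a grid of method variants — feature x regressor x
Kalman on/off — and reports paired deltas between the Kalman-on and -off
rows of the same method, the headline quantity being the relative change in
the number of suspect samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import imaging, res
from .kalman import KalmanParams, kalman_filter, prepare_series
from .regression import (
    PenaltyConfig,
    fit_linear_regression,
    fit_penalty_regression,
    invert_model,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "kfold_split", "run_fold", "run_cv", "run_comparison", "variant_name"]

REGRESSORS = ("penalty_poly", "linear")


@dataclass
class PipelineConfig:
    """All tunables of one method variant."""

    feature_name: str = "mean_red"
    use_kf: bool = True
    regressor: str = "penalty_poly"
    kalman: KalmanParams = field(default_factory=KalmanParams)
    penalty: PenaltyConfig = field(default_factory=PenaltyConfig)
    res: res.RESConfig = field(default_factory=res.RESConfig)
    n_folds: int = 10
    cv_seed: int = 0
    resize_side: int = 500
    stratify: bool = False

    def validate(self, n_samples: int | None = None) -> None:
        if self.feature_name not in imaging.FEATURE_NAMES:
            raise ValueError(f"unknown feature {self.feature_name!r}")
        if self.regressor not in REGRESSORS:
            raise ValueError(f"unknown regressor {self.regressor!r}")
        if self.n_folds < 2:
            raise ValueError(f"need at least 2 folds, got {self.n_folds}")
        if n_samples is not None and self.n_folds > n_samples:
            raise ValueError(
                f"{self.n_folds} folds exceed the {n_samples} available samples"
            )
        self.res.validate()


def variant_name(cfg: PipelineConfig) -> str:
    """Human-readable "KF + <feature> + <regressor>" style label."""
    reg = {"penalty_poly": "nonlinear penalty regression", "linear": "linear regression"}[
        cfg.regressor
    ]
    feat = {"mean_red": "R", "erythema": "erythema index", "hue": "hue"}[cfg.feature_name]
    prefix = "KF + " if cfg.use_kf else ""
    return f"{prefix}{feat} + {reg}"


def kfold_split(n: int, k: int, seed: int, labels=None):
    """Seeded permutation split into k near-equal folds.

    Returns a list of ``(train_idx, test_idx)`` pairs; every index appears in
    exactly one test fold. With ``labels`` given, the permutation is applied
    within each class (stratified folds); plain random is the default.
    """
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    if labels is None:
        folds = np.array_split(rng.permutation(n), k)
    else:
        # round-robin each permuted class over the folds
        labels = np.asarray(labels)
        folds = [[] for _ in range(k)]
        offset = 0
        for lab in np.unique(labels):
            for j, idx in enumerate(rng.permutation(np.flatnonzero(labels == lab))):
                folds[(offset + j) % k].append(idx)
            offset += j + 1
        folds = [np.asarray(f, dtype=int) for f in folds]
    out = []
    for i, test in enumerate(folds):
        train = np.concatenate([folds[j] for j in range(k) if j != i])
        out.append((np.sort(train), np.sort(test)))
    return out


def _feature_frame(dataset, cfg: PipelineConfig) -> pd.DataFrame:
    """Normalize the input to a (subject_id, hb_g_dl, value, label) frame.

    ``dataset`` is either a feature table (columns subject_id, hb_g_dl and
    one of value/feature) or a manifest path/frame pointing at images, in
    which case features are extracted here.
    """
    if isinstance(dataset, pd.DataFrame) and (
        "value" in dataset.columns or "feature" in dataset.columns
    ):
        df = dataset.rename(columns={"feature": "value"}).copy()
    else:
        df = imaging.extract_feature_table(
            dataset, feature_name=cfg.feature_name, resize_side=cfg.resize_side
        )
    if "subject_id" not in df.columns:
        df["subject_id"] = [f"s{i}" for i in range(len(df))]
    if "label" not in df.columns:
        df["label"] = np.where(
            df["hb_g_dl"] < cfg.res.threshold, "anemic", "nonanemic"
        )
    return df[["subject_id", "hb_g_dl", "value", "label"]]


def run_fold(train: pd.DataFrame, test: pd.DataFrame, cfg: PipelineConfig,
             fold_id: int = 0) -> pd.DataFrame:
    """Train on one fold and classify its held-out samples.

    ``train`` and ``test`` are feature frames (columns subject_id, hb_g_dl,
    value, label). Returns the per-sample RES outcomes with the fold id.
    """
    if len(train) == 0:
        raise ValueError(f"fold {fold_id}: empty training set")
    try:
        series = prepare_series(train["hb_g_dl"].to_numpy(), train["value"].to_numpy())
        if cfg.use_kf:
            series = kalman_filter(series, cfg.kalman)
        if cfg.regressor == "penalty_poly":
            model = fit_penalty_regression(series, cfg.penalty)
        else:
            model = fit_linear_regression(series)
        slope_at_t = float(
            np.polynomial.polynomial.polyval(
                cfg.res.threshold, np.polynomial.polynomial.polyder(model.coeffs)
            )
        )
        etr = res.compute_etr(
            train["hb_g_dl"],
            mode=cfg.res.etr_mode,
            fixed=cfg.res.etr,
            features=series.values,
            slope_at_threshold=slope_at_t,
        )
        h_lo, h_hi = float(train["hb_g_dl"].min()), float(train["hb_g_dl"].max())
        est = np.array(
            [invert_model(model, v, (h_lo, h_hi)) for v in test["value"]]
        )
    except Exception as exc:
        raise type(exc)(f"fold {fold_id}: {exc}") from exc

    out = test.copy()
    out["est_hb"] = est
    out = res.classify_samples(out, etr, cfg.res)
    out["fold"] = fold_id
    logger.info(
        "fold %d: ETR=%.3f, fit=%s, %d suspect of %d",
        fold_id, etr, getattr(model, "fit_report", {}), int(out["suspect"].sum()), len(out),
    )
    return out


def run_cv(dataset, cfg: PipelineConfig | None = None) -> dict:
    """Cross-validate one method variant and aggregate pooled outcomes.

    Returns a report dict with the RES indices, nonsuspect sensitivity and
    specificity, suspect count, the variant name, and the pooled per-sample
    outcome table under ``"outcomes"``.
    """
    if cfg is None:
        cfg = PipelineConfig()
    df = _feature_frame(dataset, cfg)
    cfg.validate(n_samples=len(df))
    labels = df["label"].to_numpy() if cfg.stratify else None
    splits = kfold_split(len(df), cfg.n_folds, cfg.cv_seed, labels=labels)
    pooled = pd.concat(
        [
            run_fold(df.iloc[tr], df.iloc[te], cfg, fold_id=i)
            for i, (tr, te) in enumerate(splits)
        ],
        ignore_index=True,
    )
    report = res.evaluate(pooled)
    report["variant"] = variant_name(cfg)
    report["feature_name"] = cfg.feature_name
    report["use_kf"] = cfg.use_kf
    report["regressor"] = cfg.regressor
    report["outcomes"] = pooled
    return report


def run_comparison(dataset, variants: list[PipelineConfig]) -> pd.DataFrame:
    """Evaluate several variants and add paired Kalman on/off deltas.

    One row per variant. For every (feature, regressor) pair present both with
    and without the filter, the KF-on row carries the percentage-point
    changes in sensitivity/specificity and the relative change
    (after - before)/before in the suspect count.
    """
    if not variants:
        raise ValueError("need at least one variant")
    # image datasets: extract all needed features in one resize pass
    precomputed = isinstance(dataset, pd.DataFrame) and (
        "value" in dataset.columns or "feature" in dataset.columns
    )
    if not precomputed:
        names = tuple(dict.fromkeys(cfg.feature_name for cfg in variants))
        cache = imaging.extract_feature_tables(
            dataset, names, resize_side=variants[0].resize_side
        )
    rows = []
    for cfg in variants:
        data = dataset if precomputed else cache[cfg.feature_name]
        rep = run_cv(data, cfg)
        rep.pop("outcomes")
        rep.pop("undefined", None)
        rows.append(rep)
    table = pd.DataFrame(rows)
    table["delta_sensitivity"] = np.nan
    table["delta_specificity"] = np.nan
    table["delta_n_suspect_rel"] = np.nan
    for (feat, reg), grp in table.groupby(["feature_name", "regressor"]):
        if set(grp["use_kf"]) == {True, False}:
            on = grp[grp["use_kf"]].index[0]
            off = grp[~grp["use_kf"]].index[0]
            table.loc[on, "delta_sensitivity"] = (
                table.loc[on, "sensitivity"] - table.loc[off, "sensitivity"]
            )
            table.loc[on, "delta_specificity"] = (
                table.loc[on, "specificity"] - table.loc[off, "specificity"]
            )
            before = table.loc[off, "n_suspect"]
            if before:
                table.loc[on, "delta_n_suspect_rel"] = (
                    table.loc[on, "n_suspect"] - before
                ) / before
    return table
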