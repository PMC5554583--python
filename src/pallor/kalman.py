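"""Scalar Kalman smoothing of hemoglobin-ordered feature series.

Conjunctiva color features carry measurement error from camera settings and
ambient light. Treating the hemoglobin (Hb) level as the independent variable
(the role time plays in a tracking problem) and the color feature as the noisy
dependent variable, a one-dimensional Kalman filter with constant process and
measurement noise (state transition F = 1, observation H = 1, no control input)
reduces the scatter of the feature series before a regression curve is fitted.

The recursion, for k = 2..M with x(1) = z(1) and P(1) = P1:

    K(k) = (P(k-1) + Q) / (P(k-1) + Q + R)
    x(k) = K(k) * z(k) + (1 - K(k)) * x(k-1)
    P(k) = (1 - K(k)) * P(k-1) - 2*Q*K(k) + 2*Q

where z is the raw feature, x the filtered estimate, K the gain and P the
running error covariance. Because the series is ordered by Hb, the filter is
causal in ascending-Hb order; filtering the reversed series generally gives a
different result.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSeries",
    "KalmanParams",
    "prepare_series",
    "kalman_filter",
    "variance_report",
]

#: Default sanity range for the noise constants Q and R.
NOISE_SANITY_RANGE = (1e-4, 1e-1)


@dataclass
class FeatureSeries:
    """Hb-ascending, duplicate-collapsed feature series.

    Attributes
    ----------
    hb : ndarray
        Hemoglobin levels in g/dL, strictly increasing.
    z : ndarray
        Raw feature values, one per Hb level.
    x : ndarray or None
        Filtered feature values (present after :func:`kalman_filter`).
    gain : ndarray or None
        Kalman gain trace K(k); K(1) is reported as 1 by convention
        (x(1) := z(1) means full trust in the first measurement).
    cov : ndarray or None
        Error covariance trace P(k).
    """

    hb: np.ndarray
    z: np.ndarray
    x: np.ndarray | None = None
    gain: np.ndarray | None = None
    cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hb = np.asarray(self.hb, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.hb.ndim != 1 or self.z.ndim != 1:
            raise ValueError("hb and z must be one-dimensional arrays")
        if len(self.hb) != len(self.z):
            raise ValueError(
                f"length mismatch: {len(self.hb)} Hb values vs {len(self.z)} features"
            )
        if len(self.hb) == 0:
            raise ValueError("feature series must contain at least one sample")
        if np.any(np.diff(self.hb) <= 0):
            raise ValueError("hb must be strictly increasing (collapse duplicates first)")

    def __len__(self) -> int:
        return len(self.hb)

    @property
    def values(self) -> np.ndarray:
        """Filtered values if available, else the raw feature values."""
        return self.z if self.x is None else self.x


@dataclass
class KalmanParams:
    """Constants of the simplified filter.

    Q and R default to 1e-2, the top of the small-constant range the method
    assumes for stable behaviour; both must be positive and are sanity-checked
    against ``sanity_range``.
    """

    Q: float = 1e-2
    R: float = 1e-2
    P1: float = 0.0
    sanity_range: tuple[float, float] = field(default=NOISE_SANITY_RANGE)

    def validate(self) -> None:
        if self.Q <= 0 or self.R <= 0:
            raise ValueError(f"Q and R must be positive, got Q={self.Q}, R={self.R}")
        if self.P1 < 0:
            raise ValueError(f"initial covariance P1 must be >= 0, got {self.P1}")
        lo, hi = self.sanity_range
        for name, val in (("Q", self.Q), ("R", self.R)):
            if not (lo <= val <= hi):
                warnings.warn(
                    f"{name}={val:g} outside the usual range [{lo:g}, {hi:g}]",
                    stacklevel=3,
                )


def prepare_series(hb_raw, feat_raw) -> FeatureSeries:
    """Sort (Hb, feature) pairs by ascending Hb and collapse duplicate Hb.

    One Hb level with finite precision can correspond to several feature
    values; such rows are averaged so the series becomes a one-to-one map.
    Duplicate detection uses exact equality of the values as given — Hb is
    never rounded or binned here.

    Parameters
    ----------
    hb_raw, feat_raw : array-like
        Equal-length arrays of Hb levels (g/dL, all > 0) and feature values.
    """
    hb = np.asarray(hb_raw, dtype=float)
    feat = np.asarray(feat_raw, dtype=float)
    if hb.ndim != 1 or feat.ndim != 1:
        raise ValueError("inputs must be one-dimensional")
    if len(hb) != len(feat):
        raise ValueError(f"length mismatch: {len(hb)} vs {len(feat)}")
    if len(hb) == 0:
        raise ValueError("cannot prepare an empty series")
    if np.any(hb <= 0):
        raise ValueError("all Hb values must be positive")

    order = np.argsort(hb, kind="stable")
    hb_sorted = hb[order]
    feat_sorted = feat[order]

    uniq, inverse = np.unique(hb_sorted, return_inverse=True)
    sums = np.bincount(inverse, weights=feat_sorted)
    counts = np.bincount(inverse)
    return FeatureSeries(hb=uniq, z=sums / counts)


def kalman_filter(series: FeatureSeries, params: KalmanParams | None = None) -> FeatureSeries:
    """Apply the simplified scalar Kalman filter to a prepared series.

    Returns a new :class:`FeatureSeries` carrying the filtered values ``x``
    together with the gain and covariance traces. The covariance update can in
    principle drive P below zero for some (Q, R, P) trajectories, which would
    push the gain out of (0, 1]; P is clamped at 0 (with a log warning) so
    that every update stays a convex combination of x(k-1) and z(k).
    """
    if params is None:
        params = KalmanParams()
    params.validate()

    M = len(series)
    z = series.z
    x = np.empty(M)
    K = np.empty(M)
    P = np.empty(M)

    x[0] = z[0]
    P[0] = params.P1
    K[0] = 1.0  # by convention: x(1) := z(1) is full trust in the first measurement
    Q, R = params.Q, params.R

    clamped = 0
    for k in range(1, M):
        K[k] = (P[k - 1] + Q) / (P[k - 1] + Q + R)
        x[k] = K[k] * z[k] + (1.0 - K[k]) * x[k - 1]
        Pk = (1.0 - K[k]) * P[k - 1] - 2.0 * Q * K[k] + 2.0 * Q
        if Pk < 0.0:
            clamped += 1
            Pk = 0.0
        P[k] = Pk
    if clamped:
        logger.warning(
            "covariance P went negative at %d of %d steps and was clamped to 0", clamped, M
        )

    return FeatureSeries(hb=series.hb.copy(), z=z.copy(), x=x, gain=K, cov=P)


def variance_report(series: FeatureSeries) -> dict[str, float]:
    """Standard deviations of the raw and filtered values and their ratio.

    The filter's purpose is to make the samples closer to each other; this
    summary quantifies that. For a single-sample series both standard
    deviations are 0 and the ratio is reported as 1.
    """
    if series.x is None:
        raise ValueError("series has not been filtered; run kalman_filter first")
    if len(series) < 2:
        return {"sd_raw": 0.0, "sd_filtered": 0.0, "ratio": 1.0}
    sd_z = float(np.std(series.z, ddof=1))
    sd_x = float(np.std(series.x, ddof=1))
    ratio = sd_x / sd_z if sd_z > 0 else 1.0
    return {"sd_raw": sd_z, "sd_filtered": sd_x, "ratio": ratio}
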