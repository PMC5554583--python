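"""Penalized polynomial regression of color feature on hemoglobin level.

The feature-vs-Hb relationship is modeled as an nth-order polynomial

    f(h) = sum_{i=0}^{n} a_i * h^i        (default n = 4)

whose coefficients minimize the ridge-penalized cost

    E = alpha * sum_k (f(h_k) - x_k)^2 + lambda * sum_{i>=1} c_i * a_i^2

by plain gradient descent: the update is a_i <- a_i - dE/da_i, so the
``alpha`` inside E doubles as the step size on the data term. The penalty
coefficients c_i grow with the order i, inhibiting high-order coefficients
and with them the curvature-driven overfitting that makes an unpenalized
quartic non-monotone (one feature value then maps to two Hb levels — a
matching issue at prediction time). The intercept a_0 is never penalized.

Divergence protection: if a proposed step increases E, it is rejected and the
step is retried at half length (a plain backtracking line search). The
halving leaves the stationary points of E untouched and never fires when
alpha and lambda are in the stable regime, where the procedure is exactly the
textbook update above.

Hb prediction inverts the fitted curve: the estimate for a new feature value
is the argmin over the training Hb range of |f(h) - feature|, found on a
dense grid and polished locally. Ties (the non-monotone case) resolve to the
smallest Hb — the conservative choice for anemia screening — with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial import polynomial as P
from scipy.optimize import minimize_scalar

from .kalman import FeatureSeries

__all__ = [
    "PenaltyConfig",
    "PolynomialModel",
    "MatchingIssueWarning",
    "DivergenceError",
    "predict_feature",
    "cost",
    "cost_gradient",
    "fit_penalty_regression",
    "fit_linear_regression",
    "invert_model",
]


class MatchingIssueWarning(UserWarning):
    """The fitted curve maps one feature value to several Hb levels."""


class DivergenceError(RuntimeError):
    """Gradient descent failed to make progress; try a smaller learning rate."""


@dataclass
class PenaltyConfig:
    """Hyperparameters of the penalized fit.

    Defaults are the raw-scale protocol values: order 4, penalty coefficients
    c = (1, 10, 20, 30) rising with the order, learning rate alpha = 1e-11
    (sized for features in 8-bit intensity units and Hb in g/dL, where h^4
    reaches ~1e5), penalty parameter lambda = 1e-12, and termination when two
    successive costs differ by less than 1e-6.

    ``standardize=True`` fits in standardized (h, x) coordinates — useful on
    toy problems where a much larger alpha then converges in few iterations —
    and back-transforms, so reported coefficients are always in raw units.
    """

    order: int = 4
    c: tuple[float, ...] = (1.0, 10.0, 20.0, 30.0)
    lam: float = 1e-12
    alpha: float = 1e-11
    tol: float = 1e-6
    max_iter: int = 5_000_000
    init_seed: int = 0
    standardize: bool = False

    def validate(self) -> None:
        if self.order < 1:
            raise ValueError(f"polynomial order must be >= 1, got {self.order}")
        if len(self.c) != self.order:
            raise ValueError(
                f"need {self.order} penalty coefficients c_1..c_{self.order}, "
                f"got {len(self.c)}"
            )
        if any(ci < 0 for ci in self.c):
            raise ValueError("penalty coefficients must be >= 0")
        if any(b < a for a, b in zip(self.c, self.c[1:])):
            warnings.warn(
                "penalty coefficients are not nondecreasing with order; "
                "higher-order terms usually deserve the larger penalty",
                stacklevel=3,
            )
        if self.lam < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")
        if self.alpha <= 0 or self.tol <= 0:
            raise ValueError("alpha and tol must be positive")

    @property
    def c_full(self) -> np.ndarray:
        """Penalty coefficients including the implicit c_0 = 0."""
        return np.concatenate([[0.0], np.asarray(self.c, dtype=float)])


@dataclass
class PolynomialModel:
    """Fitted polynomial feature-vs-Hb curve.

    ``coeffs`` are a_0..a_n in raw units (feature units per (g/dL)^i);
    ``fit_report`` records iterations, final cost, convergence and the
    initialization seed.
    """

    coeffs: np.ndarray
    fit_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 1 or len(self.coeffs) < 2:
            raise ValueError("coeffs must be a 1-D array a_0..a_n with n >= 1")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("model coefficients must be finite")

    @property
    def order(self) -> int:
        return len(self.coeffs) - 1

    def __call__(self, h):
        return predict_feature(self, h)


def predict_feature(model: PolynomialModel, h):
    """Evaluate f(h) = sum a_i h^i (Horner form). Scalar in, scalar out."""
    out = P.polyval(np.asarray(h, dtype=float), model.coeffs)
    return float(out) if np.isscalar(h) or np.ndim(h) == 0 else out


def _series_arrays(series: FeatureSeries | None) -> tuple[np.ndarray, np.ndarray]:
    if series is None:
        return np.empty(0), np.empty(0)
    return series.hb, series.values


def cost(model: PolynomialModel, series: FeatureSeries | None, cfg: PenaltyConfig) -> float:
    """Penalized cost E = alpha * SSE + lambda * sum_{i>=1} c_i a_i^2.

    Uses the filtered values when the series carries them, the raw values
    otherwise. ``series=None`` evaluates the penalty term alone.
    """
    h, x = _series_arrays(series)
    resid = P.polyval(h, model.coeffs) - x
    return float(cfg.alpha * np.sum(resid**2) + cfg.lam * _penalty(model.coeffs, cfg))


def _penalty(coeffs: np.ndarray, cfg: PenaltyConfig) -> float:
    c = cfg.c_full
    m = min(len(c), len(coeffs))
    return float(np.sum(c[:m] * coeffs[:m] ** 2))


def cost_gradient(
    model: PolynomialModel, series: FeatureSeries | None, cfg: PenaltyConfig
) -> np.ndarray:
    """Analytic gradient of the cost:

    dE/da_0 = 2 alpha sum_k (f(h_k) - x_k)
    dE/da_i = 2 alpha sum_k (f(h_k) - x_k) h_k^i + 2 lambda c_i a_i,  i >= 1
    """
    h, x = _series_arrays(series)
    a = model.coeffs
    resid = P.polyval(h, a) - x
    V = np.vander(h, N=len(a), increasing=True) if len(h) else np.empty((0, len(a)))
    g = 2.0 * cfg.alpha * (V.T @ resid)
    c = np.zeros(len(a))
    m = min(len(cfg.c_full), len(a))
    c[:m] = cfg.c_full[:m]
    return g + 2.0 * cfg.lam * c * a


def _gd_core(G, b, sq, a, cpen, alpha, lam, tol, max_iter):
    """Backtracking gradient descent on the quadratic cost.

    E(a) = alpha * (a'Ga - 2b'a + sq) + lam * sum(cpen * a^2); the Gram form
    makes each iteration O(n^2) regardless of the sample count.
    Returns (a, E, accepted_iterations, converged, halvings).
    """
    eta = 1.0
    halvings = 0
    E_prev = alpha * (a @ (G @ a) - 2.0 * (b @ a) + sq) + lam * np.sum(cpen * a * a)
    it = 0
    converged = False
    while it < max_iter:
        g = 2.0 * alpha * (G @ a - b) + 2.0 * lam * cpen * a
        a_new = a - eta * g
        E_new = alpha * (a_new @ (G @ a_new) - 2.0 * (b @ a_new) + sq) + lam * np.sum(
            cpen * a_new * a_new
        )
        if not np.isfinite(E_new) or E_new > E_prev:
            eta *= 0.5
            halvings += 1
            if eta < 1e-300:
                return a, E_prev, it, False, halvings
            continue
        it += 1
        delta = E_prev - E_new
        a = a_new
        E_prev = E_new
        # relative stop: the cost's absolute scale is set by alpha and the
        # feature units, so "successive costs differ by less than tol" is
        # read as a fractional change
        if delta <= tol * max(abs(E_new), 1e-300):
            converged = True
            break
    return a, E_prev, it, converged, halvings


try:  # compile the hot loop when numba is available; semantics are identical
    from numba import njit

    _gd_core_jit = njit(cache=False)(_gd_core)
except ImportError:  # pragma: no cover
    _gd_core_jit = _gd_core


def fit_penalty_regression(series: FeatureSeries, cfg: PenaltyConfig | None = None) -> PolynomialModel:
    """Fit the penalized polynomial by gradient descent.

    Initialization: a_0 is the first value of the (filtered) feature data;
    a_1..a_n are drawn uniformly from [0, 1] under ``cfg.init_seed``.
    Iterates until two successive costs differ by less than ``cfg.tol`` or
    ``cfg.max_iter`` is reached; the fit_report records which.
    """
    if cfg is None:
        cfg = PenaltyConfig()
    cfg.validate()
    h = np.asarray(series.hb, dtype=float)
    x = np.asarray(series.values, dtype=float)
    n = cfg.order
    if len(h) < n + 1:
        warnings.warn(
            f"only {len(h)} samples for a degree-{n} fit; the problem is underdetermined",
            stacklevel=2,
        )

    if cfg.standardize:
        mh, mx = float(np.mean(h)), float(np.mean(x))
        sh = float(np.std(h, ddof=1)) if len(h) > 1 else 1.0
        sx = float(np.std(x, ddof=1)) if len(x) > 1 else 1.0
        sh, sx = sh or 1.0, sx or 1.0
        hf, xf = (h - mh) / sh, (x - mx) / sx
    else:
        hf, xf = h, x

    rng = np.random.default_rng(cfg.init_seed)
    a0 = np.empty(n + 1)
    a0[0] = xf[0]
    a0[1:] = rng.uniform(0.0, 1.0, size=n)

    V = np.vander(hf, N=n + 1, increasing=True)
    G = V.T @ V
    bb = V.T @ xf
    sq = float(xf @ xf)

    a, E, iters, converged, halvings = _gd_core_jit(
        G, bb, sq, a0.copy(), cfg.c_full, cfg.alpha, cfg.lam, cfg.tol, cfg.max_iter
    )
    if not converged and iters < cfg.max_iter:
        raise DivergenceError(
            "gradient descent could not reduce the cost even at vanishing step "
            "length; use a smaller learning rate alpha"
        )
    if not np.all(np.isfinite(a)) or E > 1e12:
        raise DivergenceError(
            f"fit diverged (cost {E:.3g}); use a smaller learning rate alpha"
        )

    if cfg.standardize:
        inner = P.Polynomial([-mh / sh, 1.0 / sh])
        total = P.Polynomial([0.0])
        for i, ai in enumerate(a):
            total = total + ai * inner**i
        raw = sx * total.coef
        raw = np.pad(raw, (0, n + 1 - len(raw)))
        raw[0] += mx
    else:
        raw = a

    report = {
        "iterations": int(iters),
        "final_cost": float(E),
        "converged": bool(converged),
        "step_halvings": int(halvings),
        "init_seed": cfg.init_seed,
        "standardized": cfg.standardize,
    }
    return PolynomialModel(coeffs=raw, fit_report=report)


def fit_linear_regression(series: FeatureSeries) -> PolynomialModel:
    """Closed-form least-squares line (baseline regressor, order 1)."""
    h = np.asarray(series.hb, dtype=float)
    x = np.asarray(series.values, dtype=float)
    if len(h) < 2 or np.ptp(h) == 0:
        raise ValueError("linear regression needs >= 2 samples with distinct Hb")
    coeffs = P.polyfit(h, x, 1)
    return PolynomialModel(coeffs=coeffs, fit_report={"method": "closed_form_ols"})


def invert_model(
    model: PolynomialModel,
    feature: float,
    h_range: tuple[float, float],
    grid_points: int = 10_000,
    tie_tol: float = 1e-9,
) -> float:
    """Estimate Hb from a feature value by inverting the fitted curve.

    Returns argmin over h in [h_lo, h_hi] of |f(h) - feature|, located on a
    dense grid then refined within the winning grid cell. If several
    separated grid minima tie within ``tie_tol``, the smallest Hb is returned
    and a :class:`MatchingIssueWarning` is issued.
    """
    h_lo, h_hi = float(h_range[0]), float(h_range[1])
    if not np.isfinite(h_lo) or not np.isfinite(h_hi) or h_lo >= h_hi:
        raise ValueError(f"invalid Hb range [{h_lo}, {h_hi}]")
    grid = np.linspace(h_lo, h_hi, grid_points)
    d = np.abs(P.polyval(grid, model.coeffs) - feature)
    dmin = d.min()
    tied = np.flatnonzero(d <= dmin + tie_tol)
    # separated runs of tied indices = distinct candidate roots
    if len(tied) > 1 and np.any(np.diff(tied) > 1):
        warnings.warn(
            f"matching issue: feature {feature:g} fits {int(np.sum(np.diff(tied) > 1)) + 1} "
            "separate Hb regions equally well; returning the smallest (most "
            "conservative for anemia screening)",
            MatchingIssueWarning,
            stacklevel=2,
        )
    idx = int(tied[0])
    lo = grid[max(idx - 1, 0)]
    hi = grid[min(idx + 1, grid_points - 1)]
    if hi > lo:
        res = minimize_scalar(
            lambda hh: (P.polyval(hh, model.coeffs) - feature) ** 2,
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-12},
        )
        if res.fun <= (d[idx] ** 2) + tie_tol:
            return float(min(max(res.x, h_lo), h_hi))
    return float(grid[idx])


def unpenalized(cfg: PenaltyConfig) -> PenaltyConfig:
    """Convenience: the same configuration with the penalty switched off."""
    return replace(cfg, lam=0.0)
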