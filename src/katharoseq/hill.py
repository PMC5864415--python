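"""Allosteric sigmoidal (Hill) dose-response fitting.

The model is

    y(x) = Ymax * x^h / (K^h + x^h),        x >= 0, K > 0, h > 0,

with ``y`` a target composition in [0, 1], ``x`` either input cells or read
depth, ``K`` the half-saturation constant (the x at which y = Ymax/2) and
``h`` the Hill coefficient.  In cells-vs-composition fits K is read as the
background contamination load of the whole pipeline in cell equivalents:
a sample that starts with K cells of real material yields reads that are
half signal, half contaminant.  In reads-vs-composition fits, K (at
Ymax = 1, the read count where half of the reads are the expected target)
is a natural sample-exclusion threshold.

:class:`HillCurveModel` is a scikit-learn regressor; the module-level
functions (:func:`fit_hill`, :func:`hill_curve`, :func:`solve_two_point`,
:func:`invert_hill`, :func:`r_squared`) are the thin functional surface
over it.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DegenerateFitError, InsufficientPointsError

H_BOUNDS = (0.1, 10.0)
_TOL = 1e-8


def hill_curve(x, ymax: float, k_half: float, h: float):
    """Evaluate the Hill curve; accepts scalars or arrays, vectorized.

    Strictly increasing on x > 0, with y(0) = 0 and y -> ymax as x -> inf.
    """
    if not (k_half > 0 and h > 0 and ymax > 0):
        raise DegenerateFitError(
            f"invalid Hill parameters: ymax={ymax}, k_half={k_half}, h={h}"
        )
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0):
        raise ValueError("x must be non-negative")
    with np.errstate(over="ignore"):
        r = (xa / k_half) ** h
        y = ymax * r / (1.0 + r)
    y = np.where(np.isinf(r), ymax, y)
    return float(y) if np.isscalar(x) or xa.ndim == 0 else y


def solve_two_point(
    x1: float, y1: float, x2: float, y2: float, ymax: float = 1.0
) -> Tuple[float, float]:
    """Closed-form (k_half, h) through two points at a fixed Ymax.

    With r(y) = y/(ymax - y):  h = ln(r(y2)/r(y1)) / ln(x2/x1) and
    k_half = x1 * r(y1)^(-1/h).  The returned curve passes exactly through
    both points.
    """
    if not (0 < x1 < x2):
        raise DegenerateFitError(f"need 0 < x1 < x2, got x1={x1}, x2={x2}")
    if not (0 < y1 < y2 < ymax):
        raise DegenerateFitError(
            f"need 0 < y1 < y2 < ymax, got y1={y1}, y2={y2}, ymax={ymax}"
        )
    r1 = y1 / (ymax - y1)
    r2 = y2 / (ymax - y2)
    h = math.log(r2 / r1) / math.log(x2 / x1)
    k_half = x1 * r1 ** (-1.0 / h)
    return k_half, h


@dataclass(frozen=True)
class HillFit:
    """A fitted Hill curve.

    ``x_variable`` records whether x was input cells or read depth, which
    decides the interpretation of ``k_half`` (background cell load vs. read
    threshold).  ``converged`` is False when the fit was refused (no
    variance in y) or the optimizer did not meet its tolerance.
    """

    ymax: float
    k_half: float
    h: float
    r_squared: float
    n_points: int
    x_variable: str = "cells"
    converged: bool = True

    def __post_init__(self) -> None:
        if not (self.k_half > 0 and self.h > 0 and 0 < self.ymax <= 1):
            raise DegenerateFitError(
                f"invalid HillFit: ymax={self.ymax}, k_half={self.k_half}, h={self.h}"
            )

    def predict(self, x):
        return hill_curve(x, self.ymax, self.k_half, self.h)

    def invert(self, y: float) -> float:
        return invert_hill(self, y)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, payload: str) -> "HillFit":
        return cls(**json.loads(payload))


def invert_hill(fit: HillFit, y: float) -> float:
    """The x at which the fitted curve attains y, for 0 < y < Ymax.

    Closed form: x = k_half * (y / (ymax - y))^(1/h); at y = ymax/2 this is
    k_half itself.
    """
    if not (0 < y < fit.ymax):
        raise DegenerateFitError(
            f"invert_hill needs 0 < y < ymax={fit.ymax}, got y={y}"
        )
    return fit.k_half * (y / (fit.ymax - y)) ** (1.0 / fit.h)


def r_squared(points: Iterable[Tuple[float, float]], fit: HillFit) -> float:
    """Coefficient of determination 1 - SSres/SStot about the mean of y."""
    pts = np.asarray(list(points), dtype=float)
    if len(pts) < 2:
        raise InsufficientPointsError("r_squared needs at least 2 points")
    x, y = pts[:, 0], pts[:, 1]
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateFitError("zero total sum of squares (constant y)")
    ss_res = float(np.sum((y - fit.predict(x)) ** 2))
    return 1.0 - ss_res / ss_tot


class HillCurveModel(RegressorMixin, BaseEstimator):
    """Least-squares Hill curve regressor.

    Parameters
    ----------
    ymax_mode : {"free", "fixed_1"}, default "free"
        Whether the plateau Ymax is estimated (bounded by 1) or fixed at 1.
        The free mode needs >= 3 distinct x levels; fixed needs >= 2.
    x_variable : {"cells", "reads"}, default "cells"
        Label recorded in the fit; controls interpretation only.
    tol : float, default 1e-8
        Relative convergence tolerance passed to the optimizer.

    Attributes (after fit)
    ----------------------
    ymax_, k_half_, h_ : fitted parameters.
    r_squared_ : 1 - SSres/SStot (weighted when sample_weight given).
    converged_ : whether the optimizer met its tolerance.
    n_points_ : number of points used.

    Fitting is deterministic: the optimizer is initialized from the
    closed-form two-point solution through the mean y at the smallest and
    largest x levels (with a fixed fallback when those means are unusable).
    With exactly two distinct x levels and Ymax fixed, the closed form is
    the exact least-squares solution through the level means and is used
    directly.
    """

    def __init__(
        self,
        ymax_mode: str = "free",
        x_variable: str = "cells",
        tol: float = _TOL,
    ):
        self.ymax_mode = ymax_mode
        self.x_variable = x_variable
        self.tol = tol

    # -- sklearn plumbing --------------------------------------------------

    def _validate_xy(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single dose column")
            X = X[:, 0]
        elif X.ndim != 1:
            raise ValueError("X must be 1d or a single-column 2d array")
        y = np.asarray(y, dtype=float)
        if y.shape != X.shape:
            raise ValueError("X and y length mismatch")
        if np.any(X < 0):
            raise ValueError("doses must be non-negative")
        if np.any((y < 0) | (y > 1)):
            raise ValueError("responses must lie in [0, 1]")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite inputs")
        return X, y

    def fit(self, X, y, sample_weight=None):
        if self.ymax_mode not in ("free", "fixed_1"):
            raise ValueError(f"unknown ymax_mode {self.ymax_mode!r}")
        x, yv = self._validate_xy(X, y)
        if sample_weight is None:
            w = np.ones_like(yv)
        else:
            w = np.asarray(sample_weight, dtype=float)
            if w.shape != yv.shape or np.any(w < 0):
                raise ValueError("bad sample_weight")
        min_levels = 2 if self.ymax_mode == "fixed_1" else 3
        levels = np.unique(x)
        if len(levels) < min_levels:
            raise InsufficientPointsError(
                f"ymax_mode={self.ymax_mode!r} needs >= {min_levels} distinct "
                f"x levels, got {len(levels)}"
            )
        self.n_points_ = len(x)
        if np.ptp(yv) == 0.0:
            # no variance in the response: the fit is refused, not faked
            self.ymax_ = min(max(float(yv[0]), 1e-9), 1.0)
            pos_levels = levels[levels > 0]
            self.k_half_ = float(np.median(pos_levels)) if len(pos_levels) else 1.0
            self.h_ = 1.0
            self.converged_ = False
            self.r_squared_ = float("nan")
            return self

        ymax0, k0, h0 = self._initialize(x, yv, levels)

        if self.ymax_mode == "fixed_1" and len(levels) == 2:
            k, h, converged = self._two_level_fixed(x, yv, w, levels, (k0, h0))
            self.ymax_ = 1.0
        elif self.ymax_mode == "fixed_1":
            theta0 = np.array([k0, h0])
            lo = np.array([1e-9, H_BOUNDS[0]])
            hi = np.array([np.inf, H_BOUNDS[1]])
            res = least_squares(
                lambda t: np.sqrt(w) * (hill_curve(x, 1.0, t[0], t[1]) - yv),
                np.clip(theta0, lo, hi),
                bounds=(lo, hi),
                xtol=self.tol,
                ftol=self.tol,
                gtol=self.tol,
            )
            k, h = float(res.x[0]), float(res.x[1])
            converged = bool(res.success)
            self.ymax_ = 1.0
        else:
            theta0 = np.array([ymax0, k0, h0])
            lo = np.array([1e-9, 1e-9, H_BOUNDS[0]])
            hi = np.array([1.0, np.inf, H_BOUNDS[1]])
            res = least_squares(
                lambda t: np.sqrt(w) * (hill_curve(x, t[0], t[1], t[2]) - yv),
                np.clip(theta0, lo, hi),
                bounds=(lo, hi),
                xtol=self.tol,
                ftol=self.tol,
                gtol=self.tol,
            )
            self.ymax_ = float(res.x[0])
            k, h = float(res.x[1]), float(res.x[2])
            converged = bool(res.success)

        self.k_half_ = k
        self.h_ = h
        self.converged_ = converged
        pred = hill_curve(x, self.ymax_, self.k_half_, self.h_)
        ss_res = float(np.sum(w * (yv - pred) ** 2))
        ss_tot = float(np.sum(w * (yv - np.average(yv, weights=w)) ** 2))
        self.r_squared_ = 1.0 - ss_res / ss_tot
        return self

    @staticmethod
    def _initialize(x, y, levels):
        """Deterministic start: two-point closed form through the mean y at
        the smallest positive and largest x levels, else a neutral guess."""
        pos = levels[levels > 0]
        ymax0 = min(1.0, max(float(np.max(y)) * 1.05, 1e-6))
        k0 = float(np.median(pos)) if len(pos) else 1.0
        h0 = 1.0
        if len(pos) >= 2:
            x_lo, x_hi = float(pos[0]), float(pos[-1])
            y_lo = float(np.mean(y[x == x_lo]))
            y_hi = float(np.mean(y[x == x_hi]))
            if 0 < y_lo < y_hi < ymax0:
                try:
                    k0, h0 = solve_two_point(x_lo, y_lo, x_hi, y_hi, ymax0)
                    h0 = min(max(h0, H_BOUNDS[0]), H_BOUNDS[1])
                except DegenerateFitError:
                    pass
        return ymax0, k0, h0

    @staticmethod
    def _two_level_fixed(x, y, w, levels, fallback):
        """Exact least-squares through the (weighted) level means.

        With two free parameters and two distinct doses, the weighted
        least-squares Hill curve interpolates the weighted mean response at
        each dose; the closed form gives it without iteration.
        """
        x1, x2 = float(levels[0]), float(levels[1])
        y1 = float(np.average(y[x == x1], weights=w[x == x1]))
        y2 = float(np.average(y[x == x2], weights=w[x == x2]))
        try:
            if x1 == 0:
                raise DegenerateFitError("zero dose level")
            k, h = solve_two_point(x1, y1, x2, y2, 1.0)
            if H_BOUNDS[0] <= h <= H_BOUNDS[1]:
                return k, h, True
        except DegenerateFitError:
            pass
        k0, h0 = fallback
        res = least_squares(
            lambda t: np.sqrt(w) * (hill_curve(x, 1.0, t[0], t[1]) - y),
            np.array([max(k0, 1e-6), min(max(h0, H_BOUNDS[0]), H_BOUNDS[1])]),
            bounds=(np.array([1e-9, H_BOUNDS[0]]), np.array([np.inf, H_BOUNDS[1]])),
            xtol=_TOL,
            ftol=_TOL,
            gtol=_TOL,
        )
        return float(res.x[0]), float(res.x[1]), bool(res.success)

    def predict(self, X):
        check_is_fitted(self, "k_half_")
        X = np.asarray(X, dtype=float)
        x = X[:, 0] if X.ndim == 2 else X
        return hill_curve(x, self.ymax_, self.k_half_, self.h_)

    def invert(self, y: float) -> float:
        check_is_fitted(self, "k_half_")
        return invert_hill(self.to_fit(), y)

    def to_fit(self) -> HillFit:
        check_is_fitted(self, "k_half_")
        return HillFit(
            ymax=self.ymax_,
            k_half=self.k_half_,
            h=self.h_,
            r_squared=self.r_squared_,
            n_points=self.n_points_,
            x_variable=self.x_variable,
            converged=self.converged_,
        )


def fit_hill(
    points: Sequence[Tuple[float, float]],
    ymax_mode: str = "free",
    weights: Optional[Sequence[float]] = None,
    x_variable: str = "cells",
) -> HillFit:
    """Fit the Hill curve to (x, y) points; thin wrapper over
    :class:`HillCurveModel`."""
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InsufficientPointsError("points must be (x, y) pairs")
    model = HillCurveModel(ymax_mode=ymax_mode, x_variable=x_variable)
    model.fit(pts[:, 0], pts[:, 1], sample_weight=weights)
    return model.to_fit()
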