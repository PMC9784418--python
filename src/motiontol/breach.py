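"""Breaching-point regression: D95% vs added motion, and volume trends.

Corrected PTV D95% fractions observed at the added-motion design points
(0, 5, 10, 20 mm) are fitted with an ordinary-least-squares quadratic
``y = a + b x + c x^2`` (unconstrained intercept).  The first and second
breaching points are the smallest non-negative added motions at which the
fitted curve crosses 95% and 90% of prescription.  Across a cohort, the
breaching points are regressed on log tumor volume, which captures the
level-off of motion tolerance with increasing tumor size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "QuadraticFit",
    "Breach",
    "BreachResult",
    "LogVolumeFit",
    "fit_quadratic",
    "solve_breach",
    "fit_log_volume",
    "summarize_cohort",
]


@dataclass
class QuadraticFit:
    a: float  # intercept, fraction of prescription
    b: float  # per mm
    c: float  # per mm^2
    r2: float
    x: np.ndarray | None = None
    y: np.ndarray | None = None

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a + self.b * x + self.c * x * x


@dataclass
class Breach:
    """One threshold crossing: added motion in mm, or not found."""

    x: float | None
    at_zero: bool = False
    extrapolated: bool = False

    @property
    def found(self) -> bool:
        return self.x is not None


@dataclass
class BreachResult:
    x95: Breach
    x90: Breach


@dataclass
class LogVolumeFit:
    """OLS of breach (mm) on ln(volume), with a linear-in-volume comparison."""

    slope: float
    intercept: float
    r2_log: float
    r2_linear: float
    n: int

    def predict(self, volumes) -> np.ndarray:
        return self.intercept + self.slope * np.log(np.asarray(volumes, dtype=float))


def _ols_r2(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return beta, r2


def fit_quadratic(x, y) -> QuadraticFit:
    """OLS quadratic fit of D95% fractions on added motion (mm)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-D arrays")
    if len(np.unique(x)) < 3:
        raise ValueError("quadratic fit needs at least 3 distinct x values")
    X = np.column_stack([np.ones_like(x), x, x * x])
    beta, r2 = _ols_r2(X, y)
    return QuadraticFit(a=float(beta[0]), b=float(beta[1]), c=float(beta[2]), r2=r2, x=x, y=y)


def solve_breach(fit: QuadraticFit, threshold: float, design_max: float = 20.0) -> Breach:
    """Smallest non-negative added motion where the fit crosses ``threshold``.

    Returns 0.0 (flagged ``at_zero``) when the fitted curve already sits
    below the threshold at zero added motion, and a not-found result when
    the quadratic never reaches it for non-negative motion.  Roots beyond
    the fitted design range are flagged ``extrapolated``.
    """
    if fit.a < threshold:
        return Breach(0.0, at_zero=True)
    if abs(fit.c) < 1e-15:
        if abs(fit.b) < 1e-15:
            return Breach(None)
        root = (threshold - fit.a) / fit.b
        roots = [root]
    else:
        disc = fit.b * fit.b - 4.0 * fit.c * (fit.a - threshold)
        if disc < 0:
            return Breach(None)
        sq = math.sqrt(disc)
        roots = [(-fit.b - sq) / (2 * fit.c), (-fit.b + sq) / (2 * fit.c)]
    nonneg = [r for r in roots if r >= -1e-9]
    if not nonneg:
        return Breach(None)
    x = max(0.0, min(nonneg))
    return Breach(float(x), extrapolated=x > design_max)


def fit_log_volume(volumes, breaches) -> LogVolumeFit:
    """Regress breaching points on ln(volume); also fit linear-in-volume.

    Pairs whose breach was not found are dropped; at least 3 usable pairs
    are required.
    """
    v = np.asarray(volumes, dtype=float)
    b = np.array([np.nan if x is None else float(x) for x in breaches])
    if v.shape != b.shape:
        raise ValueError("volumes and breaches must have matching lengths")
    keep = np.isfinite(b)
    v, b = v[keep], b[keep]
    if len(v) < 3:
        raise ValueError("need at least 3 usable (volume, breach) pairs")
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    beta, r2_log = _ols_r2(np.column_stack([np.ones_like(v), np.log(v)]), b)
    _, r2_lin = _ols_r2(np.column_stack([np.ones_like(v), v]), b)
    return LogVolumeFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        r2_log=r2_log,
        r2_linear=r2_lin,
        n=len(v),
    )


def summarize_cohort(values_by_group: dict[str, list[float | None]]) -> dict[str, dict]:
    """Per-group mean and sample SD (n-1), not-found entries excluded.

    Returns ``{group: {"mean": m, "sd": s, "n": k}}``; the SD is ``None``
    for groups with fewer than two usable members.
    """
    out: dict[str, dict] = {}
    for group, values in values_by_group.items():
        arr = np.array([v for v in values if v is not None], dtype=float)
        if len(arr) == 0:
            out[group] = {"mean": None, "sd": None, "n": 0}
        else:
            out[group] = {
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if len(arr) > 1 else None,
                "n": int(len(arr)),
            }
    return out
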