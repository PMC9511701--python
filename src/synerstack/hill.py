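"""Four-parameter logistic (Hill) monotherapy dose-response curves.

The 4PL model used throughout is

    y(x) = (Emin + Emax * t) / (1 + t),    t = (x / m) ** lam

which is algebraically identical to the conventional form
``Emin + (Emax - Emin) * t / (1 + t)``.  ``m`` is the dose producing the
midpoint effect between ``Emin`` and ``Emax`` (the relative IC50) and
``lam`` is the shape (slope) parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["HillCurve", "hill_response", "fit_hill", "ic50", "DegenerateCurveError"]


class DegenerateCurveError(ValueError):
    """Raised when an operation needs a non-flat dose-response curve."""


@dataclass(frozen=True)
class HillCurve:
    """Fitted 4PL monotherapy curve.

    Attributes
    ----------
    emin, emax : float
        Minimum and maximum drug response (inhibition fraction scale).
    m : float
        Dose producing the midpoint effect (relative IC50), ``> 0``.
    lam : float
        Shape/slope parameter, ``> 0``.
    degenerate : bool
        True for flat fits, where ``emin == emax`` and ``m``/``lam`` are
        placeholders that evaluate to the flat value.
    """

    emin: float
    emax: float
    m: float
    lam: float
    degenerate: bool = False

    def response(self, dose):
        return hill_response(dose, self)


def hill_response(dose, curve: HillCurve):
    """Evaluate a 4PL curve at nonnegative dose(s)."""
    x = np.asarray(dose, dtype=float)
    if np.any(x < 0):
        raise ValueError("doses must be nonnegative")
    if curve.degenerate:
        out = np.full_like(x, curve.emin, dtype=float)
        return float(out) if np.isscalar(dose) or x.ndim == 0 else out
    with np.errstate(divide="ignore"):
        t = np.power(x / curve.m, curve.lam)
    y = (curve.emin + curve.emax * t) / (1.0 + t)
    # x == 0 with lam > 0 gives t = 0 exactly; inf t (huge doses) -> emax
    y = np.where(np.isinf(t), curve.emax, y)
    return float(y) if np.isscalar(dose) or x.ndim == 0 else y


def _residuals(params, x, y):
    emin, emax, log_m, log_lam = params
    t = np.power(x / np.exp(log_m), np.exp(log_lam))
    return (emin + emax * t) / (1.0 + t) - y


def _jacobian(params, x, y):
    emin, emax, log_m, log_lam = params
    m, lam = np.exp(log_m), np.exp(log_lam)
    lr = np.log(x / m)
    t = np.exp(lam * lr)
    inv = 1.0 / (1.0 + t)
    core = (emax - emin) * inv * inv * t
    return np.column_stack([inv, t * inv, -lam * core, lam * lr * core])


_FLAT_TOL = 1e-12


def fit_hill(doses, responses, *, n_starts: int = 4) -> HillCurve:
    """Least-squares 4PL fit on a monotherapy series.

    Uses a fixed multi-start grid of (m, lam) initial values (log-spaced m
    across the tested dose range, lam in {0.5, 1, 2, 4}) and keeps the
    lowest-SSE solution, so the result is deterministic for given inputs.
    Constant responses yield a degenerate (flat) curve.

    Parameters
    ----------
    doses, responses : array-like
        Paired monotherapy observations; at least 3 distinct positive doses.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("doses and responses must be 1-D and the same length")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("doses must be finite and nonnegative")
    pos = x > 0
    if len(np.unique(x[pos])) < 3:
        raise ValueError("need at least 3 distinct positive doses to fit a Hill curve")

    if np.ptp(y) < _FLAT_TOL:
        flat = float(np.mean(y))
        return HillCurve(flat, flat, float(np.median(x[pos])), 1.0, degenerate=True)

    xp, yp = x[pos], y[pos]
    lo, hi = float(xp.min()), float(xp.max())
    m_bounds = (lo / 10.0, hi * 10.0)
    lam_bounds = (0.1, 20.0)
    y_lo, y_hi = float(y.min()), float(y.max())
    pad = 0.5 * (y_hi - y_lo) + 0.1

    m_starts = np.exp(np.linspace(np.log(lo), np.log(hi), 4))
    lam_starts = np.array([0.5, 1.0, 2.0, 4.0])

    # rank the fixed 4x4 start grid by initial SSE, polish the best few
    starts = [(float(m0), float(l0)) for m0 in m_starts for l0 in lam_starts]
    init_sse = [float(np.sum(_residuals([y_lo, y_hi, np.log(m0), np.log(l0)],
                                        xp, yp) ** 2)) for m0, l0 in starts]
    order = np.argsort(init_sse, kind="stable")[: max(1, n_starts)]

    bounds = (
        [y_lo - pad, y_lo - pad, np.log(m_bounds[0]), np.log(lam_bounds[0])],
        [y_hi + pad, y_hi + pad, np.log(m_bounds[1]), np.log(lam_bounds[1])],
    )
    best = None
    for i in order:
        m0, lam0 = starts[i]
        p0 = [y_lo, y_hi, np.log(m0), np.log(lam0)]
        try:
            sol = least_squares(_residuals, p0, jac=_jacobian, args=(xp, yp),
                                bounds=bounds, method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except ValueError:
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0] - 1e-15:
            best = (sse, sol.x)
    if best is None:  # pragma: no cover - bounds always admit the start
        raise RuntimeError("Hill fit failed for all starts")
    emin, emax, log_m, log_lam = best[1]
    if emin > emax:  # enforce Emin <= Emax by swapping (curve decreasing in t)
        emin, emax = emax, emin
    if abs(emax - emin) < 1e-9:
        flat = float(0.5 * (emin + emax))
        return HillCurve(flat, flat, float(np.exp(log_m)), 1.0, degenerate=True)
    return HillCurve(float(emin), float(emax), float(np.exp(log_m)), float(np.exp(log_lam)))


def ic50(curve: HillCurve, *, mode: str = "relative") -> float:
    """Dose of half-maximal effect.

    ``relative`` returns the midpoint dose ``m`` (response = (Emin+Emax)/2);
    ``absolute`` solves ``y(x) = 0.5`` on the response scale.
    """
    if curve.degenerate:
        raise DegenerateCurveError("IC50 undefined for a flat curve")
    if mode == "relative":
        return float(curve.m)
    if mode == "absolute":
        target = 0.5
        if not (min(curve.emin, curve.emax) < target < max(curve.emin, curve.emax)):
            raise DegenerateCurveError("response 0.5 not attained by this curve")
        # invert (emin + emax*t)/(1+t) = target  ->  t = (target-emin)/(emax-target)
        t = (target - curve.emin) / (curve.emax - target)
        return float(curve.m * t ** (1.0 / curve.lam))
    raise ValueError(f"unknown IC50 mode: {mode!r}")
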