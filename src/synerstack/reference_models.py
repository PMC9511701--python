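"""Synergy reference models: Bliss, HSA, Loewe, ZIP and a CSS-style score.

A reference model predicts the *expected* non-interacting response of a drug
pair at a dose combination; synergy is the (percentage-scaled) mean excess of
the observed response over that expectation across the positive-dose grid.
Responses are inhibition fractions (0 = no effect, 1 = full inhibition),
though values outside [0, 1] are tolerated and passed through.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hill import DegenerateCurveError, HillCurve, fit_hill, hill_response, ic50

__all__ = [
    "DoseResponseMatrix",
    "expected_bliss",
    "expected_hsa",
    "expected_loewe",
    "expected_zip",
    "summarize_synergy",
    "css_score",
    "score_matrix",
    "score_table",
    "SYNERGY_MODELS",
]

SYNERGY_MODELS = ("bliss", "hsa", "loewe", "zip")


@dataclass
class DoseResponseMatrix:
    """Observed responses of one drug pair on one cell line over a dose grid.

    ``d1``/``d2``/``y`` are flat, aligned arrays covering a rectangular grid
    (every (d1, d2) combination exactly once).  ``mono1``/``mono2`` are the
    monotherapy (dose, response) series for each drug.
    """

    drug1_id: str
    drug2_id: str
    cell_id: str
    d1: np.ndarray
    d2: np.ndarray
    y: np.ndarray
    mono1: tuple[np.ndarray, np.ndarray]
    mono2: tuple[np.ndarray, np.ndarray]
    _curves: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.d1 = np.asarray(self.d1, dtype=float)
        self.d2 = np.asarray(self.d2, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.d1.shape == self.d2.shape == self.y.shape):
            raise ValueError("d1, d2, y must be aligned 1-D arrays")
        self.validate_grid()

    def validate_grid(self):
        pairs = set(zip(self.d1.tolist(), self.d2.tolist()))
        u1, u2 = np.unique(self.d1), np.unique(self.d2)
        if len(pairs) != len(self.d1):
            raise ValueError("duplicate (d1, d2) grid points")
        if len(pairs) != len(u1) * len(u2):
            raise ValueError("dose grid is not rectangular")

    def curve(self, which: int, cache: dict | None = None) -> HillCurve:
        """Fitted monotherapy Hill curve for drug 1 or 2, memoized."""
        if which not in (1, 2):
            raise ValueError("which must be 1 or 2")
        if which not in self._curves:
            doses, resp = self.mono1 if which == 1 else self.mono2
            key = None
            if cache is not None:
                drug = self.drug1_id if which == 1 else self.drug2_id
                key = (drug, self.cell_id)
                if key in cache:
                    self._curves[which] = cache[key]
                    return self._curves[which]
            self._curves[which] = fit_hill(doses, resp)
            if cache is not None:
                cache[key] = self._curves[which]
        return self._curves[which]


def _check_finite(*vals):
    for v in vals:
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite input")


def expected_bliss(y1, y2):
    """Bliss independence expectation ``y1 + y2 - y1*y2`` (symmetric)."""
    _check_finite(y1, y2)
    return y1 + y2 - y1 * y2


def expected_hsa(y1, y2):
    """Highest-single-agent expectation ``max(y1, y2)``."""
    _check_finite(y1, y2)
    return np.maximum(y1, y2)


def expected_loewe(x1, x2, curve: HillCurve):
    """Loewe additivity expectation: the 4PL evaluated at total dose x1+x2.

    Uses a single (Emin, Emax, m, lam) parameter set; which drug supplies it
    is chosen by the caller (see :func:`summarize_synergy`).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.any(x1 < 0) or np.any(x2 < 0):
        raise ValueError("doses must be nonnegative")
    return hill_response(x1 + x2, curve)


def _unit_hill(x, m, lam):
    with np.errstate(divide="ignore"):
        t = np.power(np.asarray(x, dtype=float) / m, lam)
    return np.where(np.isinf(t), 1.0, t / (1.0 + t))


def expected_zip(x1, x2, curve1: HillCurve, curve2: HillCurve):
    """ZIP expectation: Bliss combination of the two unit-interval Hill terms."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.any(x1 < 0) or np.any(x2 < 0):
        raise ValueError("doses must be nonnegative")
    for c in (curve1, curve2):
        if c.degenerate:
            return np.full(np.broadcast(x1, x2).shape, c.emin) if x1.ndim else c.emin
    h1 = _unit_hill(x1, curve1.m, curve1.lam)
    h2 = _unit_hill(x2, curve2.m, curve2.lam)
    out = h1 + h2 - h1 * h2
    return float(out) if out.ndim == 0 else out


def _loewe_curve(matrix: DoseResponseMatrix, attribution: str, cache=None) -> HillCurve:
    c1, c2 = matrix.curve(1, cache), matrix.curve(2, cache)
    if attribution == "more_potent":
        if c1.degenerate:
            return c2
        if c2.degenerate:
            return c1
        return c1 if c1.m <= c2.m else c2
    if attribution == "drug1":
        return c1
    if attribution == "drug2":
        return c2
    if attribution == "mean":
        if c1.degenerate or c2.degenerate:
            return c1 if c2.degenerate else c2
        return HillCurve(
            0.5 * (c1.emin + c2.emin),
            0.5 * (c1.emax + c2.emax),
            float(np.sqrt(c1.m * c2.m)),
            0.5 * (c1.lam + c2.lam),
        )
    raise ValueError(f"unknown Loewe attribution: {attribution!r}")


def expected_matrix(matrix: DoseResponseMatrix, model: str, *,
                    loewe_attribution: str = "more_potent", cache=None) -> np.ndarray:
    """Per-grid-point expected response under a reference model."""
    d1, d2 = matrix.d1, matrix.d2
    if model == "bliss" or model == "hsa":
        y1 = hill_response(d1, matrix.curve(1, cache))
        y2 = hill_response(d2, matrix.curve(2, cache))
        return expected_bliss(y1, y2) if model == "bliss" else expected_hsa(y1, y2)
    if model == "loewe":
        return expected_loewe(d1, d2, _loewe_curve(matrix, loewe_attribution, cache))
    if model == "zip":
        return expected_zip(d1, d2, matrix.curve(1, cache), matrix.curve(2, cache))
    raise ValueError(f"unknown reference model: {model!r}")


def summarize_synergy(matrix: DoseResponseMatrix, model: str, *,
                      loewe_attribution: str = "more_potent", cache=None) -> float:
    """Matrix-level synergy score for one reference model.

    Computes the observed-minus-expected residual at every grid point where
    both doses are positive and returns 100 x the arithmetic mean, so a
    constant +0.05 excess response scores 5.0.
    """
    if model not in SYNERGY_MODELS:
        raise ValueError(f"unknown reference model: {model!r}")
    mask = (matrix.d1 > 0) & (matrix.d2 > 0)
    if not mask.any():
        raise ValueError("no grid points with both doses positive")
    expected = expected_matrix(matrix, model, loewe_attribution=loewe_attribution,
                               cache=cache)
    return float(100.0 * np.mean(matrix.y[mask] - expected[mask]))


def _nearest_dose(doses: np.ndarray, target: float) -> float:
    # ties broken toward the lower dose
    doses = np.sort(np.unique(doses))
    gaps = np.abs(doses - target)
    return float(doses[np.argmin(gaps)])  # argmin takes the first (lower) tie


def _auc_along_axis(free_doses, responses, lo, hi, n_grid=256):
    """Normalized log10-dose AUC of a 4PL fitted to (free_doses, responses)."""
    curve = fit_hill(free_doses, responses)
    grid = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    vals = hill_response(grid, curve)
    span = np.log10(hi) - np.log10(lo)
    return float(np.trapezoid(vals, np.log10(grid)) / span)


def css_score(matrix: DoseResponseMatrix, *, cache=None) -> float:
    """Combination sensitivity (CSS-style) score on a 0-100 scale.

    For each orientation the partner drug is pinned at its tested dose
    closest to its IC50; a 4PL is fitted to the combination responses along
    the free axis and integrated over log10 dose between the smallest and
    largest positive tested doses, normalized by the log-dose span and
    scaled by 100.  The score is the mean over the two orientations.  This
    is a documented variant of the DrugComb CSS, not a numerical clone.
    """
    results = []
    for free, part in ((1, 2), (2, 1)):
        part_curve = matrix.curve(part, cache)
        try:
            target = ic50(part_curve)
        except DegenerateCurveError:
            raise DegenerateCurveError(
                f"CSS undefined: drug {part} monotherapy curve is flat")
        part_d = matrix.d2 if part == 2 else matrix.d1
        free_d = matrix.d1 if free == 1 else matrix.d2
        pinned = _nearest_dose(part_d[part_d > 0], target)
        sel = (part_d == pinned) & (free_d > 0)
        xs, ys = free_d[sel], matrix.y[sel]
        if len(np.unique(xs)) < 3:
            raise ValueError("need >=3 distinct positive doses along the free axis")
        results.append(_auc_along_axis(xs, ys, xs.min(), xs.max()))
    return float(100.0 * np.mean(results))


def score_matrix(matrix: DoseResponseMatrix, models=None, *, cache=None,
                 loewe_attribution: str = "more_potent") -> dict:
    """All requested scores for one matrix, as a flat record dict."""
    models = list(models) if models is not None else list(SYNERGY_MODELS) + ["css"]
    rec = {"drug1": matrix.drug1_id, "drug2": matrix.drug2_id, "cell": matrix.cell_id}
    for model in models:
        if model == "css":
            rec["score_css"] = css_score(matrix, cache=cache)
        else:
            rec[f"score_{model}"] = summarize_synergy(
                matrix, model, loewe_attribution=loewe_attribution, cache=cache)
    return rec


def score_table(matrices, models=None, *, loewe_attribution: str = "more_potent",
                progress: bool = False) -> pd.DataFrame:
    """Score a collection of matrices; monotherapy fits are cached per (drug, cell)."""
    cache: dict = {}
    rows = [score_matrix(m, models, cache=cache, loewe_attribution=loewe_attribution)
            for m in matrices]
    df = pd.DataFrame(rows)
    if df.duplicated(subset=["drug1", "drug2", "cell"]).any():
        raise ValueError("duplicate (drug pair, cell) keys in scored table")
    return df
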