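"""Four-parameter logistic (4PL) dose-response fitting and censored IC50.

The model is ``r(x) = bottom + (top - bottom) / (1 + (x / c)^h)`` with
dose x > 0, inflection c > 0 and Hill slope h.  With h > 0 the curve
decreases with dose (response at x -> 0 approaches ``top``), the usual
shape for a viability readout normalized to untreated control = 100 %.

The reported IC50 is the *absolute* IC50 — the dose at which the fitted
curve crosses 50 % of control — not the relative EC50 (the inflection),
because responses are anchored to untreated = 100 % and the quantity of
interest is loss of half the control signal.  When the curve does not
cross 50 % inside the tested dose range the IC50 is censored and
reported as "<min_dose" or ">max_dose".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import gmean

from .errors import FitError

__all__ = [
    "FourPLParams",
    "IC50Result",
    "four_pl",
    "fit_four_pl",
    "ic50_from_fit",
    "fit_dose_response_table",
]


def four_pl(x, bottom: float, top: float, hill: float, inflection: float):
    """Evaluate the 4PL curve at dose(s) ``x``."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / inflection) ** hill)


@dataclass(frozen=True)
class FourPLParams:
    bottom: float
    top: float
    hill: float
    inflection: float

    def __iter__(self):
        return iter((self.bottom, self.top, self.hill, self.inflection))


def _model_logc(x, bottom, top, hill, log_c):
    return bottom + (top - bottom) / (1.0 + (x / np.exp(log_c)) ** hill)


def fit_four_pl(doses, responses) -> FourPLParams:
    """Unweighted least-squares 4PL fit.

    Initialization is deterministic: top = max response, bottom = min
    response, inflection = geometric mean of the doses, and |hill| = 1
    with the sign chosen so the model's direction matches the empirical
    response trend against log dose.  The inflection is optimized on the
    log scale to keep it positive.  The returned parameters are
    normalized so that top > bottom (the 4PL has an exact
    (bottom, top, h) <-> (top, bottom, -h) symmetry).

    Raises
    ------
    FitError
        Fewer than 4 distinct positive doses, flat responses, or
        optimizer non-convergence (with diagnostics in the message).
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitError("doses and responses must be 1-D and equally long")
    if np.unique(x).size < 4:
        raise FitError(f"need >= 4 distinct doses, got {np.unique(x).size}")
    if (x <= 0).any():
        raise FitError("doses must be strictly positive")
    if not np.isfinite(y).all():
        raise FitError("responses must be finite")
    if np.ptp(y) == 0:
        raise FitError("responses are constant; inflection undefined")

    slope = np.polyfit(np.log(x), y, 1)[0]
    hill0 = 1.0 if slope < 0 else -1.0  # h > 0 <=> decreasing with dose
    p0 = [float(y.min()), float(y.max()), hill0, float(np.log(gmean(x)))]
    try:
        popt, _ = curve_fit(_model_logc, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    bottom, top, hill, log_c = (float(v) for v in popt)
    if bottom > top:
        bottom, top, hill = top, bottom, -hill
    return FourPLParams(bottom, top, hill, float(np.exp(log_c)))


@dataclass(frozen=True)
class IC50Result:
    """An absolute IC50, possibly censored against the tested dose range.

    ``value`` is the crossing dose when it lies inside the tested range,
    else ``None`` with ``censored`` set to ``"below_min"``/``"above_max"``
    and ``bound`` the corresponding range limit.
    """

    value: float | None
    censored: str | None = None
    bound: float | None = None

    def __str__(self) -> str:
        if self.censored == "below_min":
            return f"<{self.bound:g}"
        if self.censored == "above_max":
            return f">{self.bound:g}"
        return f"{self.value:g}"


def ic50_from_fit(params: FourPLParams, dose_range) -> IC50Result:
    """Dose where the fitted curve crosses 50 % of control.

    ``dose_range`` is ``(min_dose, max_dose)`` of the tested doses.  A
    crossing outside the range — or a curve that never reaches 50 within
    its asymptotes — is censored toward the side where the curve would
    cross, following its direction.
    """
    lo, hi = (float(v) for v in dose_range)
    if not (0 < lo < hi):
        raise FitError(f"invalid dose range ({lo}, {hi})")
    b, t, h, c = params.bottom, params.top, params.hill, params.inflection
    if h == 0:
        raise FitError("hill = 0; curve is flat")
    if not (b < 50.0 < t):
        # 50 outside the asymptotes: censor toward where the curve heads.
        # h > 0: response falls with dose, so a curve entirely above 50
        # would cross beyond the top of the range and one entirely below
        # 50 crossed before its bottom; h < 0 mirrors this.
        curve_above = min(b, t) >= 50.0
        if (curve_above and h > 0) or (not curve_above and h < 0):
            return IC50Result(None, "above_max", hi)
        return IC50Result(None, "below_min", lo)
    x50 = c * ((t - 50.0) / (50.0 - b)) ** (1.0 / h)
    if x50 < lo:
        return IC50Result(None, "below_min", lo)
    if x50 > hi:
        return IC50Result(None, "above_max", hi)
    return IC50Result(float(x50))


def fit_dose_response_table(table: pd.DataFrame) -> pd.DataFrame:
    """Fit one 4PL curve per cell line from a long-format table.

    Input columns: ``cell_line, dose_uM, response_pct`` and optionally
    ``replicate``; replicate responses are averaged per dose before the
    (unweighted) fit.  Output: one row per cell line with the fitted
    parameters and the (possibly censored) IC50 as text.
    """
    rows = []
    for line, grp in table.groupby("cell_line", sort=True):
        per_dose = (
            grp.groupby("dose_uM", sort=True)["response_pct"].mean().reset_index()
        )
        doses = per_dose["dose_uM"].to_numpy(dtype=float)
        params = fit_four_pl(doses, per_dose["response_pct"].to_numpy(dtype=float))
        ic50 = ic50_from_fit(params, (doses.min(), doses.max()))
        rows.append(
            (line, params.bottom, params.top, params.hill, params.inflection,
             str(ic50))
        )
    return pd.DataFrame(
        rows, columns=["cell_line", "bottom", "top", "hill", "inflection", "ic50"]
    )
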