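"""Four-parameter logistic (4PL) dose-response fitting and compound triage.

The model is

    y(x) = bottom + (top - bottom) / (1 + (x / ic50) ** hill)

with ``x`` the compound concentration in molar units. With ``hill > 0`` the
response falls from ``top`` (no compound) to ``bottom`` (saturating
inhibition); ``ic50`` is the concentration of half-maximal effect and
``pic50 = -log10(ic50)`` its log-molar potency.

Fitting is deterministic: starting values come from a fixed heuristic on the
data (response extremes, the concentration bracketing half-response, the sign
of the response trend) and the optimizer is a bounded trust-region least
squares. IC50 values beyond the tested concentration range are reported as
right-censored bounds ("> max tested") rather than as point estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "four_pl",
    "fit_4pl",
    "pic50",
    "DoseResponseFit",
    "TriageThresholds",
    "CompoundTriage",
    "triage",
]


def four_pl(x, top, bottom, ic50, hill):
    """Evaluate the 4PL curve at concentrations ``x`` (molar)."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


def pic50(ic50_molar: float, precision: int | None = None) -> float:
    """Negative log10 of an IC50 given in molar units.

    Parameters
    ----------
    ic50_molar:
        IC50 in molar. Must be strictly positive.
    precision:
        If given, round the result to this many decimal places (potencies are
        conventionally reported to 1-2 d.p.).
    """
    if not np.isfinite(ic50_molar) or ic50_molar <= 0:
        raise ValueError(f"ic50 must be a positive finite molar value, got {ic50_molar!r}")
    value = -math.log10(ic50_molar)
    if precision is not None:
        value = round(value, precision)
    return value


@dataclass
class DoseResponseFit:
    """Result of a 4PL fit.

    ``ic50`` is in molar. ``censored`` marks fits whose IC50 lies above the
    highest tested concentration; ``ic50_bound`` then holds that bound and the
    potency should be read as "> bound". ``hill_raw`` preserves the slope sign
    before canonicalization (inhibition curves are canonicalized to
    ``top >= bottom`` with positive hill).
    """

    top: float
    bottom: float
    ic50: float
    hill: float
    rss: float
    converged: bool
    censored: bool = False
    ic50_bound: float | None = None
    hill_raw: float | None = None
    conc_min: float = float("nan")
    conc_max: float = float("nan")
    n_points: int = 0

    @property
    def pic50(self) -> float:
        """Log-molar potency; NaN for unconverged or censored fits."""
        if not self.converged or self.censored or not np.isfinite(self.ic50):
            return float("nan")
        return -math.log10(self.ic50)

    def predict(self, x):
        return four_pl(x, self.top, self.bottom, self.ic50, self.hill)


def _failed_fit(conc: np.ndarray, resp: np.ndarray) -> DoseResponseFit:
    level = float(np.mean(resp)) if resp.size else float("nan")
    return DoseResponseFit(
        top=level,
        bottom=level,
        ic50=float("nan"),
        hill=float("nan"),
        rss=float(np.sum((resp - level) ** 2)) if resp.size else float("nan"),
        converged=False,
        conc_min=float(conc.min()),
        conc_max=float(conc.max()),
        n_points=int(resp.size),
    )


def fit_4pl(concentrations, responses, weights=None) -> DoseResponseFit:
    """Least-squares 4PL fit of responses against molar concentrations.

    Replicates are passed as repeated concentration values and fitted jointly.
    At least 4 distinct concentrations are required. Degenerate data (constant
    responses) or optimizer failure yields a fit flagged ``converged=False``
    instead of an exception.
    """
    conc = np.asarray(concentrations, dtype=float).ravel()
    resp = np.asarray(responses, dtype=float).ravel()
    if conc.shape != resp.shape:
        raise ValueError("concentrations and responses must have equal length")
    if np.any(conc <= 0) or not np.all(np.isfinite(conc)):
        raise ValueError("concentrations must be positive and finite (molar)")
    if not np.all(np.isfinite(resp)):
        raise ValueError("responses must be finite")
    distinct = np.unique(conc)
    if distinct.size < 4:
        raise ValueError(f"need >= 4 distinct concentrations, got {distinct.size}")
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float).ravel())
        if w.shape != resp.shape:
            raise ValueError("weights must match responses")
    else:
        w = None

    cmin, cmax = float(distinct.min()), float(distinct.max())
    if np.ptp(resp) == 0:
        return _failed_fit(conc, resp)

    # Deterministic initialization: extremes for the asymptotes, the
    # concentration whose mean response is nearest half-maximum for ic50,
    # slope sign from the response trend along concentration.
    top0 = float(resp.max())
    bot0 = float(resp.min())
    means = np.array([resp[conc == c].mean() for c in distinct])
    half = (top0 + bot0) / 2.0
    ic50_0 = float(distinct[np.argmin(np.abs(means - half))])
    trend = np.polyfit(np.log10(distinct), means, 1)[0]
    hill0 = 1.0 if trend <= 0 else -1.0

    lo = [bot0 - abs(top0 - bot0), bot0 - abs(top0 - bot0), math.log10(cmin / 100.0), -10.0]
    hi = [top0 + abs(top0 - bot0), top0 + abs(top0 - bot0), math.log10(cmax * 100.0), 10.0]

    def resid(p):
        t, b, log_ic50, h = p
        r = four_pl(conc, t, b, 10.0 ** log_ic50, h) - resp
        return r * w if w is not None else r

    x0 = np.array([top0, bot0, math.log10(ic50_0), hill0])
    x0 = np.clip(x0, lo, hi)
    try:
        sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15)
    except Exception:
        return _failed_fit(conc, resp)
    if not sol.success or not np.all(np.isfinite(sol.x)):
        return _failed_fit(conc, resp)

    top, bottom, log_ic50, hill = (float(v) for v in sol.x)
    hill_raw = hill
    if top < bottom:  # canonicalize so inhibition potency is positive
        top, bottom = bottom, top
        hill = -hill
    ic50 = 10.0 ** log_ic50
    rss = float(np.sum(sol.fun ** 2))

    fit = DoseResponseFit(
        top=top,
        bottom=bottom,
        ic50=ic50,
        hill=hill,
        rss=rss,
        converged=True,
        hill_raw=hill_raw,
        conc_min=cmin,
        conc_max=cmax,
        n_points=int(resp.size),
    )
    # Right-censor potencies beyond the tested range: the data contain no
    # information to place the inflection, so report "> max tested".
    if ic50 > cmax:
        fit.censored = True
        fit.ic50_bound = cmax
    return fit


@dataclass
class TriageThresholds:
    """Potency/selectivity cutoffs for compound triage.

    ``active_ic50`` is the activity potency required to call a compound
    active (10 µM default; a stricter 5 µM confirmation mode is common).
    ``selectivity`` is the minimum viability-IC50 / activity-IC50 ratio.
    """

    active_ic50: float = 10e-6
    selectivity: float = 5.0


@dataclass
class CompoundTriage:
    activity: DoseResponseFit
    viability: DoseResponseFit | None
    active: bool
    selectivity_ratio: float
    selective: bool
    thresholds: TriageThresholds = field(default_factory=TriageThresholds)


def triage(
    activity_fit: DoseResponseFit,
    viability_fit: DoseResponseFit | None,
    thresholds: TriageThresholds | None = None,
) -> CompoundTriage:
    """Classify a compound from its activity and viability fits.

    A compound is *active* when its activity fit converged in-range with
    IC50 at or below the potency threshold. The selectivity ratio is
    viability IC50 over activity IC50; a censored viability fit contributes
    its bound (a conservative lower limit on the true ratio), and an absent
    viability fit means no cytotoxicity was observed in range, treated as
    censored at the activity fit's top tested concentration.
    """
    thresholds = thresholds or TriageThresholds()
    active = (
        activity_fit.converged
        and not activity_fit.censored
        and activity_fit.ic50 <= thresholds.active_ic50
    )

    if viability_fit is None:
        viab_value = activity_fit.conc_max
    elif viability_fit.censored or not viability_fit.converged:
        viab_value = viability_fit.ic50_bound or viability_fit.conc_max
    else:
        viab_value = viability_fit.ic50

    if active and np.isfinite(viab_value):
        ratio = viab_value / activity_fit.ic50
    else:
        ratio = float("nan")
    selective = bool(active and np.isfinite(ratio) and ratio >= thresholds.selectivity)
    return CompoundTriage(
        activity=activity_fit,
        viability=viability_fit,
        active=bool(active),
        selectivity_ratio=float(ratio),
        selective=selective,
        thresholds=thresholds,
    )
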