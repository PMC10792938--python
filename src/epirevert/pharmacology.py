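"""Three-parameter log-logistic dose-response fitting and Loewe synergy.

The single-agent model is the "log(inhibitor) vs. response, three
parameters" curve with Hill slope 1:

    R(d) = bottom + (top - bottom) / (1 + d / ic50)

with viability in percent of untreated (DMSO-normalised) and dose in nM.
Combination effects are judged against Loewe additivity: the expected effect
E of a dose pair (dA, dB) solves dA/A(E) + dB/B(E) = 1, where A(E) and B(E)
are the single-agent doses producing effect E.  Synergy is reported as
observed - expected viability, so negative values mean a synergistic
viability reduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize


class FitFailureError(RuntimeError):
    """Dose-response fit did not converge or produced an implausible IC50."""


@dataclass
class DoseResponseCurve:
    """A fitted (or exact) three-parameter log-logistic curve."""

    drug: str
    ic50: float  # nM
    top: float  # viability % at dose 0
    bottom: float  # viability % at saturating dose
    hill: float = 1.0
    doses: np.ndarray = field(default_factory=lambda: np.empty(0))
    responses: np.ndarray = field(default_factory=lambda: np.empty(0))
    residual_sd: float = np.nan

    def __post_init__(self):
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")
        if self.top <= self.bottom:
            raise ValueError("top must exceed bottom")

    def __call__(self, dose):
        d = np.asarray(dose, dtype=float)
        resp = self.bottom + (self.top - self.bottom) / (1 + (d / self.ic50) ** self.hill)
        return float(resp) if resp.ndim == 0 else resp

    def inverse(self, effect):
        """Dose producing a given effect (viability %); inf/0 outside range."""
        e = np.asarray(effect, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = (self.top - e) / (e - self.bottom)
            d = self.ic50 * np.maximum(ratio, 0.0) ** (1.0 / self.hill)
        return float(d) if d.ndim == 0 else d


def fit_ic50(
    doses,
    responses,
    drug: str = "",
    fix_hill: bool = True,
) -> DoseResponseCurve:
    """Least-squares fit of (ic50, top, bottom) on the log-dose axis.

    Requires >= 4 dose points spanning the transition.  With
    ``fix_hill=False`` a fourth parameter (Hill slope) is fitted as well.
    Raises FitFailureError on non-convergence, a degenerate (flat) response,
    or an IC50 more than 100x outside the tested dose range.
    """
    d = np.asarray(doses, dtype=float)
    r = np.asarray(responses, dtype=float)
    if len(d) != len(r):
        raise ValueError("doses and responses must have equal length")
    if len(d) < 4:
        raise ValueError("need at least 4 dose points")
    if np.any(d < 0):
        raise ValueError("doses must be >= 0")
    if np.ptp(r) < 1e-9:
        raise FitFailureError("responses are constant; no transition to fit")

    top0, bot0 = float(r.max()), float(r.min())
    mid = (top0 + bot0) / 2
    pos = d[d > 0]
    ic0 = float(pos[np.argmin(np.abs(r[d > 0] - mid))]) if len(pos) else 1.0

    def model3(dose, log_ic50, top, bottom):
        return bottom + (top - bottom) / (1 + dose / np.exp(log_ic50))

    def model4(dose, log_ic50, top, bottom, hill):
        return bottom + (top - bottom) / (1 + (dose / np.exp(log_ic50)) ** hill)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            if fix_hill:
                popt, _ = optimize.curve_fit(
                    model3, d, r, p0=[np.log(ic0), top0, bot0], maxfev=20_000
                )
                log_ic50, top, bottom = popt
                hill = 1.0
            else:
                popt, _ = optimize.curve_fit(
                    model4, d, r, p0=[np.log(ic0), top0, bot0, 1.0], maxfev=20_000
                )
                log_ic50, top, bottom, hill = popt
    except RuntimeError as exc:
        raise FitFailureError(f"dose-response fit did not converge: {exc}") from exc

    ic50 = float(np.exp(log_ic50))
    if len(pos) and not (pos.min() / 100 <= ic50 <= pos.max() * 100):
        raise FitFailureError(
            f"fitted IC50 {ic50:.3g} nM lies outside the tested dose range x100"
        )
    if top <= bottom:
        raise FitFailureError("fit collapsed (top <= bottom)")
    curve = DoseResponseCurve(
        drug=drug,
        ic50=ic50,
        top=float(top),
        bottom=float(bottom),
        hill=float(hill),
        doses=d,
        responses=r,
    )
    curve.residual_sd = float(np.std(r - curve(d), ddof=min(len(d) - 1, 3)))
    return curve


def loewe_expected(
    curve_a: DoseResponseCurve,
    curve_b: DoseResponseCurve,
    dose_a: float,
    dose_b: float,
) -> float:
    """Loewe-additive expected viability for a dose pair.

    Solves dA/A(E) + dB/B(E) = 1 for the effect E by bisection on the
    interval of effects attainable by both curves; with one dose zero the
    expression reduces to the single-agent curve.  An effect outside the
    attainable range is clamped with a warning.
    """
    if dose_a < 0 or dose_b < 0:
        raise ValueError("doses must be >= 0")
    if dose_a == 0 and dose_b == 0:
        return (curve_a.top + curve_b.top) / 2
    if dose_b == 0:
        return float(curve_a(dose_a))
    if dose_a == 0:
        return float(curve_b(dose_b))

    lo = max(curve_a.bottom, curve_b.bottom)
    hi = min(curve_a.top, curve_b.top)
    if hi <= lo:
        warnings.warn("curves share no attainable effect range; clamping")
        return lo

    def f(e):
        return dose_a / curve_a.inverse(e) + dose_b / curve_b.inverse(e) - 1.0

    eps = (hi - lo) * 1e-12
    f_lo, f_hi = f(lo + eps), f(hi - eps)
    if f_hi <= 0:  # even near-zero combined dose exceeds... effect ~ top
        warnings.warn("Loewe effect clamped at the top of the attainable range")
        return hi
    if f_lo >= 0:
        warnings.warn("Loewe effect clamped at the bottom of the attainable range")
        return lo
    e = optimize.brentq(f, lo + eps, hi - eps, xtol=1e-10)
    return float(e)


@dataclass
class SynergySurface:
    """Observed vs Loewe-expected viability on a dose grid."""

    doses_a: np.ndarray
    doses_b: np.ndarray
    observed: np.ndarray  # shape (len(doses_a), len(doses_b))
    loewe: np.ndarray
    synergy: np.ndarray  # observed - loewe; 0 on the single-agent margins

    @property
    def mean_synergy(self) -> float:
        return float(np.mean(self.synergy))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, da in enumerate(self.doses_a):
            for j, db in enumerate(self.doses_b):
                rows.append(
                    {
                        "dose_a": da,
                        "dose_b": db,
                        "observed": self.observed[i, j],
                        "loewe_expected": self.loewe[i, j],
                        "synergy": self.synergy[i, j],
                    }
                )
        return pd.DataFrame(rows)


def synergy_matrix(
    doses_a,
    doses_b,
    observed,
    curve_a: DoseResponseCurve,
    curve_b: DoseResponseCurve,
) -> SynergySurface:
    """Synergy = observed - Loewe-expected viability per grid cell.

    The grid must be complete (no NaN cells).  Margin cells (either dose 0)
    define the single agents and carry synergy 0 by convention.
    """
    da = np.asarray(doses_a, dtype=float)
    db = np.asarray(doses_b, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if obs.shape != (len(da), len(db)):
        raise ValueError("observed grid shape does not match the dose axes")
    if np.any(np.isnan(obs)):
        where = [(int(i), int(j)) for i, j in np.argwhere(np.isnan(obs))]
        raise ValueError(f"observed surface has missing cells at {where}")
    loewe = np.empty_like(obs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, a in enumerate(da):
            for j, b in enumerate(db):
                loewe[i, j] = loewe_expected(curve_a, curve_b, a, b)
    syn = obs - loewe
    syn[da == 0, :] = 0.0
    syn[:, db == 0] = 0.0
    return SynergySurface(da, db, obs, loewe, syn)
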