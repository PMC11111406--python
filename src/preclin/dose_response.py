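"""Constrained dose-response fitting and pharmacology summaries.

This module covers four related tasks:

* robust four-parameter logistic (4PL) fits of pooled-screen viability
  curves, with the asymptote constraints used for multiplexed barcode
  screens (upper asymptote pinned near 1, lower asymptote in [0, 1.01],
  direction of the curve not enforced);
* per-curve summaries: normalized area under the fitted curve over the
  tested log10-dose window (AUC, so an untreated flat curve scores 1) and
  the dose at which the fitted curve crosses 50% viability (IC50, defined
  only when the curve actually drops below 50%);
* a three-parameter sigmoid exposure-response model (top fixed at 1 on the
  vehicle-normalized scale) for PK-PD EC50 estimation;
* non-compartmental exposure metrics (trapezoidal AUC, terminal half-life,
  tissue-to-blood exposure ratio Kp) and tumour-volume response metrics
  (percent change from baseline, best response, exponential growth rate).

The logistic is parameterized as

    f(x) = b + (a - b) / (1 + exp(s * ln(x / ec50)))

with natural log in the exponent; ``s > 0`` gives viability decreasing
with dose.  Any other log base is absorbed into ``s``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "FourPLFit",
    "SigmoidFit",
    "ExposureSummary",
    "TumourResponse",
    "four_pl",
    "fit_4pl",
    "curve_auc",
    "curve_ic50",
    "fit_sigmoid_ec50",
    "exposure_metrics",
    "tumour_response",
]

# Asymptote bounds applied to every screen fit.
A_BOUNDS = (0.99, 1.01)
B_BOUNDS = (0.0, 1.01)
S_BOUNDS = (-30.0, 30.0)


def four_pl(x, a: float, b: float, s: float, ec50: float):
    """Four-parameter logistic viability at dose ``x`` (same units as ec50)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        return b + (a - b) / (1.0 + np.exp(s * np.log(x / ec50)))


@dataclass
class FourPLFit:
    """Fitted 4PL parameters plus the dose window they were fitted on."""

    a: float
    b: float
    s: float
    ec50: float
    converged: bool
    robust_fallback_used: bool
    dose_min: float
    dose_max: float

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.s, self.ec50)

    def __call__(self, x):
        return four_pl(x, *self.params)


def _residual_fn(log_doses: np.ndarray, viability: np.ndarray):
    def resid(theta):
        a, b, s, log_ec50 = theta
        with np.errstate(over="ignore"):
            pred = b + (a - b) / (1.0 + np.exp(s * (log_doses - log_ec50)))
        return pred - viability

    return resid


def fit_4pl(doses: Sequence[float], viability: Sequence[float]) -> FourPLFit:
    """Fit the constrained 4PL to (dose, viability-fraction) data.

    The optimizer is initialized at a = 1, b = 0.5, s = 1 and ec50 at the
    geometric centre of the tested doses.  If the plain least-squares fit
    fails to converge (or returns non-finite parameters), the fit is
    repeated with a soft-L1 robust loss starting from the failed fit's last
    iterate and ``robust_fallback_used`` is set.

    Raises ``ValueError`` for fewer than 4 distinct positive doses or
    all-NaN viabilities.
    """
    doses = np.asarray(doses, dtype=float)
    viability = np.asarray(viability, dtype=float)
    if doses.shape != viability.shape:
        raise ValueError("doses and viability must have the same length")
    keep = np.isfinite(doses) & np.isfinite(viability) & (doses > 0)
    doses, viability = doses[keep], viability[keep]
    if viability.size == 0:
        raise ValueError("no finite viability values to fit")
    if np.unique(doses).size < 4:
        raise ValueError("need at least 4 distinct positive doses")

    log_doses = np.log(doses)
    resid = _residual_fn(log_doses, viability)
    # Allow ec50 well outside the tested window so flat / shifted curves can
    # park it at a boundary instead of failing.
    log_lo, log_hi = log_doses.min() - np.log(1e4), log_doses.max() + np.log(1e4)
    lower = [A_BOUNDS[0], B_BOUNDS[0], S_BOUNDS[0], log_lo]
    upper = [A_BOUNDS[1], B_BOUNDS[1], S_BOUNDS[1], log_hi]
    x0 = np.array([1.0, 0.5, 1.0, float(np.median(log_doses))])

    res = optimize.least_squares(resid, x0, bounds=(lower, upper), method="trf")
    robust = False
    ok = bool(res.success) and np.all(np.isfinite(res.x))
    if not ok:
        start = res.x if np.all(np.isfinite(res.x)) else x0
        res = optimize.least_squares(
            resid, start, bounds=(lower, upper), method="trf",
            loss="soft_l1", f_scale=0.1,
        )
        robust = True
        ok = bool(res.success) and np.all(np.isfinite(res.x))

    a, b, s, log_ec50 = res.x
    return FourPLFit(
        a=float(a), b=float(b), s=float(s), ec50=float(np.exp(log_ec50)),
        converged=ok, robust_fallback_used=robust,
        dose_min=float(doses.min()), dose_max=float(doses.max()),
    )


def _params_of(fit) -> tuple[float, float, float, float]:
    if hasattr(fit, "params"):
        return fit.params
    a, b, s, ec50 = fit
    return (float(a), float(b), float(s), float(ec50))


def curve_auc(fit, dose_min: Optional[float] = None,
              dose_max: Optional[float] = None) -> float:
    """Mean fitted viability over the tested log10-dose window.

    AUC = (1 / (log10 dmax - log10 dmin)) * int f(10^u) du, so a flat curve
    at viability 1 scores exactly 1 and lower curves score lower.  The
    integral is evaluated to absolute tolerance 1e-6.
    """
    a, b, s, ec50 = _params_of(fit)
    if dose_min is None:
        dose_min = fit.dose_min
    if dose_max is None:
        dose_max = fit.dose_max
    if not (0 < dose_min < dose_max):
        raise ValueError("need 0 < dose_min < dose_max")
    u0, u1 = np.log10(dose_min), np.log10(dose_max)
    val, _ = integrate.quad(
        lambda u: four_pl(10.0 ** u, a, b, s, ec50), u0, u1,
        epsabs=1e-8, epsrel=1e-8, limit=200,
    )
    return float(val / (u1 - u0))


def curve_ic50(fit, dose_min: Optional[float] = None,
               dose_max: Optional[float] = None) -> Optional[float]:
    """Smallest dose in the window where the fitted curve equals 0.5.

    Returns ``None`` (undefined, not an error) when the curve never crosses
    50% viability inside [dose_min, dose_max].  Uses the closed-form
    inversion of the logistic; the 4PL is monotone in dose so the crossing,
    when it exists, is unique.
    """
    a, b, s, ec50 = _params_of(fit)
    if dose_min is None:
        dose_min = fit.dose_min
    if dose_max is None:
        dose_max = fit.dose_max
    if s == 0:
        return None
    # f(x) = 0.5  <=>  exp(s ln(x/ec50)) = (a - 0.5) / (0.5 - b)
    num, den = a - 0.5, 0.5 - b
    if den == 0 or (num / den) <= 0:
        return None
    x = ec50 * (num / den) ** (1.0 / s)
    if not (dose_min <= x <= dose_max):
        return None
    return float(x)


# ---------------------------------------------------------------------------
# PK-PD exposure-response


@dataclass
class SigmoidFit:
    """Three-parameter sigmoid exposure-response fit, top fixed at 1."""

    bottom: float
    ec50: float
    hill: float
    converged: bool

    def __call__(self, conc):
        conc = np.asarray(conc, dtype=float)
        return self.bottom + (1.0 - self.bottom) / (
            1.0 + (conc / self.ec50) ** self.hill
        )


def fit_sigmoid_ec50(concentrations: Sequence[float],
                     responses: Sequence[float],
                     fix: str = "top") -> SigmoidFit:
    """Fit r(C) = bottom + (1 - bottom) / (1 + (C / EC50)^h).

    ``responses`` are fraction-of-vehicle (so the top plateau is 1 by
    construction and is fixed; ``fix='bottom'`` instead fixes bottom at 0
    and frees the top).  Requires >= 4 points spanning at least one decade
    of positive concentration.  A flat response profile returns an
    unconverged fit with ``ec50 = nan``.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if conc.size < 4 or np.log10(conc.max() / conc.min()) < 1.0:
        raise ValueError("need >= 4 concentrations spanning >= 1 log10 unit")
    if np.ptp(resp) < 1e-9:
        return SigmoidFit(bottom=float(resp.mean()), ec50=float("nan"),
                          hill=float("nan"), converged=False)

    log_c = np.log(conc)
    if fix == "top":
        def resid(theta):
            bottom, log_ec50, h = theta
            pred = bottom + (1.0 - bottom) / (1.0 + np.exp(h * (log_c - log_ec50)))
            return pred - resp
        lower = [0.0, log_c.min() - np.log(1e4), 0.05]
        upper = [1.0, log_c.max() + np.log(1e4), 10.0]
        x0 = [0.0, float(np.median(log_c)), 1.0]
    elif fix == "bottom":
        def resid(theta):
            top, log_ec50, h = theta
            pred = top / (1.0 + np.exp(h * (log_c - log_ec50)))
            return pred - resp
        lower = [0.0, log_c.min() - np.log(1e4), 0.05]
        upper = [2.0, log_c.max() + np.log(1e4), 10.0]
        x0 = [1.0, float(np.median(log_c)), 1.0]
    else:
        raise ValueError("fix must be 'top' or 'bottom'")

    res = optimize.least_squares(resid, x0, bounds=(lower, upper), method="trf")
    p0, log_ec50, h = res.x
    bottom = p0 if fix == "top" else 0.0
    return SigmoidFit(bottom=float(bottom), ec50=float(np.exp(log_ec50)),
                      hill=float(h), converged=bool(res.success))


@dataclass
class ExposureSummary:
    """Non-compartmental exposure metrics for one tissue profile."""

    auc_0_t: float            # concentration * time (e.g. nM*h)
    half_life: float          # h; nan when no declining terminal phase
    kp: float = float("nan")  # AUC_tissue / AUC_blood, when blood provided
    ec50_pd: float = float("nan")


def _terminal_half_life(times: np.ndarray, conc: np.ndarray,
                        min_points: int = 3) -> float:
    """Half-life from log-linear regression on the terminal declining phase.

    The terminal phase is the longest suffix of strictly declining, positive
    concentrations; at least ``min_points`` points are required.
    """
    pos = conc > 0
    start = len(conc) - 1
    while start > 0 and pos[start - 1] and conc[start - 1] > conc[start]:
        start -= 1
    tail_t, tail_c = times[start:], conc[start:]
    if tail_c.size < min_points or np.any(tail_c <= 0):
        return float("nan")
    slope, _ = np.polyfit(tail_t, np.log(tail_c), 1)
    if slope >= 0:
        return float("nan")
    return float(np.log(2.0) / -slope)


def exposure_metrics(times: Sequence[float], concentrations: Sequence[float],
                     blood_concentrations: Optional[Sequence[float]] = None,
                     ) -> ExposureSummary:
    """Trapezoidal AUC, terminal half-life and (optionally) Kp.

    ``times`` must be sorted ascending with >= 2 points.  When a matched
    blood profile is given, Kp = AUC_tissue / AUC_blood.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 timepoints")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be sorted strictly ascending")
    auc = float(np.trapezoid(c, t))
    t_half = _terminal_half_life(t, c)
    kp = float("nan")
    if blood_concentrations is not None:
        auc_blood = float(np.trapezoid(np.asarray(blood_concentrations, float), t))
        kp = auc / auc_blood if auc_blood > 0 else float("nan")
    return ExposureSummary(auc_0_t=auc, half_life=t_half, kp=kp)


# ---------------------------------------------------------------------------
# Tumour volume response


@dataclass
class TumourResponse:
    pct_change: np.ndarray   # % volume change from baseline at each timepoint
    best_response: float     # minimum % change over follow-up
    growth_rate: float       # per-day exponential rate (slope of ln V vs t)


def tumour_response(times_days: Sequence[float],
                    volumes: Sequence[float]) -> TumourResponse:
    """Percent change from baseline, best response, exponential growth rate.

    The first volume is the baseline and must be positive.  The growth rate
    is the least-squares slope of ln(volume) against time (per day).
    """
    t = np.asarray(times_days, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if v.size == 0 or not np.isfinite(v[0]) or v[0] <= 0:
        raise ValueError("missing or non-positive baseline volume")
    pct = 100.0 * (v - v[0]) / v[0]
    if np.any(v <= 0):
        rate = float("nan")
    else:
        rate = float(np.polyfit(t, np.log(v), 1)[0])
    return TumourResponse(pct_change=pct, best_response=float(pct.min()),
                          growth_rate=rate)
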