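"""Kinetic and dose-response quantification of receptor endocytosis.

Per-frame endosome counts, normalized per cell, rise along a sigmoid time
course upon agonist stimulation:

    y(t) = bottom + (top - bottom) / (1 + 10^((t_half - t) * slope))

whose parameters summarize the response: Emax = top (maximal number of
vesicles per cell), t_half (minutes to half-maximal response) and slope
(steepness). Maximal responses across agonist concentrations follow a
four-parameter logistic on log10 dose,

    E(d) = e_min + (e_max - e_min) / (1 + 10^((log10 EC50 - log10 d) * h)),

reported as pEC50 = -log10 EC50. Conditions where no sigmoid response can
be established are flagged "n.d." (not detected).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

import pandas as pd

__all__ = [
    "KineticCurve",
    "SigmoidFit",
    "DoseResponseFit",
    "SigmoidRegressor",
    "DoseResponseRegressor",
    "counts_per_cell",
    "sigmoid",
    "fit_sigmoid",
    "fit_dose_response",
    "compare_fits",
]

_EXP_CLIP = 300.0  # 10**x overflow guard


@dataclass(frozen=True)
class KineticCurve:
    """Per-timepoint endosome counts normalized per cell."""

    times: np.ndarray
    counts_per_cell: np.ndarray
    n_cells: int = 1

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=np.float64)
        y = np.asarray(self.counts_per_cell, dtype=np.float64)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("times and counts_per_cell must be equal-length 1D")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("counts_per_cell must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "counts_per_cell", y)


@dataclass(frozen=True)
class SigmoidFit:
    """Result of a sigmoid time-course fit.

    ``detected`` is False ("n.d.") when the optimizer fails, the fitted
    span (top - bottom) is below the minimum response, or r^2 is too low.
    """

    bottom: float
    top: float
    t_half: float
    slope: float
    se_bottom: float
    se_top: float
    se_t_half: float
    se_slope: float
    r_squared: float
    detected: bool
    message: str = ""


@dataclass(frozen=True)
class DoseResponseFit:
    """Result of a four-parameter logistic dose-response fit."""

    pec50: float
    e_min: float
    e_max: float
    hill_slope: float
    se_pec50: float
    se_e_min: float
    se_e_max: float
    se_hill_slope: float
    r_squared: float
    converged: bool
    bell_flag: bool
    message: str = ""


def counts_per_cell(
    counts: Sequence[float],
    n_cells: int,
    times: Sequence[float] | None = None,
    frame_interval: float = 1.0,
) -> KineticCurve:
    """Divide per-frame detection counts by the number of cells in the field."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    counts = np.asarray(counts, dtype=np.float64)
    if times is None:
        times = np.arange(counts.size, dtype=np.float64) * frame_interval
    return KineticCurve(
        times=np.asarray(times, dtype=np.float64),
        counts_per_cell=counts / n_cells,
        n_cells=int(n_cells),
    )


def sigmoid(t, bottom: float, top: float, t_half: float, slope: float):
    """Sigmoid time course; equals (bottom+top)/2 at t = t_half."""
    t = np.asarray(t, dtype=np.float64)
    expo = np.clip((t_half - t) * slope, -_EXP_CLIP, _EXP_CLIP)
    out = bottom + (top - bottom) / (1.0 + 10.0**expo)
    return out if out.ndim else float(out)


def _logistic_dose(x, e_min: float, e_max: float, log_ec50: float, hill: float):
    """4PL on x = log10(dose)."""
    x = np.asarray(x, dtype=np.float64)
    expo = np.clip((log_ec50 - x) * hill, -_EXP_CLIP, _EXP_CLIP)
    out = e_min + (e_max - e_min) / (1.0 + 10.0**expo)
    return out if out.ndim else float(out)


def _r_squared(y: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return float("nan")
    return 1.0 - ss_res / ss_tot


def _midrange_crossing(t: np.ndarray, y: np.ndarray) -> float:
    """First time the curve crosses midway between its min and max."""
    mid = (y.min() + y.max()) / 2.0
    above = y >= mid
    idx = np.nonzero(above)[0]
    if idx.size == 0 or idx[0] == 0:
        return float(t[t.size // 2])
    i = idx[0]
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t[i])
    return float(t[i - 1] + (mid - y0) * (t[i] - t[i - 1]) / (y1 - y0))


class SigmoidRegressor(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of the endocytosis sigmoid time course.

    Parameters
    ----------
    min_span : float
        Minimum fitted response (top - bottom, vesicles/cell) for the
        condition to count as detected.
    min_r_squared : float
        Minimum r^2 for the condition to count as detected.
    max_slope : float
        Upper bound of the slope parameter (per-minute log units).

    Fitted attributes: ``bottom_``, ``top_``, ``t_half_``, ``slope_``,
    their standard errors ``se_*``, ``r_squared_`` and ``detected_``.
    """

    def __init__(
        self, min_span: float = 3.0, min_r_squared: float = 0.5, max_slope: float = 10.0
    ):
        self.min_span = min_span
        self.min_r_squared = min_r_squared
        self.max_slope = max_slope

    def fit(self, X, y) -> "SigmoidRegressor":
        t = np.asarray(X, dtype=np.float64).reshape(-1)
        y = np.asarray(y, dtype=np.float64).reshape(-1)
        if t.size != y.size:
            raise ValueError("X and y must have the same length")
        if t.size < 5:
            raise ValueError("need at least 5 timepoints to fit a sigmoid")

        # Reparametrize as (bottom, span, t_half, slope), span = top - bottom,
        # so the bounded optimizer enforces top >= bottom >= 0.
        def model(tt, bottom, span, t_half, slope):
            return sigmoid(tt, bottom, bottom + span, t_half, slope)

        t_lo, t_hi = float(t.min()) - 5.0, float(t.max()) + 5.0
        p0 = (
            max(float(y.min()), 0.0),
            max(float(y.max() - y.min()), 1e-6),
            _midrange_crossing(t, y),
            0.5,
        )
        bounds = ([0.0, 0.0, t_lo, 1e-6], [np.inf, np.inf, t_hi, self.max_slope])
        self.detected_ = False
        self.message_ = ""
        try:
            popt, pcov = optimize.curve_fit(
                model, t, y, p0=p0, bounds=bounds, maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
        except (RuntimeError, ValueError) as exc:
            self._set_failed(f"fit did not converge: {exc}")
            return self

        bottom, span, t_half, slope = popt
        se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
        # top = bottom + span: propagate the covariance of the sum.
        var_top = pcov[0, 0] + pcov[1, 1] + 2.0 * pcov[0, 1]
        self.bottom_ = float(bottom)
        self.top_ = float(bottom + span)
        self.t_half_ = float(t_half)
        self.slope_ = float(slope)
        self.se_bottom_ = float(se[0])
        self.se_top_ = float(np.sqrt(max(var_top, 0.0)))
        self.se_t_half_ = float(se[2])
        self.se_slope_ = float(se[3])
        pred = model(t, *popt)
        self.r_squared_ = _r_squared(y, pred)
        span_ok = span >= self.min_span
        r2_ok = np.isfinite(self.r_squared_) and self.r_squared_ >= self.min_r_squared
        self.detected_ = bool(span_ok and r2_ok)
        if not span_ok:
            self.message_ = f"response span {span:.2f} < {self.min_span} vesicles/cell"
        elif not r2_ok:
            self.message_ = f"r^2 {self.r_squared_:.3f} < {self.min_r_squared}"
        return self

    def _set_failed(self, message: str) -> None:
        nan = float("nan")
        self.bottom_ = self.top_ = self.t_half_ = self.slope_ = nan
        self.se_bottom_ = self.se_top_ = self.se_t_half_ = self.se_slope_ = nan
        self.r_squared_ = nan
        self.detected_ = False
        self.message_ = message

    def predict(self, X) -> np.ndarray:
        t = np.asarray(X, dtype=np.float64).reshape(-1)
        return sigmoid(t, self.bottom_, self.top_, self.t_half_, self.slope_)

    def result_(self) -> SigmoidFit:
        return SigmoidFit(
            bottom=self.bottom_,
            top=self.top_,
            t_half=self.t_half_,
            slope=self.slope_,
            se_bottom=self.se_bottom_,
            se_top=self.se_top_,
            se_t_half=self.se_t_half_,
            se_slope=self.se_slope_,
            r_squared=self.r_squared_,
            detected=self.detected_,
            message=self.message_,
        )


def fit_sigmoid(
    curve: KineticCurve, min_span: float = 3.0, min_r_squared: float = 0.5
) -> SigmoidFit:
    """Fit the sigmoid time course to a kinetic curve (see SigmoidRegressor)."""
    reg = SigmoidRegressor(min_span=min_span, min_r_squared=min_r_squared)
    reg.fit(curve.times, curve.counts_per_cell)
    return reg.result_()


class DoseResponseRegressor(RegressorMixin, BaseEstimator):
    """Four-parameter logistic dose-response fit on log10 dose.

    ``fit(doses, responses)`` takes molar doses (> 0). ``fix_hill`` pins the
    Hill slope (e.g. to 1) instead of fitting it. The ``bell_flag_``
    attribute is set when the response at the highest dose falls below
    ``bell_fraction`` of the peak response — the signature of a bell-shaped
    series, which the monotone 4PL cannot represent; the fit still uses all
    points.
    """

    def __init__(self, fix_hill: float | None = None, bell_fraction: float = 0.8):
        self.fix_hill = fix_hill
        self.bell_fraction = bell_fraction

    def fit(self, X, y) -> "DoseResponseRegressor":
        doses = np.asarray(X, dtype=np.float64).reshape(-1)
        resp = np.asarray(y, dtype=np.float64).reshape(-1)
        if doses.size != resp.size:
            raise ValueError("doses and responses must have the same length")
        if np.any(doses <= 0):
            raise ValueError("doses must be > 0 (molar)")
        if np.unique(doses).size < 4:
            raise ValueError("need at least 4 distinct doses")

        order = np.argsort(doses)
        top_dose_resp = resp[order][-1]
        peak = resp.max()
        self.bell_flag_ = bool(peak > 0 and top_dose_resp < self.bell_fraction * peak)

        x = np.log10(doses)
        self.converged_ = False
        self.message_ = ""
        if np.allclose(resp, resp[0]):
            self._set_failed("all responses equal; dose-response fit is undefined")
            return self

        x_lo, x_hi = float(x.min()) - 3.0, float(x.max()) + 3.0
        xs = x[order]
        p0_core = (float(resp.min()), float(resp.max()), _midrange_crossing(xs, resp[order]))
        try:
            if self.fix_hill is None:
                popt, pcov = optimize.curve_fit(
                    _logistic_dose,
                    x,
                    resp,
                    p0=(*p0_core, 1.0),
                    bounds=([-np.inf, -np.inf, x_lo, -10.0], [np.inf, np.inf, x_hi, 10.0]),
                    maxfev=20000,
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                )
                hill, se_hill = float(popt[3]), float(np.sqrt(max(pcov[3, 3], 0.0)))
            else:
                h = float(self.fix_hill)

                def model(xx, e_min, e_max, log_ec50):
                    return _logistic_dose(xx, e_min, e_max, log_ec50, h)

                popt, pcov = optimize.curve_fit(
                    model,
                    x,
                    resp,
                    p0=p0_core,
                    bounds=([-np.inf, -np.inf, x_lo], [np.inf, np.inf, x_hi]),
                    maxfev=20000,
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                )
                hill, se_hill = h, 0.0
        except (RuntimeError, ValueError) as exc:
            self._set_failed(f"fit did not converge: {exc}")
            return self

        se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
        self.e_min_ = float(popt[0])
        self.e_max_ = float(popt[1])
        self.pec50_ = float(-popt[2])
        self.hill_slope_ = hill
        self.se_e_min_ = float(se[0])
        self.se_e_max_ = float(se[1])
        self.se_pec50_ = float(se[2])
        self.se_hill_slope_ = se_hill
        pred = _logistic_dose(x, popt[0], popt[1], popt[2], hill)
        self.r_squared_ = _r_squared(resp, pred)
        self.converged_ = True
        return self

    def _set_failed(self, message: str) -> None:
        nan = float("nan")
        self.pec50_ = self.e_min_ = self.e_max_ = self.hill_slope_ = nan
        self.se_pec50_ = self.se_e_min_ = self.se_e_max_ = self.se_hill_slope_ = nan
        self.r_squared_ = nan
        self.converged_ = False
        self.message_ = message

    def predict(self, X) -> np.ndarray:
        doses = np.asarray(X, dtype=np.float64).reshape(-1)
        return _logistic_dose(
            np.log10(doses), self.e_min_, self.e_max_, -self.pec50_, self.hill_slope_
        )

    def result_(self) -> DoseResponseFit:
        return DoseResponseFit(
            pec50=self.pec50_,
            e_min=self.e_min_,
            e_max=self.e_max_,
            hill_slope=self.hill_slope_,
            se_pec50=self.se_pec50_,
            se_e_min=self.se_e_min_,
            se_e_max=self.se_e_max_,
            se_hill_slope=self.se_hill_slope_,
            r_squared=self.r_squared_,
            converged=self.converged_,
            bell_flag=self.bell_flag_,
            message=self.message_,
        )


def fit_dose_response(
    doses: Sequence[float],
    responses: Sequence[float],
    fix_hill: float | None = None,
) -> DoseResponseFit:
    """Fit the 4PL dose-response curve (see DoseResponseRegressor)."""
    reg = DoseResponseRegressor(fix_hill=fix_hill)
    reg.fit(doses, responses)
    return reg.result_()


def compare_fits(groups: dict[str, Sequence[SigmoidFit]]) -> pd.DataFrame:
    """One-way ANOVA of sigmoid parameters across experimental conditions.

    ``groups`` maps condition name -> list of SigmoidFit (>= 2 groups with
    >= 2 fits each). Returns a table with F statistic and p-value per
    parameter (t_half, emax = top, slope).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    extract = {
        "t_half": lambda f: f.t_half,
        "emax": lambda f: f.top,
        "slope": lambda f: f.slope,
    }
    for name, fits in groups.items():
        if len(fits) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 fits")
    rows = []
    for pname, get in extract.items():
        samples = [np.array([get(f) for f in fits], dtype=float) for fits in groups.values()]
        if any(not np.all(np.isfinite(s)) for s in samples):
            raise ValueError(f"non-finite {pname} values (undetected fits?) in input")
        f_stat, p = stats.f_oneway(*samples)
        rows.append({"parameter": pname, "F": float(f_stat), "p_value": float(p)})
    return pd.DataFrame(rows)
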