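"""Hill dose-response analysis for sensillum rate series and oocyte currents.

The pharmacological model is the Hill equation on a log-dose axis,

    R(d) = baseline + (Emax - baseline) / (1 + (EC50 / d)^n),

with the baseline fixed at 0 by default (water-injected control oocytes
show no odorant-evoked current); a free-baseline four-parameter variant is
available.  Doses span several decades, so the fit is parameterized in
log10(EC50) and started from a grid over the observed dose decades to
avoid local minima, then polished with an unconstrained
Levenberg-Marquardt pass.  The EC50 confidence interval comes from the
linear (Jacobian) approximation at the optimum on the log10 scale.

SSR dose series use log10 v/v dilution as a pseudo-concentration axis; an
EC50 obtained there is in dilution units, not molar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    FitFailureError,
    InsufficientDataError,
    InvalidParameterError,
    SchemaError,
)
from .synth import OocyteCurrentTrace


@dataclass
class DoseResponseSeries:
    """One ligand/receptor (or odorant/sensillum) dose-response series."""

    doses: np.ndarray
    responses: np.ndarray
    sem: np.ndarray | None = None
    ligand: str = ""
    receptor: str = ""
    dose_units: str = "M"

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise InvalidParameterError("doses and responses must align")
        if np.any(self.doses <= 0):
            raise InvalidParameterError("doses must be positive")
        if np.any(np.diff(self.doses) <= 0):
            raise InvalidParameterError("doses must be strictly increasing")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.shape != self.doses.shape:
                raise InvalidParameterError("sem must align with doses")


@dataclass
class DoseResponseFit:
    """Fitted Hill parameters with diagnostics."""

    emax: float
    ec50: float
    hill_n: float
    baseline: float
    ssr: float
    converged: bool
    unidentifiable: bool = False
    extrapolated: bool = False
    ec50_ci: tuple[float, float] | None = None
    ligand: str = ""
    receptor: str = ""

    def predict(self, doses) -> np.ndarray:
        d = np.asarray(doses, dtype=float)
        return self.baseline + (self.emax - self.baseline) / (
            1.0 + (self.ec50 / d) ** self.hill_n
        )


def extract_amplitude(trace: OocyteCurrentTrace, smooth_s: float = 0.025) -> float:
    """Peak response amplitude (nA) of a voltage-clamp trace.

    Amplitude is the absolute deviation of the most extreme point inside
    the application window from the pre-application baseline (median of the
    samples before the window).  When the pre-application segment shows
    measurable noise (robust MAD estimate > 0) the window is first smoothed
    with a short moving average (``smooth_s``, 25 ms by default) so the
    reported peak is not inflated by noise extremes; a noiseless trace is
    read raw, making the extraction exact.  A flat trace gives 0.
    """
    if trace.application_window is None:
        raise SchemaError("trace carries no application window")
    t0, t1 = trace.application_window
    pre = trace.current[trace.time < t0]
    if pre.size == 0:
        raise SchemaError("no pre-application samples to define a baseline")
    baseline = float(np.median(pre))
    in_window = (trace.time >= t0) & (trace.time <= t1)
    window = trace.current[in_window]
    if window.size == 0:
        raise SchemaError("application window contains no samples")
    noise = 1.4826 * float(np.median(np.abs(pre - baseline)))
    if noise > 0 and window.size > 2:
        dt = float(np.median(np.diff(trace.time)))
        width = max(int(round(smooth_s / dt)) | 1, 1)
        if width > 1:
            kernel = np.full(width, 1.0 / width)
            window = np.convolve(window, kernel, mode="same")
    return float(np.max(np.abs(window - baseline)))


def normalize_series(
    amplitudes, mode: str = "max_is_100", reference: float | None = None
) -> np.ndarray:
    """Normalize response amplitudes to a 0-100 scale.

    ``max_is_100`` divides by the series maximum (the maximum becomes
    exactly 100, and the operation is idempotent); ``reference_odorant``
    divides by an external reference amplitude, e.g. the same oocyte's
    response to the reference ligand.
    """
    a = np.asarray(amplitudes, dtype=float)
    if mode == "max_is_100":
        denom = a.max() if a.size else 0.0
    elif mode == "reference_odorant":
        if reference is None:
            raise InvalidParameterError("reference mode requires a reference")
        denom = float(reference)
    else:
        raise InvalidParameterError(f"unknown mode {mode!r}")
    if denom <= 0:
        raise InvalidParameterError("normalization reference must be > 0")
    return a / denom * 100.0


def _hill_log(x, emax, p, n, baseline):
    # x = log10 dose, p = log10 EC50; exponent clipped against overflow
    expo = np.clip(n * (p - x), -300.0, 300.0)
    return baseline + (emax - baseline) / (1.0 + 10.0**expo)


def fit_hill(
    series: DoseResponseSeries,
    fix_baseline: bool = True,
    baseline: float = 0.0,
) -> DoseResponseFit:
    """Least-squares Hill fit with multi-start initialization.

    Requires at least 4 dose points and non-negative responses.  A series
    whose responses do not vary with dose is returned immediately with the
    ``unidentifiable`` flag set; an EC50 landing outside
    [min dose / 10, max dose * 10] sets the ``extrapolated`` flag.
    """
    d, y = series.doses, series.responses
    if d.size < 4:
        raise InsufficientDataError("need at least 4 dose points")
    if np.any(y < 0):
        raise InvalidParameterError("responses must be non-negative")
    x = np.log10(d)
    span = float(np.ptp(y))
    scale = max(float(np.abs(y).max()), 1.0)
    if span <= 1e-3 * scale:
        return DoseResponseFit(
            emax=float(y.mean()),
            ec50=math.nan,
            hill_n=math.nan,
            baseline=baseline if fix_baseline else float(y.mean()),
            ssr=float(np.sum((y - y.mean()) ** 2)),
            converged=False,
            unidentifiable=True,
            ligand=series.ligand,
            receptor=series.receptor,
        )

    if fix_baseline:
        def resid(theta):
            return _hill_log(x, theta[0], theta[1], theta[2], baseline) - y
    else:
        def resid(theta):
            return _hill_log(x, theta[0], theta[1], theta[2], theta[3]) - y

    lo = [1e-12, x.min() - 3.0, 0.05] + ([] if fix_baseline else [-np.inf])
    hi = [10.0 * max(y.max(), 1e-12), x.max() + 3.0, 10.0] + (
        [] if fix_baseline else [np.inf]
    )
    e0 = float(y.max())
    starts = []
    for p0 in np.unique(np.concatenate([x, [x.mean()]])):
        for n0 in (0.5, 1.0, 2.0):
            theta0 = [e0, float(p0), n0] + ([] if fix_baseline else [float(y.min())])
            starts.append(theta0)

    best = None
    for theta0 in starts:
        try:
            res = least_squares(resid, theta0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        ssr = float(np.sum(res.fun**2))
        if res.success and (best is None or ssr < best[1]):
            best = (res, ssr)
    if best is None:
        raise FitFailureError(
            f"Hill fit failed from all {len(starts)} starts for "
            f"{series.ligand or 'series'}"
        )
    res, ssr = best
    # unconstrained polish for full numerical precision on clean data
    try:
        polished = least_squares(resid, res.x, method="lm")
        pssr = float(np.sum(polished.fun**2))
        theta = polished.x
        if (
            pssr <= ssr
            and theta[0] > 0
            and 0 < theta[2] <= 20
            and lo[1] <= theta[1] <= hi[1]
        ):
            res, ssr = polished, pssr
    except Exception:
        pass

    theta = res.x
    emax, p, n = float(theta[0]), float(theta[1]), float(theta[2])
    b = baseline if fix_baseline else float(theta[3])
    ec50 = 10.0**p
    m, kpar = y.size, len(theta)
    ci = None
    if m > kpar:
        jac = res.jac
        try:
            cov = np.linalg.inv(jac.T @ jac) * ssr / (m - kpar)
            se_p = math.sqrt(max(cov[1, 1], 0.0))
            lo_e = max(min(p - 1.96 * se_p, 300.0), -300.0)
            hi_e = max(min(p + 1.96 * se_p, 300.0), -300.0)
            ci = (10.0**lo_e, 10.0**hi_e)
        except np.linalg.LinAlgError:
            ci = None
    extrapolated = not (d.min() / 10.0 <= ec50 <= d.max() * 10.0)
    return DoseResponseFit(
        emax=emax,
        ec50=ec50,
        hill_n=n,
        baseline=b,
        ssr=ssr,
        converged=bool(res.success),
        extrapolated=extrapolated,
        ec50_ci=ci,
        ligand=series.ligand,
        receptor=series.receptor,
    )


@dataclass
class ThresholdResult:
    """Lowest dose reaching a response criterion."""

    dose: float
    grid_dose: float | None
    above_range: bool = False


def threshold_dose(
    fit: DoseResponseFit,
    criterion: float | None = None,
    fraction_of_emax: float | None = None,
    dose_grid=None,
) -> ThresholdResult:
    """Lowest dose at which the fitted response reaches a criterion.

    The criterion is either an absolute response (``criterion``, same units
    as the fit) or a fraction of Emax above baseline.  The continuous
    solution inverts the Hill equation; if a ``dose_grid`` is supplied the
    lowest grid dose whose fitted response reaches the criterion is also
    reported.  A criterion at or above Emax is unreachable and returns the
    above-range sentinel.
    """
    if (criterion is None) == (fraction_of_emax is None):
        raise InvalidParameterError(
            "give exactly one of criterion or fraction_of_emax"
        )
    if fraction_of_emax is not None:
        if not (0 < fraction_of_emax < 1):
            raise InvalidParameterError("fraction_of_emax must be in (0, 1)")
        criterion = fit.baseline + fraction_of_emax * (fit.emax - fit.baseline)
    if criterion <= fit.baseline:
        raise InvalidParameterError("criterion must exceed the baseline")
    if criterion >= fit.emax:
        return ThresholdResult(math.nan, None, above_range=True)
    ratio = (fit.emax - fit.baseline) / (criterion - fit.baseline) - 1.0
    dose = fit.ec50 * ratio ** (-1.0 / fit.hill_n)
    grid_dose = None
    if dose_grid is not None:
        grid = np.sort(np.asarray(dose_grid, dtype=float))
        reached = grid[fit.predict(grid) >= criterion]
        grid_dose = float(reached[0]) if reached.size else None
    return ThresholdResult(float(dose), grid_dose, above_range=False)
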