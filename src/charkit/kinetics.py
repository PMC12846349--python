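"""Phenotype quantification from plate-reader and titration time series.

Covers the standard bench characterizations of a lytic phage:

* local virulence and the integrated virulence index (Storms-style
  area-under-the-killing-curve statistics over an MOI ladder),
* one-step growth analysis (latent period, rise period, burst size),
* adsorption kinetics (fraction unadsorbed, first-order rate constant),
* crystal-violet biofilm inhibition percentage,
* stability log10 reduction with detection-limit censoring.

Local virulence at one MOI is v = 1 - A_phage / A_control, where A is the
trapezoidal area under the OD curve from infection onset to the
integration endpoint T (by default the onset of stationary phase in the
phage-free control). The virulence index integrates v over log10(MOI),
normalized so that complete suppression at every MOI gives 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (EmptyInputError, NoBurstError, UndefinedValueError,
                     UnterminatedRiseError)


@dataclass
class GrowthCurveSet:
    """Replicate-averaged OD time series: a phage-free control plus an MOI ladder."""

    times: np.ndarray                 # minutes, ascending
    control_od: np.ndarray
    moi_curves: dict[float, np.ndarray]
    window_end: float | None = None   # integration endpoint T (minutes)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.control_od = np.asarray(self.control_od, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("need at least two time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly ascending")
        if len(self.control_od) != len(self.times):
            raise ValueError("control curve length mismatch")
        self.moi_curves = {float(m): np.asarray(v, dtype=float)
                           for m, v in self.moi_curves.items()}
        for m, v in self.moi_curves.items():
            if len(v) != len(self.times):
                raise ValueError(f"curve for MOI {m} has wrong length")
            if m <= 0:
                raise ValueError("MOIs must be positive")

    def resolved_window_end(self) -> float:
        if self.window_end is not None:
            return float(self.window_end)
        return stationary_onset(self.times, self.control_od)


@dataclass(frozen=True)
class LocalVirulence:
    moi: float
    v: float  # in [0, 1], clamped below at 0


@dataclass
class TiterSeries:
    """Time-indexed PFU/mL measurements with a detection limit.

    ``n0`` is the total number of infective phage input at t0 and
    ``volume_ml`` the culture volume, so plateau_titer * volume_ml / n0 is
    the burst size.
    """

    times: np.ndarray
    titer: np.ndarray
    lod: float = 0.0
    n0: float | None = None
    volume_ml: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.titer = np.asarray(self.titer, dtype=float)
        if len(self.times) != len(self.titer):
            raise ValueError("times/titer length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly ascending")
        if np.any(self.titer < 0):
            raise ValueError("titers must be non-negative")


@dataclass(frozen=True)
class OneStepResult:
    latent_min: float
    rise_min: float
    plateau_titer: float
    burst_size: float


@dataclass
class AdsorptionResult:
    times: np.ndarray
    fraction_unadsorbed: np.ndarray
    percent_adsorbed_at: dict[float, float]
    rate_constant: float | None = None  # mL cell^-1 min^-1


def stationary_onset(times: np.ndarray, od: np.ndarray,
                     slope_frac: float = 0.05) -> float:
    """Detect the onset of stationary phase in a growth curve.

    Returns the first time at which the forward difference of OD falls
    below ``slope_frac`` of the maximum forward difference, searching only
    after the point of maximum slope (so the lag phase is not mistaken for
    stationarity). Falls back to the final time if growth never flattens.
    """
    times = np.asarray(times, dtype=float)
    od = np.asarray(od, dtype=float)
    d = np.diff(od) / np.diff(times)
    imax = int(np.argmax(d))
    thresh = slope_frac * d[imax]
    for i in range(imax + 1, len(d)):
        if d[i] < thresh:
            return float(times[i])
    return float(times[-1])


def _curve_area(times: np.ndarray, values: np.ndarray, t_end: float) -> float:
    """Trapezoidal area over [times[0], t_end]; the endpoint is linearly
    interpolated when it falls between grid points."""
    if t_end > times[-1] + 1e-9:
        raise ValueError("window_end beyond last time point")
    mask = times <= t_end
    t = times[mask]
    v = values[mask]
    if t[-1] < t_end:
        t = np.append(t, t_end)
        v = np.append(v, np.interp(t_end, times, values))
    return float(np.trapezoid(v, t))


def local_virulence(curves: GrowthCurveSet, moi: float) -> LocalVirulence:
    """v = max(0, 1 - A_moi / A_control) with trapezoidal areas over
    [t0, window_end]."""
    moi = float(moi)
    if moi not in curves.moi_curves:
        raise KeyError(f"MOI {moi} not in curve set")
    t_end = curves.resolved_window_end()
    a_control = _curve_area(curves.times, curves.control_od, t_end)
    if a_control == 0:
        raise UndefinedValueError("control curve has zero area")
    a_moi = _curve_area(curves.times, curves.moi_curves[moi], t_end)
    return LocalVirulence(moi=moi, v=max(0.0, 1.0 - a_moi / a_control))


def virulence_index(locals_: list[LocalVirulence]) -> float:
    """Normalized trapezoidal area of local virulence versus log10(MOI).

    The area under v(log10 MOI) is divided by the area of v = 1 over the
    same log10-MOI range, giving a value in [0, 1].
    """
    if len(locals_) < 2:
        raise ValueError("virulence index requires >= 2 MOIs")
    pairs = sorted((lv.moi, lv.v) for lv in locals_)
    mois = np.array([p[0] for p in pairs])
    if np.any(np.diff(mois) == 0):
        raise ValueError("duplicate MOI in virulence index input")
    x = np.log10(mois)
    v = np.array([p[1] for p in pairs])
    return float(np.trapezoid(v, x) / (x[-1] - x[0]))


def virulence_curve(curves: GrowthCurveSet) -> list[LocalVirulence]:
    """Local virulence at every MOI in the set, ascending."""
    return [local_virulence(curves, m) for m in sorted(curves.moi_curves)]


def one_step(series: TiterSeries, rise_factor: float = 1.5,
             plateau_tol: float = 0.10) -> OneStepResult:
    """Latent period, rise period and burst size from a one-step growth curve.

    The baseline is the titer at t0. The latent period is the last sample
    time at which the titer is still <= rise_factor * baseline before the
    first sustained rise. The plateau is the first maximal run of >= 2
    consecutive post-rise points over which growth has ceased: each next
    point stays within (1 + plateau_tol) of the run's running maximum, so
    a second burst (another rise_factor-scale jump) terminates the run but
    measurement noise does not. Burst size = mean plateau titer * volume / n0.
    """
    t = series.times
    y = series.titer
    if len(t) < 4:
        raise ValueError("one-step analysis requires >= 4 time points")
    if series.n0 is None or series.n0 <= 0:
        raise ValueError("one-step analysis requires the phage input n0 > 0")
    baseline = y[0]
    cut = rise_factor * baseline
    # first sustained crossing: above the cut and not an isolated spike
    rise_idx = None
    for i in range(1, len(y)):
        if y[i] > cut and (i + 1 == len(y) or y[i + 1] > cut):
            rise_idx = i
            break
    if rise_idx is None:
        raise NoBurstError("no rise above rise_factor * baseline detected")
    latent = float(t[rise_idx - 1])
    # first plateau at/after the rise: growth has ceased once the next point
    # no longer exceeds the running maximum by more than plateau_tol
    run_start = None
    for i in range(rise_idx, len(y) - 1):
        if y[i] > 0 and y[i + 1] <= (1 + plateau_tol) * y[i]:
            run_start = i
            break
    if run_start is None:
        raise UnterminatedRiseError("rise never settles into a plateau")
    run_end = run_start + 1
    hi = max(y[run_start], y[run_end])
    while run_end + 1 < len(y) and y[run_end + 1] <= (1 + plateau_tol) * hi:
        run_end += 1
        hi = max(hi, y[run_end])
    plateau = float(np.mean(y[run_start:run_end + 1]))
    burst = plateau * series.volume_ml / series.n0
    return OneStepResult(latent_min=latent,
                         rise_min=float(t[run_start]) - latent,
                         plateau_titer=plateau,
                         burst_size=burst)


def adsorption(series: TiterSeries,
               cell_density: float | None = None) -> AdsorptionResult:
    """Fraction of free phage P(t)/P0 and, when the cell density N is
    given, the first-order adsorption rate constant k from the model
    P(t) = P0 exp(-k N t), fitted as the least-squares slope of
    -ln(P/P0) against N*t through the origin."""
    p0 = series.titer[0]
    if p0 <= 0:
        raise ValueError("initial titer must be positive")
    frac = series.titer / p0
    pct = {float(tt): float(100.0 * (1.0 - f))
           for tt, f in zip(series.times, frac)}
    rate = None
    if cell_density is not None:
        mask = frac > 0
        x = cell_density * series.times[mask]
        yv = -np.log(frac[mask])
        sxx = float(np.dot(x, x))
        rate = float(np.dot(x, yv) / sxx) if sxx > 0 else 0.0
    return AdsorptionResult(times=series.times, fraction_unadsorbed=frac,
                            percent_adsorbed_at=pct, rate_constant=rate)


def biofilm_inhibition(od_control, od_phage) -> float:
    """Crystal-violet biofilm inhibition percentage:
    100 * (mean control - mean treated) / mean control. Negative values
    (biofilm enhancement) are reported as-is."""
    c = float(np.mean(np.asarray(od_control, dtype=float)))
    p = float(np.mean(np.asarray(od_phage, dtype=float)))
    if c <= 0:
        raise UndefinedValueError("mean control OD must be positive")
    return 100.0 * (c - p) / c


def log_reduction(titer_ref: float, titer_treated: float,
                  lod: float = 0.0) -> tuple[float, bool]:
    """log10 titer reduction with detection-limit censoring.

    Returns (value, censored); when the treated titer is below the limit
    of detection the value is computed against the LOD and flagged
    censored, i.e. it is a lower bound ("complete inactivation")."""
    if titer_ref <= 0:
        raise ValueError("reference titer must be positive")
    censored = titer_treated < lod
    denom = max(titer_treated, lod)
    if denom <= 0:
        raise ValueError("treated titer and LOD both non-positive")
    return math.log10(titer_ref) - math.log10(denom), censored


# ---------------------------------------------------------------- I/O helpers

def read_long_table(path: str) -> pd.DataFrame:
    """Read a long-format TSV/CSV with columns time_min, condition,
    replicate, value (replicates averaged downstream)."""
    sep = "," if path.endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    required = {"time_min", "condition", "value"}
    missing = required - set(df.columns)
    if missing:
        raise EmptyInputError(f"table {path!r} lacks columns {sorted(missing)}")
    return df


def growth_curves_from_table(df: pd.DataFrame, control: str = "control",
                             window_end: float | None = None) -> GrowthCurveSet:
    """Build a GrowthCurveSet from a long table whose condition column holds
    ``control`` for the phage-free wells and the MOI (as a number) otherwise."""
    mean = (df.groupby(["condition", "time_min"])["value"]
              .mean().reset_index())
    times = np.array(sorted(mean["time_min"].unique()), dtype=float)
    curves = {}
    control_od = None
    for cond, sub in mean.groupby("condition"):
        sub = sub.sort_values("time_min")
        if len(sub) != len(times):
            raise ValueError(f"condition {cond!r} missing time points")
        vals = sub["value"].to_numpy(dtype=float)
        if str(cond) == control:
            control_od = vals
        else:
            curves[float(cond)] = vals
    if control_od is None:
        raise EmptyInputError(f"no condition {control!r} in table")
    return GrowthCurveSet(times=times, control_od=control_od,
                          moi_curves=curves, window_end=window_end)


def titer_series_from_table(df: pd.DataFrame, condition: str | None = None,
                            lod: float = 0.0, n0: float | None = None,
                            volume_ml: float = 1.0) -> TiterSeries:
    if condition is not None:
        df = df[df["condition"].astype(str) == condition]
    if df.empty:
        raise EmptyInputError("no rows for titer series")
    mean = df.groupby("time_min")["value"].mean().sort_index()
    return TiterSeries(times=mean.index.to_numpy(dtype=float),
                       titer=mean.to_numpy(dtype=float),
                       lod=lod, n0=n0, volume_ml=volume_ml)
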