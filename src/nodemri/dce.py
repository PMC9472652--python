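"""Tofts two-compartment pharmacokinetic model for DCE-MRI.

The standard (non-extended) Tofts model describes the tissue contrast
concentration as a convolution of the arterial plasma concentration Cp with
an exponential impulse response,

    Ct(t) = Ktrans * integral_0^t Cp(tau) * exp(-Kep * (t - tau)) dtau,

where Ktrans (/min) is the plasma -> extravascular-extracellular-space (EES)
transfer constant, Kep (/min) the back-flux rate, and Ve = Ktrans / Kep the
EES volume fraction.  Ve is always derived from that ratio, never fitted as
a third free parameter.

The plasma input is a named population arterial input function (AIF); the
default is the Weinmann biexponential.  The convolution is evaluated by
trapezoidal quadrature on a refined uniform grid and sampled at the
requested times; injection is at t = 0 and pre-contrast (baseline) samples
carry t < 0, where both Cp and Ct are identically zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DataError

__all__ = [
    "AIF_PRESETS",
    "ArterialInputFunction",
    "DCESeries",
    "ToftsFit",
    "evaluate_aif",
    "default_times",
    "tofts_concentration",
    "tofts_fit",
]

#: Named population AIF presets: Cp(t) = dose * (a1*exp(-m1*t) + a2*exp(-m2*t)).
#: Amplitudes in kg/L, rates in /min, dose in mmol/kg, so Cp is in mM.
AIF_PRESETS: dict[str, dict[str, float]] = {
    "weinmann": {"a1": 3.99, "m1": 0.144, "a2": 4.78, "m2": 0.0111, "dose": 0.1},
}

_KTRANS_BOUNDS = (0.0, 5.0)
_KEP_BOUNDS = (0.01, 10.0)
_FIT_TOL = 1e-14


@dataclass(frozen=True)
class ArterialInputFunction:
    """Biexponential population AIF, zero before injection (t < 0)."""

    a1: float
    m1: float
    a2: float
    m2: float
    dose: float
    aif_id: str = "custom"

    @classmethod
    def from_preset(cls, aif_id: str) -> "ArterialInputFunction":
        try:
            p = AIF_PRESETS[aif_id]
        except KeyError:
            raise DataError(
                f"unknown AIF preset {aif_id!r}; known: {sorted(AIF_PRESETS)}"
            ) from None
        return cls(aif_id=aif_id, **p)


def _resolve_aif(aif) -> ArterialInputFunction:
    if isinstance(aif, ArterialInputFunction):
        return aif
    return ArterialInputFunction.from_preset(str(aif))


def evaluate_aif(aif, t):
    """Plasma concentration (mM) at time t (minutes since injection)."""
    a = _resolve_aif(aif)
    t = np.asarray(t, dtype=float)
    cp = a.dose * (a.a1 * np.exp(-a.m1 * t) + a.a2 * np.exp(-a.m2 * t))
    out = np.where(t < 0, 0.0, cp)
    return float(out) if out.ndim == 0 else out


def default_times(n_baseline: int = 4, n_dynamic: int = 31, dt_s: float = 8.0) -> np.ndarray:
    """Acquisition time stamps in minutes: baseline frames before injection.

    The default mirrors a 4 + 31 frame dynamic series at 8 s temporal
    resolution; injection occurs at t = 0, so baseline frames have t < 0.
    """
    idx = np.arange(n_baseline + n_dynamic, dtype=float) - n_baseline
    return idx * dt_s / 60.0


@dataclass(frozen=True)
class DCESeries:
    """A tissue concentration-time series (mM vs minutes)."""

    times: tuple[float, ...]
    concentration: tuple[float, ...]
    n_baseline: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentration, dtype=float)
        if t.size != c.size:
            raise DataError("times and concentration must have equal length")
        if np.any(np.diff(t) <= 0):
            raise DataError("times must be strictly increasing")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "concentration", tuple(float(x) for x in c))

    @property
    def times_arr(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def conc_arr(self) -> np.ndarray:
        return np.asarray(self.concentration, dtype=float)


@dataclass(frozen=True)
class ToftsFit:
    ktrans: float  # /min
    kep: float  # /min
    ve: float  # = ktrans / kep, fraction
    residual_sse: float
    flagged: bool = False


def tofts_concentration(
    ktrans: float,
    kep: float,
    times,
    aif="weinmann",
    grid_dt_min: float = 1.0 / 300.0,
) -> np.ndarray:
    """Noiseless tissue concentration at ``times`` (minutes).

    The convolution integral is evaluated with the trapezoidal rule on a
    uniform grid of spacing ``grid_dt_min`` (default 0.2 s) and linearly
    interpolated at the requested times; times < 0 map to zero.  The result
    is exactly linear in ktrans.
    """
    if kep <= 0:
        raise DataError("kep must be positive")
    if ktrans < 0:
        raise DataError("ktrans must be non-negative")
    t = np.asarray(times, dtype=float)
    if ktrans == 0:
        return np.zeros_like(t)
    a = _resolve_aif(aif)
    t_max = max(float(t.max()), grid_dt_min)
    n = int(np.ceil(t_max / grid_dt_min)) + 1
    grid = np.arange(n) * grid_dt_min
    cp = evaluate_aif(a, grid)
    kern = np.exp(-kep * grid)
    full = np.convolve(cp, kern)[:n]
    # trapezoid end-point correction of the Riemann sum
    trap = grid_dt_min * (full - 0.5 * cp[0] * kern - 0.5 * cp * kern[0])
    ct_grid = ktrans * trap
    return np.interp(t, grid, ct_grid, left=0.0)


def tofts_fit(series: DCESeries, aif="weinmann", grid_dt_min: float = 1.0 / 300.0) -> ToftsFit:
    """Bounded nonlinear least squares for (ktrans, kep); ve = ktrans/kep.

    Bounds ktrans to [0, 5]/min and kep to [0.01, 10]/min with the fixed
    initialization (0.3, 1.0).  An all-zero series short-circuits to a
    flagged ktrans = 0 result.  A fitted ve above 1 is flagged, not clipped.
    """
    t = series.times_arr
    c = series.conc_arr
    if np.sum(t > 0) < 10:
        raise DataError("tofts_fit needs at least 10 post-baseline samples")
    if np.allclose(c, 0.0):
        return ToftsFit(ktrans=0.0, kep=1.0, ve=0.0, residual_sse=0.0, flagged=True)
    aif_obj = _resolve_aif(aif)

    def resid(x):
        return tofts_concentration(x[0], x[1], t, aif_obj, grid_dt_min) - c

    sol = least_squares(
        resid,
        np.array([0.3, 1.0]),
        bounds=([_KTRANS_BOUNDS[0], _KEP_BOUNDS[0]], [_KTRANS_BOUNDS[1], _KEP_BOUNDS[1]]),
        x_scale=[0.1, 1.0],
        ftol=_FIT_TOL,
        xtol=_FIT_TOL,
        gtol=_FIT_TOL,
    )
    ktrans, kep = (float(v) for v in sol.x)
    ve = ktrans / kep
    flagged = False
    if ve > 1.0:
        warnings.warn(f"fitted ve = {ve:.3f} exceeds 1; result flagged", stacklevel=2)
        flagged = True
    r = resid(sol.x)
    return ToftsFit(
        ktrans=ktrans, kep=kep, ve=ve, residual_sse=float(r @ r), flagged=flagged
    )
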