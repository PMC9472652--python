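"""Diffusion-MRI signal models and fitters.

Three formalisms operate on the same multi-b-value magnitude decay:

* monoexponential ADC: ``S(b) = S0 * exp(-b * ADC)``, fitted by linear least
  squares on the log signal;
* diffusion kurtosis (DKI): ``S(b) = S0 * exp(-b*D + (1/6)*b^2*D^2*K)``,
  fitted by bounded nonlinear least squares for (S0, D, K), where D is
  reported as MD and K as MK;
* intravoxel incoherent motion (IVIM):
  ``S(b) = S0 * [(1-PF)*exp(-b*D_slow) + PF*exp(-b*D_fast)]``, fitted by the
  standard two-stage segmented scheme (high-b monoexponential for D_slow and
  the perfusion fraction, then a 1-D search for D_fast), with an optional
  full biexponential refinement.

b-values are in s/mm^2 and diffusivities in mm^2/s throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DataError

__all__ = [
    "DEFAULT_DWI_BVALUES",
    "DEFAULT_DKI_BVALUES",
    "DEFAULT_IVIM_BVALUES",
    "BValueScheme",
    "DiffusionMeasurement",
    "MonoexponentialFit",
    "KurtosisFit",
    "IvimFit",
    "mono_signal",
    "dki_signal",
    "ivim_signal",
    "adc_fit",
    "dki_fit",
    "ivim_fit",
]

# Default acquisition schemes (s/mm^2), configurable everywhere they are used.
DEFAULT_DWI_BVALUES = (0.0, 600.0)
DEFAULT_DKI_BVALUES = (0.0, 500.0, 1000.0, 1500.0, 2000.0)
DEFAULT_IVIM_BVALUES = (
    0.0, 10.0, 20.0, 30.0, 50.0, 80.0, 100.0, 150.0, 200.0, 400.0, 600.0, 800.0,
)

_FIT_TOL = 1e-14
# fit-domain bounds, base units
_D_BOUNDS = (1e-5, 4e-3)
_K_BOUNDS = (0.0, 3.0)
_DFAST_MAX = 1.0


@dataclass(frozen=True)
class BValueScheme:
    """An ordered diffusion-weighting scheme.

    Values must be non-negative, strictly increasing and include b = 0
    (the unweighted reference S0).
    """

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size < 2:
            raise DataError("b_scheme needs at least 2 b-values")
        if np.any(v < 0):
            raise DataError("b_scheme values must be non-negative")
        if np.any(np.diff(v) <= 0):
            raise DataError("b_scheme values must be strictly increasing")
        if v[0] != 0:
            raise DataError("b_scheme must contain b = 0")
        object.__setattr__(self, "values", tuple(float(x) for x in v))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class DiffusionMeasurement:
    """Signal intensities of one voxel (or ROI mean) over a b-value scheme."""

    b_scheme: BValueScheme
    signal: tuple[float, ...]

    def __post_init__(self) -> None:
        s = np.asarray(self.signal, dtype=float)
        if s.size != len(self.b_scheme.values):
            raise DataError("signal length must match b_scheme length")
        if np.any(s <= 0) or not np.all(np.isfinite(s)):
            raise DataError("signals must be positive and finite")
        object.__setattr__(self, "signal", tuple(float(x) for x in s))

    @property
    def b_values(self) -> np.ndarray:
        return self.b_scheme.as_array()

    @property
    def s0(self) -> float:
        """Measured signal at b = 0."""
        return self.signal[0]


@dataclass(frozen=True)
class MonoexponentialFit:
    adc: float  # mm^2/s
    s0_est: float
    residual_sse: float


@dataclass(frozen=True)
class KurtosisFit:
    md: float  # mm^2/s
    mk: float  # unitless
    s0_est: float
    residual_sse: float
    converged: bool = True


@dataclass(frozen=True)
class IvimFit:
    d_slow: float  # mm^2/s
    d_fast: float  # mm^2/s
    pf: float  # fraction in [0, 1]
    s0_est: float
    residual_sse: float
    b_split: float = 200.0
    refined: bool = False


# ---------------------------------------------------------------- forward models


def mono_signal(b, adc, s0):
    """Monoexponential decay ``s0 * exp(-b * adc)``."""
    b = np.asarray(b, dtype=float)
    out = s0 * np.exp(-b * adc)
    return float(out) if out.ndim == 0 else out


def dki_signal(b, d, k, s0):
    """Kurtosis decay ``s0 * exp(-b*d + (1/6)*b^2*d^2*k)``."""
    b = np.asarray(b, dtype=float)
    out = s0 * np.exp(-b * d + (b * d) ** 2 * k / 6.0)
    return float(out) if out.ndim == 0 else out


def ivim_signal(b, d_slow, d_fast, pf, s0):
    """Biexponential decay: slow tissue compartment plus fast pseudo-diffusion."""
    b = np.asarray(b, dtype=float)
    out = s0 * ((1.0 - pf) * np.exp(-b * d_slow) + pf * np.exp(-b * d_fast))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------- fitters


def adc_fit(meas: DiffusionMeasurement) -> MonoexponentialFit:
    """Two-variable linear least squares of ln(S) on b.

    The slope is -ADC and the intercept ln(S0).  With exactly two b-values
    this reduces to the closed form ``ADC = ln(S0/Sb) / b``.
    """
    b = meas.b_values
    s = np.asarray(meas.signal)
    slope, intercept = np.polyfit(b, np.log(s), 1)
    adc = -float(slope)
    s0_est = float(np.exp(intercept))
    resid = s - mono_signal(b, adc, s0_est)
    return MonoexponentialFit(adc=adc, s0_est=s0_est, residual_sse=float(resid @ resid))


def dki_fit(meas: DiffusionMeasurement) -> KurtosisFit:
    """Constrained nonlinear least squares for (S0, MD, MK).

    Requires at least three distinct b-values spanning at least
    1000 s/mm^2; bounds MD to (1e-5, 4e-3) mm^2/s and MK to [0, 3];
    initialization comes from the monoexponential fit (MD0 = ADC, MK0 = 0.5).
    """
    b = meas.b_values
    s = np.asarray(meas.signal)
    if b.size < 3:
        raise DataError("dki_fit needs at least 3 b-values")
    if b.max() - b.min() < 1000:
        raise DataError("dki_fit needs a b-value span of at least 1000 s/mm^2")

    mono = adc_fit(meas)
    d0 = float(np.clip(mono.adc, _D_BOUNDS[0] * 1.01, _D_BOUNDS[1] * 0.99))
    x0 = np.array([mono.s0_est, d0, 0.5])

    def resid(x):
        return dki_signal(b, x[1], x[2], x[0]) - s

    sol = least_squares(
        resid,
        x0,
        bounds=([1e-12, _D_BOUNDS[0], _K_BOUNDS[0]], [np.inf, _D_BOUNDS[1], _K_BOUNDS[1]]),
        x_scale=[max(meas.s0, 1e-6), 1e-3, 1.0],
        ftol=_FIT_TOL,
        xtol=_FIT_TOL,
        gtol=_FIT_TOL,
    )
    r = resid(sol.x)
    return KurtosisFit(
        md=float(sol.x[1]),
        mk=float(sol.x[2]),
        s0_est=float(sol.x[0]),
        residual_sse=float(r @ r),
        converged=bool(sol.status > 0),
    )


def ivim_fit(
    meas: DiffusionMeasurement,
    b_split: float = 200.0,
    refine: bool = False,
) -> IvimFit:
    """Segmented IVIM fit with optional full biexponential refinement.

    Stage 1 fits a monoexponential to the b >= ``b_split`` portion, giving
    D_slow and an extrapolated zero-b intercept A; the perfusion fraction is
    ``PF = 1 - A / S0`` (clamped to [0, 1]).  Stage 2 fixes D_slow and PF and
    solves a 1-D nonlinear least squares for D_fast on the full curve,
    bounded to [D_slow, 1] mm^2/s.  With ``refine=True`` a simultaneous
    3-parameter (D_slow, D_fast, PF) refinement starts from the segmented
    solution, so its residual never exceeds the segmented one.
    """
    b = meas.b_values
    s = np.asarray(meas.signal)
    high = b >= b_split
    if high.sum() < 2 or (~high).sum() < 2:
        raise DataError(
            f"ivim_fit needs >= 2 b-values on each side of b_split={b_split:g}"
        )

    # stage 1: log-linear fit restricted to the high-b regime
    slope, intercept = np.polyfit(b[high], np.log(s[high]), 1)
    d_slow = float(np.clip(-slope, _D_BOUNDS[0], _D_BOUNDS[1]))
    a = float(np.exp(intercept))
    s0 = meas.s0
    pf = float(np.clip(1.0 - a / s0, 0.0, 1.0))

    # stage 2: 1-D search for the pseudo-diffusion coefficient
    def resid_dfast(x):
        return ivim_signal(b, d_slow, x[0], pf, s0) - s

    x0 = np.array([min(max(5.0 * d_slow, 1e-2), _DFAST_MAX)])
    sol = least_squares(
        resid_dfast,
        x0,
        bounds=([d_slow], [_DFAST_MAX]),
        ftol=_FIT_TOL,
        xtol=_FIT_TOL,
        gtol=_FIT_TOL,
    )
    d_fast = float(sol.x[0])
    r = resid_dfast(sol.x)
    fit = IvimFit(
        d_slow=d_slow,
        d_fast=d_fast,
        pf=pf,
        s0_est=s0,
        residual_sse=float(r @ r),
        b_split=float(b_split),
    )
    if not refine:
        return fit

    def resid_full(x):
        return ivim_signal(b, x[0], x[1], x[2], s0) - s

    sol2 = least_squares(
        resid_full,
        np.array([fit.d_slow, max(fit.d_fast, fit.d_slow * 1.001), fit.pf]),
        bounds=([_D_BOUNDS[0], _D_BOUNDS[0], 0.0], [1e-2, _DFAST_MAX, 1.0]),
        x_scale=[1e-3, 1e-2, 0.1],
        ftol=_FIT_TOL,
        xtol=_FIT_TOL,
        gtol=_FIT_TOL,
    )
    ds, df, p = (float(v) for v in sol2.x)
    if df < ds:  # compartments swapped at the optimum: relabel
        ds, df = df, ds
        p = 1.0 - p
    r2 = resid_full(sol2.x)
    sse2 = float(r2 @ r2)
    if sse2 > fit.residual_sse:  # keep the better solution (should not happen)
        return fit
    return IvimFit(
        d_slow=ds,
        d_fast=df,
        pf=p,
        s0_est=s0,
        residual_sse=sse2,
        b_split=float(b_split),
        refined=True,
    )
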