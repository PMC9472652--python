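"""Digital-phantom cohort generator.

Emulates a two-timepoint cohort of metastatic cervical lymph nodes with the
statistical structure the downstream analysis assumes: per-node ground-truth
parameter 9-tuples (ADC, MD, MK, D_slow, D_fast, PF, Ktrans, Kep, Ve) drawn
from group-specific truncated normal distributions whose means and SDs
default to the published responding-group (RG) / non-responding-group (NRG)
summaries, including the pretreatment elevation of PF and Ktrans in
responders; node volumes and sphericity-derived diameters whose pre-to-post
change is consistent with the assigned RG/NRG label under the RECIST
percentage rules; and voxel-level forward signals (multi-b diffusion decays
with Rician noise, Tofts concentration-time curves with Gaussian noise).

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import dce, diffusion
from .errors import ConfigurationError, DataError
from .nodes import classify_recist
from .scales import PARAM_NAMES, from_report, to_report

__all__ = [
    "DEFAULT_PARAM_DISTS",
    "DEFAULT_VOLUME_PRE_DIST",
    "DEFAULT_REDUCTION_DIST",
    "PhantomSpec",
    "NodeParams",
    "GroundTruthNode",
    "generate_cohort",
    "cohort_to_frame",
    "simulate_diffusion_signal",
    "simulate_dce_series",
    "render_parameter_maps",
]

#: Default (mean, sd) of each generated parameter, on the reporting scale,
#: keyed (parameter, timepoint, group).  Ve has no entry: it is always
#: recomputed as Ktrans/Kep after the draws.
DEFAULT_PARAM_DISTS: dict[tuple[str, str, str], tuple[float, float]] = {
    ("adc", "pre", "RG"): (1251.65, 210.64),
    ("adc", "pre", "NRG"): (1202.02, 210.64),
    ("adc", "post", "RG"): (1375.59, 235.54),
    ("adc", "post", "NRG"): (1413.29, 342.48),
    ("md", "pre", "RG"): (1024.44, 202.53),
    ("md", "pre", "NRG"): (1066.17, 318.57),
    ("md", "post", "RG"): (1263.82, 228.33),
    ("md", "post", "NRG"): (1309.57, 395.87),
    ("mk", "pre", "RG"): (993.17, 151.61),
    ("mk", "pre", "NRG"): (981.02, 173.83),
    ("mk", "post", "RG"): (883.30, 151.83),
    ("mk", "post", "NRG"): (819.95, 186.90),
    ("d_slow", "pre", "RG"): (741.79, 261.22),
    ("d_slow", "pre", "NRG"): (762.76, 284.00),
    ("d_slow", "post", "RG"): (828.68, 273.48),
    ("d_slow", "post", "NRG"): (999.14, 826.25),
    ("d_fast", "pre", "RG"): (507.27, 243.43),
    ("d_fast", "pre", "NRG"): (431.76, 216.35),
    ("d_fast", "post", "RG"): (393.50, 239.72),
    ("d_fast", "post", "NRG"): (366.74, 208.56),
    ("pf", "pre", "RG"): (263.71, 68.44),
    ("pf", "pre", "NRG"): (205.60, 56.83),
    ("pf", "post", "RG"): (214.25, 66.55),
    ("pf", "post", "NRG"): (183.48, 54.83),
    ("ktrans", "pre", "RG"): (1226.75, 385.23),
    ("ktrans", "pre", "NRG"): (925.81, 311.04),
    ("ktrans", "post", "RG"): (940.64, 369.19),
    ("ktrans", "post", "NRG"): (762.38, 390.16),
    ("kep", "pre", "RG"): (1398.35, 707.56),
    ("kep", "pre", "NRG"): (1426.62, 961.53),
    ("kep", "post", "RG"): (1104.55, 635.26),
    ("kep", "post", "NRG"): (1353.12, 962.58),
}

#: Pre-treatment node volume (mean, sd) in cm^3 per group.
DEFAULT_VOLUME_PRE_DIST: dict[str, tuple[float, float]] = {
    "RG": (12.26, 9.16),
    "NRG": (9.31, 10.09),
}

#: Percent volume reduction (mean, sd) per group; positive = shrinkage.
DEFAULT_REDUCTION_DIST: dict[str, tuple[float, float]] = {
    "RG": (76.85, 12.89),
    "NRG": (30.99, 17.55),
}

# Physical truncation ranges in internal base units.
_PHYS_RANGE = {
    "adc": (1e-5, 4e-3),
    "md": (1e-5, 4e-3),
    "d_slow": (1e-5, 4e-3),
    "d_fast": (1e-5, 0.5),
    "mk": (0.0, 3.0),
    "pf": (0.0, 1.0),
    "ktrans": (1e-4, 5.0),
    "kep": (0.01, 10.0),
}

# A 30% diameter decrease corresponds to a 1 - 0.7^3 = 65.7% volume decrease
# under sphericity; reduction draws are truncated with a small safety margin
# so generated labels always agree with the RECIST classifier.
_RG_REDUCTION_RANGE = (66.0, 99.9)
_SD_REDUCTION_RANGE = (-72.0, 65.0)
_PD_DIAMETER_FACTOR_RANGE = (1.201, 1.40)



@dataclass(frozen=True)
class PhantomSpec:
    """Full generative description of a synthetic node cohort.

    Parameter distributions are on the reporting scales of the result
    tables; ``noise_sd`` is the Rician noise scale relative to the
    unweighted signal S0 (0.02 corresponds to SNR 50).
    """

    seed: int
    n_rg: int = 52
    n_nrg: int = 42
    n_patients: int = 40
    param_dists: dict = field(default_factory=lambda: dict(DEFAULT_PARAM_DISTS))
    volume_pre_dist: dict = field(default_factory=lambda: dict(DEFAULT_VOLUME_PRE_DIST))
    reduction_dist: dict = field(default_factory=lambda: dict(DEFAULT_REDUCTION_DIST))
    nrg_pd_fraction: float = 0.10
    pre_post_corr: float = 0.5
    noise_sd: float = 0.02

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("seed: must be an integer")
        if self.n_rg < 1:
            raise ConfigurationError("n_rg: must be >= 1")
        if self.n_nrg < 1:
            raise ConfigurationError("n_nrg: must be >= 1")
        if self.n_patients < 1:
            raise ConfigurationError("n_patients: must be >= 1")
        if not 0.0 <= self.nrg_pd_fraction <= 1.0:
            raise ConfigurationError("nrg_pd_fraction: must be in [0, 1]")
        if not -1.0 < self.pre_post_corr < 1.0:
            raise ConfigurationError("pre_post_corr: must be in (-1, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd: must be >= 0")
        for key, (mean, sd) in self.param_dists.items():
            if sd < 0:
                raise ConfigurationError(f"param_dists[{key}]: sd must be >= 0")
            if key[0] not in PARAM_NAMES:
                raise ConfigurationError(f"param_dists[{key}]: unknown parameter")
        for name, dist in (("volume_pre_dist", self.volume_pre_dist),
                           ("reduction_dist", self.reduction_dist)):
            for group, (mean, sd) in dist.items():
                if sd < 0:
                    raise ConfigurationError(f"{name}[{group}]: sd must be >= 0")


@dataclass(frozen=True)
class NodeParams:
    """One node's nine ground-truth parameters in internal base units."""

    adc: float
    md: float
    mk: float
    d_slow: float
    d_fast: float
    pf: float
    ktrans: float
    kep: float
    ve: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}


@dataclass(frozen=True)
class GroundTruthNode:
    node_id: str
    patient_id: str
    group: str  # RG | NRG
    category: str  # CR | PR | SD | PD
    params_pre: NodeParams
    params_post: NodeParams
    diameter_pre: float  # mm, short axis
    diameter_post: float
    volume_pre: float  # cm^3
    volume_post: float


def _truncnorm_ppf(u: np.ndarray, mean: float, sd: float, lo, hi, what: str) -> np.ndarray:
    """Inverse CDF of a normal(mean, sd) truncated to (lo, hi).

    ``lo``/``hi`` may be per-element arrays (for conditional constraints
    like D_fast > D_slow).  With sd = 0 the value is the constant mean,
    which must already lie inside the range.
    """
    from scipy.stats import truncnorm

    lo = np.broadcast_to(np.asarray(lo, dtype=float), u.shape)
    hi = np.broadcast_to(np.asarray(hi, dtype=float), u.shape)
    if sd == 0:
        if np.any(mean <= lo) or np.any(mean >= hi):
            raise ConfigurationError(
                f"{what}: zero-sd mean {mean} outside the physical range"
            )
        return np.full(u.shape, float(mean))
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    if np.any(a >= b):
        raise ConfigurationError(f"{what}: empty truncation range")
    out = truncnorm.ppf(u, a, b, loc=mean, scale=sd)
    # guard against ppf saturating at the bounds in the extreme tails
    return np.clip(out, np.nextafter(lo, hi), np.nextafter(hi, lo))


def _draw_correlated_truncated(
    rng: np.random.Generator,
    n: int,
    pre_ms: tuple[float, float],
    post_ms: tuple[float, float],
    lo,
    hi,
    corr: float,
    what: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n (pre, post) pairs whose marginals are normals truncated to
    (lo, hi), coupled through a Gaussian copula with the given correlation.

    Inverse-CDF sampling keeps the truncated marginals exact even under
    per-node bounds, with no rejection loop to fail in extreme tails.
    """
    beta = math.sqrt(max(0.0, 1.0 - corr**2))
    z1 = rng.standard_normal(n)
    z2 = corr * z1 + beta * rng.standard_normal(n)
    from scipy.stats import norm

    pre = _truncnorm_ppf(norm.cdf(z1), *pre_ms, lo, hi, what)
    post = _truncnorm_ppf(norm.cdf(z2), *post_ms, lo, hi, what)
    return pre, post


def _draw_truncated(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    what: str,
) -> np.ndarray:
    return _truncnorm_ppf(rng.uniform(size=n), mean, sd, lo, hi, what)


def _group_nodes(
    rng: np.random.Generator, spec: PhantomSpec, group: str, n: int
) -> list[dict]:
    """Draw all per-node quantities for one response group."""
    corr = spec.pre_post_corr

    def dist(param: str, tp: str) -> tuple[float, float]:
        try:
            mean, sd = spec.param_dists[(param, tp, group)]
        except KeyError:
            raise ConfigurationError(f"param_dists[({param!r}, {tp!r}, {group!r})]: missing")
        return from_report(mean, param), from_report(sd, param)

    drawn: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for param in ("adc", "md", "mk", "d_slow", "ktrans"):
        lo, hi = _PHYS_RANGE[param]
        drawn[param] = _draw_correlated_truncated(
            rng, n, dist(param, "pre"), dist(param, "post"), lo, hi,
            corr, f"{param}/{group}",
        )
    # pseudo-diffusion must exceed the tissue diffusivity at both timepoints
    drawn["d_fast"] = _draw_correlated_truncated(
        rng, n, dist("d_fast", "pre"), dist("d_fast", "post"),
        np.maximum(drawn["d_slow"][0], drawn["d_slow"][1]), _PHYS_RANGE["d_fast"][1],
        corr, f"d_fast/{group}",
    )
    lo_pf, hi_pf = _PHYS_RANGE["pf"]
    drawn["pf"] = _draw_correlated_truncated(
        rng, n, dist("pf", "pre"), dist("pf", "post"), lo_pf, hi_pf,
        corr, f"pf/{group}",
    )
    # Kep is redrawn conditional on Kep > Ktrans so that Ve = Ktrans/Kep
    # stays in (0, 1]; the Ktrans marginal is left untouched.
    drawn["kep"] = _draw_correlated_truncated(
        rng, n, dist("kep", "pre"), dist("kep", "post"),
        np.maximum(drawn["ktrans"][0], drawn["ktrans"][1]), _PHYS_RANGE["kep"][1],
        corr, f"kep/{group}",
    )

    vol_mean, vol_sd = spec.volume_pre_dist[group]
    volume_pre = _draw_truncated(
        rng, n, vol_mean, vol_sd, 0.3, np.inf, f"volume_pre_dist[{group}]"
    )

    red_mean, red_sd = spec.reduction_dist[group]
    if group == "RG":
        reduction = _draw_truncated(
            rng, n, red_mean, red_sd, *_RG_REDUCTION_RANGE, f"reduction_dist[{group}]"
        )
        categories = np.array(["PR"] * n)
    else:
        reduction = _draw_truncated(
            rng, n, red_mean, red_sd, *_SD_REDUCTION_RANGE, f"reduction_dist[{group}]"
        )
        categories = np.array(["SD"] * n)
        n_pd = int(round(spec.nrg_pd_fraction * n))
        if n_pd > 0:
            pd_idx = rng.permutation(n)[:n_pd]
            factor = rng.uniform(*_PD_DIAMETER_FACTOR_RANGE, size=n_pd)
            reduction[pd_idx] = 100.0 * (1.0 - factor**3)
            categories[pd_idx] = "PD"

    volume_post = volume_pre * (1.0 - reduction / 100.0)

    records = []
    for i in range(n):
        params = {}
        for tp_idx, tp in enumerate(("pre", "post")):
            vals = {p: float(drawn[p][tp_idx][i]) for p in drawn}
            vals["ve"] = vals["ktrans"] / vals["kep"]
            params[tp] = NodeParams(**vals)
        records.append(
            {
                "group": group,
                "category": str(categories[i]),
                "params_pre": params["pre"],
                "params_post": params["post"],
                "volume_pre": float(volume_pre[i]),
                "volume_post": float(volume_post[i]),
            }
        )
    return records


def _sphere_diameter_mm(volume_cm3: float) -> float:
    """Diameter (mm) of the sphere with the given volume (cm^3)."""
    if volume_cm3 <= 0:
        return 0.0
    return 20.0 * (3.0 * volume_cm3 / (4.0 * math.pi)) ** (1.0 / 3.0)


def generate_cohort(spec: PhantomSpec) -> list[GroundTruthNode]:
    """Generate the full two-timepoint cohort described by ``spec``.

    Responders are listed first.  Diameters derive from volumes under
    sphericity, and every node's generated label agrees with
    :func:`~nodemri.nodes.classify_recist` applied to its diameters.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records = _group_nodes(rng, spec, "RG", spec.n_rg)
    records += _group_nodes(rng, spec, "NRG", spec.n_nrg)

    nodes = []
    for i, rec in enumerate(records):
        d_pre = _sphere_diameter_mm(rec["volume_pre"])
        d_post = _sphere_diameter_mm(rec["volume_post"])
        node = GroundTruthNode(
            node_id=f"N{i + 1:03d}",
            patient_id=f"P{(i % spec.n_patients) + 1:02d}",
            diameter_pre=d_pre,
            diameter_post=d_post,
            **rec,
        )
        label = classify_recist(node.diameter_pre, node.diameter_post)
        if label.group != node.group:  # defensive: truncation should preclude this
            raise RuntimeError(
                f"generated node {node.node_id} violates its RECIST label"
            )
        nodes.append(node)
    return nodes


def cohort_to_frame(nodes: list[GroundTruthNode]):
    """Tidy table: one row per node x timepoint, reporting-scale parameters."""
    import pandas as pd

    rows = []
    for node in nodes:
        for tp, params, diam, vol in (
            ("pre", node.params_pre, node.diameter_pre, node.volume_pre),
            ("post", node.params_post, node.diameter_post, node.volume_post),
        ):
            row = {
                "node_id": node.node_id,
                "patient_id": node.patient_id,
                "group": node.group,
                "category": node.category,
                "timepoint": tp,
            }
            row.update(
                {name: to_report(val, name) for name, val in params.as_dict().items()}
            )
            row["diameter_mm"] = diam
            row["volume_cm3"] = vol
            rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------ forward signals


def _rician(rng: np.random.Generator, signal: np.ndarray, sigma: float) -> np.ndarray:
    """Magnitude of (signal + complex Gaussian noise), the MR noise model."""
    re = signal + rng.normal(0.0, sigma, size=signal.shape)
    im = rng.normal(0.0, sigma, size=signal.shape)
    return np.hypot(re, im)


def simulate_diffusion_signal(
    params: NodeParams,
    b_scheme=None,
    model: str = "ivim",
    s0: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> diffusion.DiffusionMeasurement:
    """Forward-simulate one diffusion decay from ground-truth parameters.

    ``model`` selects which parameters drive the decay: "mono" (ADC),
    "dki" (MD, MK) or "ivim" (D_slow, D_fast, PF).  ``noise_sd`` is in
    signal units; noise is Rician (magnitude of a complex Gaussian).
    """
    if s0 <= 0:
        raise DataError("s0 must be positive")
    if b_scheme is None:
        b_scheme = {
            "mono": diffusion.DEFAULT_DWI_BVALUES,
            "dki": diffusion.DEFAULT_DKI_BVALUES,
            "ivim": diffusion.DEFAULT_IVIM_BVALUES,
        }.get(model, diffusion.DEFAULT_IVIM_BVALUES)
    if not isinstance(b_scheme, diffusion.BValueScheme):
        b_scheme = diffusion.BValueScheme(tuple(b_scheme))
    b = b_scheme.as_array()
    if model == "mono":
        clean = diffusion.mono_signal(b, params.adc, s0)
    elif model == "dki":
        clean = diffusion.dki_signal(b, params.md, params.mk, s0)
    elif model == "ivim":
        clean = diffusion.ivim_signal(b, params.d_slow, params.d_fast, params.pf, s0)
    else:
        raise DataError(f"unknown diffusion model {model!r}")
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        clean = _rician(rng, clean, noise_sd)
    return diffusion.DiffusionMeasurement(b_scheme, tuple(clean))


def simulate_dce_series(
    ktrans: float,
    kep: float,
    times=None,
    aif="weinmann",
    noise_sd: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dce.DCESeries:
    """Forward-simulate a tissue concentration curve with Gaussian noise.

    Injection is at t = 0; the default sampling is 4 baseline + 31 dynamic
    frames at 8 s spacing.  ``noise_sd`` is in concentration units (mM).
    """
    if times is None:
        times = dce.default_times()
    times = np.asarray(times, dtype=float)
    conc = dce.tofts_concentration(ktrans, kep, times, aif)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        conc = conc + rng.normal(0.0, noise_sd, size=conc.shape)
    return dce.DCESeries(
        times=tuple(times),
        concentration=tuple(conc),
        n_baseline=int(np.sum(times < 0)),
    )


def render_parameter_maps(
    node: GroundTruthNode,
    timepoint: str = "pre",
    shape: tuple[int, int, int] = (32, 32, 16),
    mask_radius_voxels=8,
    texture_rel_sd: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Paint the node's nine parameters into a 3-D map stack plus ROI mask.

    Each parameter is constant (optionally with multiplicative Gaussian
    texture of relative SD ``texture_rel_sd``) inside an ellipsoidal mask
    centred in the grid; the background is zero.  Returns (maps, mask) in
    internal base units; ``mask_radius_voxels`` may be a scalar or a
    per-axis triple.
    """
    radii = np.broadcast_to(np.asarray(mask_radius_voxels, dtype=float), (3,))
    if np.any(radii <= 0):
        raise DataError("mask_radius_voxels must be positive (mask would be empty)")
    shape = tuple(int(s) for s in shape)
    center = [(s - 1) / 2.0 for s in shape]
    if any(r > c + 0.5 for r, c in zip(radii, center)):
        raise DataError("shape too small to contain the ellipsoidal mask")
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    mask = dist2 <= 1.0
    if not mask.any():
        raise DataError("ROI mask is empty")

    params = node.params_pre if timepoint == "pre" else node.params_post
    if rng is None:
        rng = np.random.default_rng(seed)
    maps: dict[str, np.ndarray] = {}
    n_vox = int(mask.sum())
    for name, value in params.as_dict().items():
        vol = np.zeros(shape, dtype=float)
        vals = np.full(n_vox, value)
        if texture_rel_sd > 0:
            vals = vals * (1.0 + texture_rel_sd * rng.standard_normal(n_vox))
        vol[mask] = vals
        maps[name] = vol
    return maps, mask
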