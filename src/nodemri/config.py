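"""Pipeline configuration: a small validated record loadable from YAML/JSON."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import dce, diffusion
from .errors import ConfigurationError

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; the seed is mandatory.

    ``phantom`` carries overrides for the cohort generator (n_rg, n_nrg,
    noise_sd, ...); unknown keys there are rejected at validation.
    """

    seed: int
    out_dir: str = "results"
    phantom: dict = field(default_factory=dict)
    dwi_bvalues: tuple = diffusion.DEFAULT_DWI_BVALUES
    dki_bvalues: tuple = diffusion.DEFAULT_DKI_BVALUES
    ivim_bvalues: tuple = diffusion.DEFAULT_IVIM_BVALUES
    aif: str = "weinmann"
    ivim_refine: bool = False
    strict_recist: bool = False
    write_maps: bool = False
    map_node_ids: tuple = ()

    _PHANTOM_KEYS = {
        "n_rg", "n_nrg", "n_patients", "nrg_pd_fraction",
        "pre_post_corr", "noise_sd",
    }

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigurationError("seed: required and must be an integer")
        unknown = set(self.phantom) - self._PHANTOM_KEYS
        if unknown:
            raise ConfigurationError(f"phantom: unknown keys {sorted(unknown)}")
        for name in ("dwi_bvalues", "dki_bvalues", "ivim_bvalues"):
            diffusion.BValueScheme(tuple(getattr(self, name)))  # raises if invalid
        if self.aif not in dce.AIF_PRESETS:
            raise ConfigurationError(f"aif: unknown preset {self.aif!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("dwi_bvalues", "dki_bvalues", "ivim_bvalues", "map_node_ids"):
            d[key] = list(d[key])
        return d

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in the run manifest."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML or JSON configuration file into a validated config."""
    import yaml

    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    if "seed" not in raw:
        raise ConfigurationError("seed: required field missing from config")
    known = {f for f in PipelineConfig.__dataclass_fields__ if not f.startswith("_")}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
    for key in ("dwi_bvalues", "dki_bvalues", "ivim_bvalues", "map_node_ids"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg
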