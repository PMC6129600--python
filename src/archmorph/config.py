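"""Analysis configuration: defaults and TOML loading.

All pipeline knobs live in one dataclass so a batch run is fully described
by a single TOML file. Keys mirror the module structure::

    resolution_px_per_mm = 2.0
    threshold = 128.0
    polarity = "light"
    fill_holes = true
    min_component_frac = 0.01
    perimeter_estimator = "boundary_count"

    [gabor]
    k0_mag = 0.7853981633974483
    epsilon = 4.0
    n_orientations = 18
    mag_floor = 0.1

    [curvature]
    sigma_px = 2.5

    [ahi.coefficients]
    beta_p = -7.351e-5
    beta_mbe = -1050.964
    intercept = 0.4597

    [ahi.cutoffs]
    high_max = 0.23
    low_min = 0.27
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .ahi import AhiCoefficients, CutoffScheme, MBEP_SCHEME
from .gabor import GaborParams

__all__ = ["AnalysisConfig", "load_config"]


@dataclass
class AnalysisConfig:
    resolution_px_per_mm: float = 2.0
    threshold: float = 128.0
    polarity: str = "light"
    fill_holes: bool = True
    min_component_frac: float = 0.01
    perimeter_estimator: str = "boundary_count"
    curvature_sigma_px: float = 2.5
    gabor: GaborParams = field(default_factory=GaborParams)
    ahi_coefficients: AhiCoefficients = field(default_factory=AhiCoefficients)
    ahi_cutoffs: CutoffScheme = field(default_factory=lambda: MBEP_SCHEME)

    def to_dict(self) -> dict:
        """Flat echo of the effective configuration (for logging)."""
        d = dataclasses.asdict(self)
        d["gabor"].pop("kernel_support_px", None)
        return d


def load_config(path=None, **overrides) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a TOML file plus overrides.

    ``overrides`` are top-level field names (e.g. ``threshold=100``) and
    win over file values; ``None`` overrides are ignored.
    """
    cfg = AnalysisConfig()
    if path is not None:
        with open(Path(path), "rb") as fh:
            data = tomllib.load(fh)
        for key in (
            "resolution_px_per_mm",
            "threshold",
            "polarity",
            "fill_holes",
            "min_component_frac",
            "perimeter_estimator",
        ):
            if key in data:
                setattr(cfg, key, data[key])
        if "curvature" in data and "sigma_px" in data["curvature"]:
            cfg.curvature_sigma_px = data["curvature"]["sigma_px"]
        if "gabor" in data:
            cfg.gabor = GaborParams(**{k: v for k, v in data["gabor"].items()})
        ahi = data.get("ahi", {})
        if "coefficients" in ahi:
            cfg.ahi_coefficients = AhiCoefficients(**ahi["coefficients"])
        if "cutoffs" in ahi:
            cfg.ahi_cutoffs = CutoffScheme(**{"name": "custom", **ahi["cutoffs"]})
    for key, value in overrides.items():
        if value is None:
            continue
        if not hasattr(cfg, key):
            raise KeyError(f"unknown config key {key!r}")
        setattr(cfg, key, value)
    return cfg
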