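"""Flat pipeline configuration with lossless YAML/JSON round trip."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the registration pipeline, with documented defaults.

    Distances and radii are in pixels, intensities on [0, 1].
    """

    # --- Harris corners + ANMS
    harris_sigma: float = 2.0        # Gaussian window scale of the autocorrelation matrix
    harris_k: float = 0.04           # corner response trace weight
    harris_rel_threshold: float = 0.01  # keep maxima above this fraction of max response
    anms_n: int = 100                # corners kept per image after ANMS
    anms_c_robust: float = 0.9       # robustness damping of the suppression rule

    # --- vessel skeleton + junctions
    vessel_sigma: float = 2.0        # Hessian scale (~ vessel half-width)
    junction_merge_radius: float = 8.0

    # --- shape context
    sc_radius: float = 100.0         # outer log-polar radius R
    sc_n_angle: int = 12
    sc_n_rad: int = 5

    # --- relaxation matching
    relax_window: int = 21           # gradient-descriptor window side (odd)
    relax_search_radius: int = 30    # target search half-width

    # --- matching vectors / merge
    vector_tol_px: float = 10.0      # allowed deviation from the side's matching vector
    merge_anms_n: int = 40           # control pairs kept after ANMS de-clustering

    # --- TPS
    tps_reg_lambda: float = 0.0      # 0 = pure interpolation

    # --- consensus trim of merged control pairs
    trim_enabled: bool = True
    trim_lambda: float = 2000.0      # regularization of the diagnostic smooth fit
    trim_threshold_px: float = 3.0   # allowed deviation from the smooth field

    # --- SOM refinement
    som_enabled: bool = True
    som_grid_size: int = 5           # competition lattice side (odd)
    som_grid_spacing: float = 1.0    # lattice pitch
    som_eta0: float = 0.9            # initial learning rate
    som_sig0: float = 1.0            # initial neighborhood radius
    som_i_max: int = 30              # iteration budget
    som_mi_stride: int = 1           # MI subsampling stride during winner search
    mi_bins: int = 32                # joint-histogram bins

    # --- preprocessing (off by default; acquisition pipelines vary)
    clahe_enabled: bool = False      # optional contrast-limited adaptive equalization
    clahe_clip: float = 0.01

    seed: int = 0                    # drives every stochastic choice (SOM sweep order)

    def __post_init__(self) -> None:
        positive = [
            "harris_sigma", "harris_rel_threshold", "anms_n", "anms_c_robust",
            "vessel_sigma", "junction_merge_radius", "sc_radius", "sc_n_angle",
            "sc_n_rad", "relax_window", "relax_search_radius", "vector_tol_px",
            "merge_anms_n", "som_grid_size", "som_grid_spacing", "som_eta0",
            "som_sig0", "som_i_max", "som_mi_stride", "mi_bins",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tps_reg_lambda < 0:
            raise ValueError("tps_reg_lambda must be >= 0")
        if self.relax_window % 2 == 0:
            raise ValueError("relax_window must be odd")

    # --- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=1))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d or {})
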