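"""Run configuration: one YAML file drives the whole pipeline.

Every stage reads only from the config and its upstream artifacts; the
validated config is serialized into the output directory so a run is fully
reproducible from that directory alone. A single global seed is expanded
into independent per-stage substreams.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator


class ExtentConfig(BaseModel):
    xmin: float = 0.0
    ymin: float = 0.0
    xmax: float = 4000.0
    ymax: float = 4000.0

    @field_validator("xmax")
    @classmethod
    def _x_ok(cls, v, info):
        if v <= info.data.get("xmin", 0.0):
            raise ValueError("xmax must exceed xmin")
        return v

    @field_validator("ymax")
    @classmethod
    def _y_ok(cls, v, info):
        if v <= info.data.get("ymin", 0.0):
            raise ValueError("ymax must exceed ymin")
        return v

    def as_tuple(self):
        return (self.xmin, self.ymin, self.xmax, self.ymax)


class GridConfig(BaseModel):
    cell_size: float = Field(200.0, gt=0)
    origin_x: float | None = None  # default: extent lower-left
    origin_y: float | None = None


class GeneratorConfig(BaseModel):
    n_patches: int = Field(350, ge=10)
    change_fraction: float = Field(0.107, ge=0, lt=1)
    road_spacing: float = Field(500.0, gt=0)
    road_buffer: float = Field(12.0, gt=0)
    tubes_per_cell: int = Field(1, ge=1, le=2)
    jitter: float = Field(20.0, ge=0)
    category_shares: dict[str, float] = {
        "natural": 0.522,
        "agriculture": 0.211,
        "artificial": 0.104,
        "transportation": 0.056,
    }
    dev_share: float = Field(0.616, ge=0, le=1)


class TruthConfig(BaseModel):
    """Data-generating truth: log-odds offsets vs natural land cover.

    Defaults are the surveillance study's parametric odds-ratio estimates on
    the log scale; distance and spatial effects are specified by named
    presets (``none``, ``category_curves``) because arbitrary callables do
    not serialize.
    """

    beta0: float = 0.3527  # logit of the natural-land SIRH rate (1016/1730)
    category_logodds: dict[str, float] = {
        "natural": 0.0,
        "agriculture": float(np.log(2.247)),
        "transportation": float(np.log(1.346)),
        "change": float(np.log(1.354)),
        "artificial": float(np.log(1.251)),
    }
    distance_effect: str = "none"  # one of: none, category_curves
    spatial_effect: str = "none"  # one of: none, sine_field


class ModelConfig(BaseModel):
    k_dist: int = Field(10, ge=4)
    k_spatial: int = Field(6, ge=4)
    lam_bounds: tuple[float, float] = (-6.0, 6.0)
    gcv_sweeps: int = Field(2, ge=1)
    search_tol: float = Field(0.1, gt=0)
    maxiter: int = Field(100, ge=1)
    tol: float = Field(1e-8, gt=0)


class RunConfig(BaseModel):
    seed: int = 0
    extent: ExtentConfig = ExtentConfig()
    grid: GridConfig = GridConfig()
    generator: GeneratorConfig = GeneratorConfig()
    truth: TruthConfig = TruthConfig()
    model: ModelConfig = ModelConfig()
    output_dir: str = "antrisk_out"

    def grid_spec(self):
        from .gridding import GridSpec

        ox = self.grid.origin_x if self.grid.origin_x is not None else self.extent.xmin
        oy = self.grid.origin_y if self.grid.origin_y is not None else self.extent.ymin
        return GridSpec.from_extent(
            ox, oy, self.extent.xmax, self.extent.ymax, self.grid.cell_size
        )

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage substream seed below 2^31."""
        import zlib

        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode()) % (2**31)])
        return int(ss.generate_state(1)[0] % (2**31 - 1))

    def truth_model(self):
        from .surveillance import TrueModel

        g_dist = None
        if self.truth.distance_effect == "category_curves":
            g_dist = default_category_curves()
        elif self.truth.distance_effect != "none":
            raise ValueError(f"unknown distance_effect '{self.truth.distance_effect}'")
        field = None
        if self.truth.spatial_effect == "sine_field":
            field = sine_field(self.extent.as_tuple())
        elif self.truth.spatial_effect != "none":
            raise ValueError(f"unknown spatial_effect '{self.truth.spatial_effect}'")
        return TrueModel(
            beta0=self.truth.beta0,
            category_logodds=dict(self.truth.category_logodds),
            g_dist=g_dist,
            spatial_field=field,
        )


def default_category_curves():
    """Category-specific nonlinear distance effects (log-odds, centered-ish).

    Transportation: elevated risk holding out to ~350 m then declining;
    land-use change: shorter ~150 m halo; other categories flat.
    """
    return {
        "transportation": lambda d: 1.2 / (1.0 + np.exp((d - 350.0) / 40.0)) - 0.6,
        "change": lambda d: 1.2 / (1.0 + np.exp((d - 150.0) / 30.0)) - 0.6,
    }


def sine_field(extent, amplitude: float = 1.0):
    """Smooth doubly periodic spatial log-odds field on the extent."""
    xmin, ymin, xmax, ymax = extent

    def field(x, y):
        u = (np.asarray(x, float) - xmin) / (xmax - xmin)
        v = (np.asarray(y, float) - ymin) / (ymax - ymin)
        return amplitude * np.sin(2 * np.pi * u) * np.cos(2 * np.pi * v)

    return field


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; errors name the offending field path."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        locs = "; ".join(
            ".".join(map(str, e["loc"])) + ": " + e["msg"] for e in err.errors()
        )
        raise ValueError(f"invalid config {path}: {locs}") from err


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False))
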