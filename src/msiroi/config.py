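"""Run configuration: one validated document for the whole pipeline.

Unknown keys are rejected so typos cannot silently fall back to defaults.
A single global seed fans out deterministically to per-stage seeds (hash of
the stage name), keeping stages independently reproducible.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

from .errors import ConfigError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", populate_by_name=True)


class PreprocessConfig(_Strict):
    imzml_path: str | None = None
    pixel_size_um: float | None = None
    smoothing_window: int = 9
    snr: float = 3.0
    alignment_tol: float = 0.05
    min_pixel_freq: float = 0.01
    centroided: bool = False
    tissue_ions: list[float] | None = None    # None: bootstrap from data
    foreground_threshold: str | float = "otsu"


class HistoConfig(_Strict):
    wsi_path: str | None = None
    he_pixel_um: float = 0.5
    backend: str = "classical"                # "classical" | "densenet201"
    weights: str | None = None                # .npz kernels for densenet201
    min_tissue_fraction: float = 0.9
    reference_tile: str | None = None
    from_image: bool = False                  # phantom mode: re-extract HF
                                              # from the rendered H&E image


class RegisterConfig(_Strict):
    enabled: bool = True
    rank: int = 8
    pair_mode: str = "auto"                   # "auto" | "manual"
    manual_pair: tuple[int, int] | None = None  # (hf, msi) 1-based
    correlation_floor: float = 0.3
    mi_bins: int = 32
    bspline_control_spacing_px: float = 8.0


class SegmentConfig(_Strict):
    k_min: int = 2
    k_max: int = 8
    n_pca: int = 50
    n_neighbors: int = 15


class ValidateConfig(_Strict):
    pc: bool = True
    dbi: bool = True
    pc_runs: int = 5
    embed_method: str = "umap"                # "umap" | "pca"


class RoiConfig(_Strict):
    unconfident_alpha: float = 0.5
    top_n_ions: int = 10


class PhantomConfig(_Strict):
    enabled: bool = False
    K_true: int = 4
    grid_rows: int = 60
    grid_cols: int = 60
    n_channels_msi: int = 120
    n_features_hf: int = 64
    msi_noise: float = 0.10
    hf_noise: float = 0.05
    saltpepper_rate: float = 0.01
    deformation_px: float = 2.0
    translation_y: float = 0.0
    translation_x: float = 0.0
    spurious_region: bool = False


class RunConfig(_Strict):
    seed: int = 0
    outdir: str = "msiroi_run"
    preprocess: PreprocessConfig = PreprocessConfig()
    histo: HistoConfig = HistoConfig()
    # "register" and "validate" stay the on-disk keys; the attributes are
    # renamed to avoid shadowing BaseModel API
    registration: RegisterConfig = Field(default_factory=RegisterConfig,
                                         alias="register")
    segment: SegmentConfig = SegmentConfig()
    validation: ValidateConfig = Field(default_factory=ValidateConfig,
                                       alias="validate")
    roi: RoiConfig = RoiConfig()
    phantom: PhantomConfig = PhantomConfig()

    # -- seeds -----------------------------------------------------------
    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)

    # -- I/O -------------------------------------------------------------
    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        try:
            if path.suffix in {".yaml", ".yml"}:
                import yaml
                data = yaml.safe_load(path.read_text()) or {}
            elif path.suffix == ".toml":
                import tomllib
                data = tomllib.loads(path.read_text())
            elif path.suffix == ".json":
                data = json.loads(path.read_text())
            else:
                raise ConfigError(f"unsupported config format {path.suffix}")
            return cls.model_validate(data)
        except ConfigError:
            raise
        except Exception as exc:
            raise ConfigError(f"invalid config {path}: {exc}") from exc

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2, by_alias=True))
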