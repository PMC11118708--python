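"""File formats, configuration schema and run reports.

Numeric payloads round-trip losslessly: CSV floats are written with 17
significant digits, maps travel as NPZ (bit-exact) with optional TIFF
export.  Pixel coordinates in all files are 0-based; visual-field outputs
are in degrees.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "RunConfig",
    "RunReport",
    "SchemaError",
    "read_cell_table",
    "write_cell_table",
    "read_maps",
    "write_maps",
    "write_maps_tiff",
    "read_results",
    "write_results",
    "load_config",
    "save_config",
]

CELL_COLUMNS = ("x_px", "y_px", "po_deg", "injection_id")


class SchemaError(ValueError):
    """A file violated its documented schema."""


class RunConfig(BaseModel):
    """Pipeline configuration; defaults mirror the reference analysis.

    Unknown keys are rejected at load time.
    """

    model_config = ConfigDict(extra="forbid")

    out_dir: str = "v2pool_out"
    seed: int = 0
    # synthetic inputs
    map_height: int = Field(64, gt=0)
    map_width: int = Field(64, gt=0)
    map_noise_sd: float = Field(0.5, ge=0)
    n_cells: int = Field(300, gt=0)
    bias_strength: float = Field(0.6, ge=0, le=1)
    # stage parameters
    n_orientations: int = 8
    sf: float = 1.0
    sigma_x: float = 0.6
    like_to_like_fwhm: float = 22.5
    grid_resolution_deg: float = 0.02
    n_resample: int = 1000
    n_shifts: int = 1500
    texture_size: int = 320
    px_per_deg: float = 100.0
    n_texture_pairs: int = 30
    n_texture_families: int = 2
    n_v1_model_cells: int = 40
    n_v2_model_pixels: int = 20


@dataclass
class RunReport:
    """Provenance of a pipeline run: per-stage parameters, warnings and
    checksummed output files."""

    seed: int
    stages: dict = dc_field(default_factory=dict)
    warnings: list = dc_field(default_factory=list)
    outputs: dict = dc_field(default_factory=dict)  # path -> sha256

    def add_output(self, path: str | Path) -> None:
        p = Path(path)
        self.outputs[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()

    def to_json(self, path: str | Path) -> None:
        payload = {"seed": self.seed, "stages": self.stages,
                   "warnings": self.warnings, "outputs": self.outputs}
        Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_cell_table(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table missing column(s): {', '.join(missing)}")
    df.to_csv(path, index=False, float_format="%.17g")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table missing column(s): {', '.join(missing)}")
    for col in ("x_px", "y_px", "po_deg"):
        bad = df[col].isna()
        if bad.any():
            raise SchemaError(f"cell table column {col!r}: missing value at "
                              f"row {int(np.flatnonzero(bad)[0])}")
    return df


def write_maps(path: str | Path, **planes: np.ndarray) -> None:
    np.savez(path, **planes)


def read_maps(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(path) as z:
        return {k: z[k] for k in z.files}


def write_maps_tiff(path: str | Path, stack: np.ndarray) -> None:
    import tifffile
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def write_results(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def read_results(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
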