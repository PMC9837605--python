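"""File formats, configuration, and seed management.

All on-disk interchange uses plain formats: BIDS-style tab-separated
events files, TSV tables for outcomes / traits / cluster tables, NIfTI-1
for volumes (voxel size and TR carried in the header), YAML for pipeline
configuration, and JSON for ground truth. Voxel indices are 0-based and
world coordinates are RAS+ millimetres throughout.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .task import TaskConfig, TrialSequence, TrialSpec

__all__ = [
    "substream",
    "spawn_rng",
    "default_affine",
    "save_nifti",
    "load_nifti",
    "write_events_tsv",
    "read_events_tsv",
    "sequence_to_frame",
    "frame_to_sequence",
    "write_table",
    "read_table",
    "PipelineConfig",
    "load_config",
    "dump_config",
]

EVENTS_COLUMNS = ["onset", "duration", "trial_type", "block", "word", "ink"]


class FormatError(ValueError):
    """Raised when an on-disk table or header is malformed."""


# ---------------------------------------------------------------------------
# Seed management: one root seed, named substreams per module
# ---------------------------------------------------------------------------


def substream(root_seed: int, name: str) -> int:
    """Derive a deterministic per-module seed (< 2**31) from a root seed.

    Every source of randomness in the pipeline draws its seed through a
    named substream so that partial re-runs of one stage are reproducible
    without re-running the others.
    """
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2**31))


def spawn_rng(root_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(substream(root_seed, name))


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------


def default_affine(shape: Sequence[int], voxel_mm: float) -> np.ndarray:
    """RAS+ affine placing the grid centre at the world origin."""
    shape = np.asarray(shape[:3])
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -(shape - 1) / 2.0 * voxel_mm
    return aff


def save_nifti(
    data: np.ndarray,
    path: str | Path,
    voxel_mm: float = 3.0,
    tr_s: float | None = None,
    affine: np.ndarray | None = None,
) -> Path:
    """Write a 3D or 4D volume with voxel size (and TR, if 4D) in the header."""
    path = Path(path)
    if affine is None:
        affine = default_affine(data.shape, voxel_mm)
    img = nib.Nifti1Image(np.asarray(data), affine)
    zooms = [voxel_mm] * 3
    if data.ndim == 4:
        zooms.append(tr_s if tr_s is not None else 1.0)
        img.header.set_xyzt_units("mm", "sec")
    img.header.set_zooms(zooms)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray, float, float | None]:
    """Load a volume; returns (data, affine, voxel_mm, tr_s or None)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"NIfTI volume not found: {path}")
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    vx = float(zooms[0])
    if not np.allclose(zooms[:3], vx, rtol=1e-6):
        raise FormatError(f"{path}: anisotropic voxels unsupported {zooms[:3]}")
    tr = float(zooms[3]) if len(zooms) > 3 else None
    return np.asarray(img.dataobj), img.affine, vx, tr


def check_common_grid(shapes: Sequence[tuple], paths: Sequence[str | Path]) -> None:
    """Raise if subject volumes do not share one grid."""
    ref = shapes[0]
    for shp, p in zip(shapes, paths):
        if tuple(shp[:3]) != tuple(ref[:3]):
            raise FormatError(
                f"grid mismatch: {p} has shape {shp[:3]}, expected {ref[:3]}"
            )


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing required column(s): {', '.join(missing)}")


def sequence_to_frame(seq: TrialSequence) -> pd.DataFrame:
    cfg = seq.config
    return pd.DataFrame(
        {
            "onset": [t.onset_s for t in seq.trials],
            "duration": [cfg.trial_s] * len(seq),
            "trial_type": [t.trial_type for t in seq.trials],
            "block": [t.block for t in seq.trials],
            "word": [t.word for t in seq.trials],
            "ink": [t.ink for t in seq.trials],
        }
    )


def frame_to_sequence(df: pd.DataFrame, config: TaskConfig) -> TrialSequence:
    _require_columns(df, EVENTS_COLUMNS, "events table")
    trials = tuple(
        TrialSpec(
            block=int(r.block),
            trial_index=i,
            trial_type=str(r.trial_type),
            onset_s=float(r.onset),
            word=str(r.word),
            ink=str(r.ink),
        )
        for i, r in enumerate(df.itertuples())
    )
    return TrialSequence(config=config, trials=trials)


def write_events_tsv(seq: TrialSequence, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sequence_to_frame(seq).to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, EVENTS_COLUMNS, f"events file {path}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    """Write any pipeline table as TSV (dot decimal, UTF-8)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_table(
    path: str | Path, required: Sequence[str] | None = None, what: str | None = None
) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if required is not None:
        _require_columns(df, required, what or f"table {path}")
    return df


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")
    return path


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PipelineConfig:
    """Resolved configuration for a full pipeline run.

    Section dictionaries mirror the keyword arguments of the module-level
    parameter dataclasses; unknown keys are rejected at load time.
    """

    rng_seed: int = 0
    out_dir: str = "eat_out"
    log_level: str = "INFO"
    n_subjects: int = 30
    task: dict = dataclasses.field(default_factory=dict)
    behavior: dict = dataclasses.field(default_factory=dict)
    neuro: dict = dataclasses.field(default_factory=dict)
    traits: dict = dataclasses.field(default_factory=dict)
    analysis: dict = dataclasses.field(default_factory=dict)

    def frozen_copy_path(self) -> Path:
        return Path(self.out_dir) / "resolved_config.yaml"


_ANALYSIS_KEYS = {
    "fir_window_s",
    "drift_order",
    "voxel_p",
    "alpha",
    "n_iter",
    "connectivity",
    "min_volume_uL",
    "n_boot",
    "n_folds",
}


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    cfg = PipelineConfig(**raw)
    bad = set(cfg.analysis) - _ANALYSIS_KEYS
    if bad:
        raise FormatError(f"unknown analysis key(s): {', '.join(sorted(bad))}")
    return cfg


def dump_config(cfg: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True))
    return path
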