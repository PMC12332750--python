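"""File formats, configuration and run manifests.

Canonical on-disk dialects: NIfTI-1 (.nii/.nii.gz, RAS+ affine) for images
and masks, CSV for cohort/cluster/prediction tables, JSON for manifests
and reports, YAML for the pipeline configuration.  Voxel indices are
0-based internally; reported coordinates are always millimetres.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "save_image",
    "load_image",
    "save_stack",
    "read_gmv_stack",
    "save_cohort",
    "load_cohort",
    "cluster_table",
]

COHORT_COLUMNS = ["id", "group", "age", "sex", "education", "site", "hamd17", "hama14"]


@dataclass
class PipelineConfig:
    """One structured config drives all stages; CLI flags override fields."""

    images_dir: str = "images"
    mask_path: str = "mask.nii.gz"
    cohort_csv: str = "cohort.csv"
    output_dir: str = "output"
    voxel_p: float = 0.001
    cluster_q: float = 0.05
    sc_q: float = 0.05
    screen_alpha: float = 0.05
    svr_C: float = 10.0
    svr_epsilon: float = 0.1
    n_perm: int = 1000
    cluster_n_perm: int = 100
    covariates: list = field(default_factory=lambda: ["age", "sex", "education"])
    connectivity: int = 26
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("voxel_p", "cluster_q", "sc_q", "screen_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.n_perm < 1 or self.cluster_n_perm < 1:
            raise ValueError("permutation counts must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunManifest:
    """Provenance record written before and finalised after each stage."""

    stage: str
    config: dict
    seed: int
    started: str = ""
    finished: str = ""
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    version: str = ""

    def start(self) -> "RunManifest":
        from anxvbm import __version__

        self.version = __version__
        self.started = time.strftime("%Y-%m-%dT%H:%M:%S")
        return self

    def add_input(self, name: str, path) -> None:
        self.inputs[name] = {"path": str(path), "sha256": _file_hash(path)}

    def add_output(self, name: str, path) -> None:
        self.outputs[name] = {"path": str(path), "sha256": _file_hash(path)}

    def finalize(self, path) -> None:
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def save_image(data: np.ndarray, affine: np.ndarray, path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    nib.save(img, str(path))


def load_image(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64), img.affine


def save_stack(stack, affine, cohort: pd.DataFrame, out_dir) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for row, vol in zip(cohort.itertuples(), stack):
        p = out_dir / f"{row.id}_gmv.nii.gz"
        save_image(vol, affine, p)
        paths.append(p)
    return paths


def read_gmv_stack(images_dir, cohort: pd.DataFrame,
                   atol: float = 1e-4) -> tuple[np.ndarray, np.ndarray]:
    """Load one NIfTI per cohort id, in cohort row order.

    All images must share grid shape and affine (within ``atol``); offenders
    are listed in the error.
    """
    images_dir = Path(images_dir)
    vols, affine, shape = [], None, None
    bad = []
    for sid in cohort["id"]:
        p = images_dir / f"{sid}_gmv.nii.gz"
        if not p.exists():
            raise FileNotFoundError(f"missing GMV image for subject {sid}: {p}")
        data, aff = load_image(p)
        if affine is None:
            affine, shape = aff, data.shape
        else:
            if data.shape != shape or not np.allclose(aff, affine, atol=atol):
                bad.append(sid)
        vols.append(data)
    if bad:
        raise ValueError(f"grid/affine mismatch for subjects: {bad}")
    return np.stack(vols), affine


def save_cohort(cohort: pd.DataFrame, path) -> None:
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


def load_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    return df


def cluster_table(clusters, statistic_name: str = "peak_stat") -> pd.DataFrame:
    """Cluster report: size, peak MNI mm coordinates, peak statistic."""
    rows = []
    for c in clusters:
        rows.append(
            {
                "cluster_size_voxels": c.size,
                "peak_mni_x": c.peak_mni[0],
                "peak_mni_y": c.peak_mni[1],
                "peak_mni_z": c.peak_mni[2],
                statistic_name: c.peak_value,
                "p_value": c.p_value,
                "p_adjusted": c.p_adjusted,
                "label": c.label,
            }
        )
    return pd.DataFrame(rows)
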