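"""File I/O: NIfTI volumes, fMRIPrep-style confound TSVs, gene tables, config.

Volumetric data travels as NIfTI-1; tabular data as TSV with fixed headers;
configuration as a flat YAML mapping that round-trips unchanged and rejects
unknown keys.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .datatypes import CONFOUND_COLUMNS, MOTION_COLUMNS, BoldSession, GeneExpressionMap, Parcellation

CONFOUND_TSV_COLUMNS = MOTION_COLUMNS + CONFOUND_COLUMNS


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[[0, 1, 2], [0, 1, 2]] = np.asarray(voxel_size_mm, dtype=float)
    return aff


def write_bold(session: BoldSession, bold_path, confounds_path, mask_path=None) -> None:
    """Write a session as 4-D NIfTI plus a confound TSV (fMRIPrep dialect)."""
    aff = _affine(session.voxel_size_mm)
    img = nib.Nifti1Image(session.data.astype(np.float32), aff)
    img.header.set_zooms((*session.voxel_size_mm, session.tr_s))
    nib.save(img, str(bold_path))
    table = pd.concat([session.motion, session.confounds], axis=1)
    table.to_csv(confounds_path, sep="\t", index=False)
    if mask_path is not None:
        nib.save(nib.Nifti1Image(session.mask.astype(np.uint8), aff), str(mask_path))


def read_bold(
    bold_path, confounds_path, mask_path=None, tr_s: float | None = None,
    subject_id: str = "sub-01", condition_id: str = "baseline",
) -> BoldSession:
    """Read a 4-D BOLD NIfTI and its confound TSV into a session.

    The TSV must carry the six motion columns and csf / white_matter /
    global_signal (extra columns such as framewise_displacement are
    ignored).  Row count must equal the number of frames.
    """
    img = nib.load(str(bold_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{bold_path}: expected 4-D BOLD, got shape {data.shape}")
    zooms = img.header.get_zooms()
    voxel_size = np.asarray(zooms[:3], dtype=float)
    if tr_s is None:
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.5
    table = pd.read_csv(confounds_path, sep="\t")
    missing = [c for c in CONFOUND_TSV_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{confounds_path}: missing columns {missing}")
    if len(table) != data.shape[3]:
        raise ValueError(
            f"confound table has {len(table)} rows but BOLD has {data.shape[3]} frames"
        )
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mask = np.asarray(mimg.dataobj) > 0
        if mask.shape != data.shape[:3]:
            raise ValueError(
                f"mask shape {mask.shape} does not match BOLD spatial shape {data.shape[:3]}"
            )
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BoldSession(
        data=data,
        tr_s=tr_s,
        mask=mask,
        confounds=table[CONFOUND_COLUMNS].copy(),
        motion=table[MOTION_COLUMNS].copy(),
        subject_id=subject_id,
        condition_id=condition_id,
        voxel_size_mm=voxel_size,
        history=["loaded"],
    )


def write_map(values: np.ndarray, path, voxel_size_mm=(3.0, 3.0, 3.0)) -> None:
    """Write a 3-D map (integer lFCD counts or float log map) as NIfTI-1."""
    values = np.asarray(values)
    dtype = np.int32 if np.issubdtype(values.dtype, np.integer) else np.float32
    nib.save(nib.Nifti1Image(values.astype(dtype), _affine(voxel_size_mm)), str(path))


def read_map(path) -> np.ndarray:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.int32)
    return arr.astype(float)


def write_parcellation(parc: Parcellation, labels_path, table_path) -> None:
    nib.save(
        nib.Nifti1Image(parc.label_volume.astype(np.int32), _affine(parc.voxel_size_mm)),
        str(labels_path),
    )
    parc.region_table.to_csv(table_path, sep="\t", index=False)


def read_parcellation(labels_path, table_path) -> Parcellation:
    img = nib.load(str(labels_path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    table = pd.read_csv(table_path, sep="\t")
    vsize = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return Parcellation(label_volume=labels, region_table=table, voxel_size_mm=vsize)


def write_gene_maps(maps: dict, path) -> None:
    rows = [
        {"region_id": rid, "gene": g.gene_name, "value": v}
        for g in maps.values()
        for rid, v in zip(g.region_ids, g.values)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_maps(path, expected_region_ids=None) -> dict:
    """Read a (region_id, gene, value) TSV into GeneExpressionMap objects.

    When ``expected_region_ids`` is given, any gene missing one of those
    regions raises with the absent ids listed.
    """
    table = pd.read_csv(path, sep="\t")
    need = {"region_id", "gene", "value"}
    if not need <= set(table.columns):
        raise ValueError(f"{path}: gene table needs columns {sorted(need)}")
    out = {}
    for gene, sub in table.groupby("gene", sort=False):
        sub = sub.sort_values("region_id")
        if expected_region_ids is not None:
            absent = sorted(set(np.asarray(expected_region_ids).tolist()) - set(sub["region_id"]))
            if absent:
                raise ValueError(f"gene {gene}: missing region ids {absent}")
        out[gene] = GeneExpressionMap(
            gene_name=str(gene),
            values=sub["value"].to_numpy(float),
            region_ids=sub["region_id"].to_numpy(int),
        )
    return out


@dataclass
class PipelineConfig:
    """All stage parameters, defaulting to the study's stated values."""

    data_dir: str = "data"
    out_dir: str = "results"
    # simulation
    grid_shape: tuple = (12, 12, 10)
    n_regions: int = 60
    n_subcortical: int = 8
    n_cerebellar: int = 6
    n_subjects: int = 15
    n_conditions: int = 3
    n_frames: int = 120
    tr_s: float = 2.5
    voxel_size_mm: float = 3.0
    hub_strength: float = 0.9
    ar_coef: float = 0.3
    n_hub_regions: int = 2
    effect_size: float = 0.15
    gene_length_scale_mm: float = 30.0
    genes: tuple = ("PVALB", "SST", "HTR3A")
    planted_gene: str = "SST"
    planted_r: float = -0.5
    # preprocessing
    low_hz: float = 0.01
    high_hz: float = 0.1
    fwhm_mm: float = 6.0
    spike_threshold_mm: float = 0.5
    mfd_threshold_mm: float = 0.3
    head_radius_mm: float = 50.0
    # lFCD
    r_threshold: float = 0.6
    connectivity: int = 6
    log_base: str = "natural"
    # group statistics
    alpha: float = 0.05
    d_variant: str = "paired_dz"
    # transcriptomics
    n_surrogates: int = 5000
    variogram_bins: int = 25
    kernel_scales: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.high_hz >= 1.0 / (2.0 * self.tr_s):
            raise ValueError(
                f"high_hz {self.high_hz} Hz is at or above the Nyquist frequency "
                f"{1.0 / (2.0 * self.tr_s)} Hz for TR {self.tr_s} s"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("grid_shape", "genes", "kernel_scales"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run: inputs, config, stages, output checksums."""

    config: dict
    input_hashes: dict = field(default_factory=dict)
    stage_order: list = field(default_factory=list)
    qc: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)

    def register_output(self, name: str, path) -> None:
        self.outputs[name] = {"path": str(path), "sha256": sha256_file(path)}

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
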