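"""Core in-memory containers shared across pipeline stages.

Each container is a thin validated dataclass around numpy/pandas objects:
a labeled brain parcellation, a single resting-state BOLD acquisition with
its nuisance signals, regional gene-expression vectors, and the
subjects x conditions x regions array that group statistics consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
CONFOUND_COLUMNS = ["csf", "white_matter", "global_signal"]
COMPARTMENTS = ("cortical", "subcortical", "cerebellar")


@dataclass
class Parcellation:
    """Integer label volume plus a per-region lookup table.

    ``label_volume`` uses 0 for background and contiguous ids 1..R for
    regions.  ``region_table`` has one row per region with columns
    ``region_id``, ``name``, ``compartment`` and ``network``.
    ``voxel_size_mm`` is the physical voxel size along each axis.
    """

    label_volume: np.ndarray
    region_table: pd.DataFrame
    voxel_size_mm: np.ndarray = field(default_factory=lambda: np.array([3.0, 3.0, 3.0]))

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        if self.label_volume.ndim != 3:
            raise ValueError("label_volume must be 3-D")
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)
        ids = np.asarray(self.region_table["region_id"])
        if not np.array_equal(np.sort(ids), np.arange(1, len(ids) + 1)):
            raise ValueError("region ids must be contiguous 1..R")
        present = np.unique(self.label_volume)
        present = present[present > 0]
        missing = set(present) - set(ids.tolist())
        if missing:
            raise ValueError(f"label volume contains ids absent from region table: {sorted(missing)}")
        counts = np.bincount(self.label_volume.ravel(), minlength=len(ids) + 1)[1:]
        if (counts == 0).any():
            empty = (np.nonzero(counts == 0)[0] + 1).tolist()
            raise ValueError(f"regions with zero voxels: {empty}")
        bad = set(self.region_table["compartment"]) - set(COMPARTMENTS)
        if bad:
            raise ValueError(f"unknown compartments: {sorted(bad)}")

    @property
    def n_regions(self) -> int:
        return len(self.region_table)

    @property
    def region_ids(self) -> np.ndarray:
        return np.asarray(self.region_table["region_id"], dtype=int)

    def ids_in_compartment(self, compartment: str) -> np.ndarray:
        tab = self.region_table
        return np.asarray(tab.loc[tab["compartment"] == compartment, "region_id"], dtype=int)


@dataclass
class BoldSession:
    """One 4-D BOLD acquisition with its nuisance tables.

    ``data`` is (x, y, z, t); ``mask`` marks in-brain voxels; ``confounds``
    carries the csf / white_matter / global_signal columns and ``motion``
    the six rigid-body parameters (translations in mm, rotations in rad),
    one row per frame each.  ``history`` records the processing stages
    applied so far, in order.
    """

    data: np.ndarray
    tr_s: float
    mask: np.ndarray
    confounds: pd.DataFrame
    motion: pd.DataFrame
    subject_id: str = "sub-01"
    condition_id: str = "baseline"
    voxel_size_mm: np.ndarray = field(default_factory=lambda: np.array([3.0, 3.0, 3.0]))
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, t)")
        if self.n_frames < 2:
            raise ValueError("a BOLD session needs at least 2 frames")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must equal the spatial shape of data")
        for name, tab, cols in (
            ("confounds", self.confounds, CONFOUND_COLUMNS),
            ("motion", self.motion, MOTION_COLUMNS),
        ):
            if list(tab.columns) != cols:
                raise ValueError(f"{name} must have columns {cols}, got {list(tab.columns)}")
            if len(tab) != self.n_frames:
                raise ValueError(
                    f"{name} has {len(tab)} rows but the session has {self.n_frames} frames"
                )

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray, stage: str) -> "BoldSession":
        """Return a copy holding new voxel data, appending ``stage`` to history."""
        return replace(self, data=np.asarray(data, dtype=float), history=[*self.history, stage])


@dataclass
class GeneExpressionMap:
    """One regional expression vector (one value per cortical region)."""

    gene_name: str
    values: np.ndarray
    region_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        if self.values.shape != self.region_ids.shape or self.values.ndim != 1:
            raise ValueError("values and region_ids must be 1-D and equally long")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"gene map {self.gene_name} contains non-finite values")


@dataclass
class ConditionDataset:
    """Subjects x conditions x regions array of regional log(lFCD).

    ``covariates`` has one row per subject (``sex``, ``genotype``);
    ``scores`` holds the per-subject, per-condition stimulant/sedation
    summaries and ``mfd`` the matching mean framewise displacements,
    both shaped (subjects, conditions).
    """

    values: np.ndarray
    condition_names: list
    region_ids: np.ndarray
    covariates: pd.DataFrame | None = None
    scores: dict | None = None
    mfd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        if self.values.ndim != 3:
            raise ValueError("values must be (subjects, conditions, regions)")
        if self.values.shape[1] != len(self.condition_names):
            raise ValueError("condition_names length must match axis 1")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 conditions")
        if self.values.shape[2] != len(self.region_ids):
            raise ValueError("region_ids length must match axis 2")
        if not np.all(np.isfinite(self.values)):
            s, c, r = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"missing cell at subject {s}, condition {c}, region {r}")
        if self.covariates is not None and len(self.covariates) != self.n_subjects:
            raise ValueError("one covariate row per subject required")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    @property
    def n_regions(self) -> int:
        return self.values.shape[2]

    def condition_index(self, name: str) -> int:
        try:
            return self.condition_names.index(name)
        except ValueError:
            raise KeyError(f"unknown condition {name!r}; have {self.condition_names}") from None
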