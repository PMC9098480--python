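"""Local functional connectivity density (lFCD) mapping.

lFCD of a seed voxel is the size of the contiguous cluster of voxels, grown
outward from the seed, whose time series correlate with the *seed* above a
threshold (r > 0.6 by default) while remaining spatially connected (face
adjacency by default).  Counts are log-transformed — degree-like measures
are roughly exponential, and the log brings them to a semi-normal scale —
then averaged within parcellation regions to give regional profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.sparse.csgraph import connected_components

from .datatypes import BoldSession, ConditionDataset, Parcellation

logger = logging.getLogger(__name__)

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class LfcdMap:
    """Voxelwise cluster sizes on the session mask.

    ``values`` holds the integer cluster size for in-mask voxels and 0
    elsewhere; every in-mask voxel has lFCD >= 1 because the seed counts
    itself.
    """

    values: np.ndarray
    mask: np.ndarray
    r_threshold: float
    connectivity: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if (self.values[self.mask] < 1).any():
            raise ValueError("in-mask lFCD must be >= 1 (seed counts itself)")


@dataclass
class RegionalProfile:
    """Per-region mean log(lFCD) for one scan."""

    values: np.ndarray
    region_ids: np.ndarray
    missing: np.ndarray
    subject_id: str = "sub-01"
    condition_id: str = "baseline"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject_id,
                "condition": self.condition_id,
                "region_id": self.region_ids,
                "value": self.values,
            }
        )


def _neighbor_offsets(connectivity: int) -> np.ndarray:
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    rank = _CONNECTIVITY_RANK[connectivity]
    offs = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0) and abs(i) + abs(j) + abs(k) <= rank
    ]
    return np.array(offs)


def _masked_zscores(session: BoldSession, min_var: float = 1e-12):
    """Standardized in-mask time series; zero-variance voxels are dropped."""
    mask = session.mask.copy()
    flat = session.data[mask]
    var = flat.var(axis=1)
    dead = var <= min_var
    if dead.any():
        logger.info("dropping %d zero-variance voxels from the mask", int(dead.sum()))
        idx = np.nonzero(mask)
        keep = ~dead
        mask = np.zeros_like(mask)
        mask[idx[0][keep], idx[1][keep], idx[2][keep]] = True
        flat = flat[keep]
    if not mask.any():
        raise ValueError("empty brain mask after removing zero-variance voxels")
    z = flat - flat.mean(axis=1, keepdims=True)
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    return z, mask


def compute_lfcd(
    session: BoldSession,
    r_threshold: float = 0.6,
    connectivity: int = 6,
    seed_mode: str = "seed",
) -> LfcdMap:
    """Voxelwise lFCD by seeded region growing.

    ``seed_mode='seed'`` (default): a voxel joins the cluster when it is
    adjacent to a cluster member and correlates with the *seed* above
    threshold — equivalently, lFCD(seed) is the size of the connected
    component containing the seed in the super-threshold mask defined
    relative to that seed.  ``seed_mode='chained'`` is a sensitivity
    variant in which adjacency edges require the two *neighboring* voxels
    to correlate above threshold; all voxels in one chained component then
    share the same lFCD.
    """
    if not 0.0 < r_threshold < 1.0:
        raise ValueError(f"r_threshold must be in (0, 1), got {r_threshold}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    z, mask = _masked_zscores(session)
    coords = np.nonzero(mask)
    n = z.shape[0]
    corr = np.clip(z @ z.T, -1.0, 1.0)
    values = np.zeros(mask.shape, dtype=np.int32)

    if seed_mode == "chained":
        adj = _adjacency(mask, _neighbor_offsets(connectivity))
        adj = adj.multiply(corr > r_threshold)
        _, labels = connected_components(adj, directed=False)
        sizes = np.bincount(labels)
        values[coords] = sizes[labels]
        return LfcdMap(values, mask, r_threshold, connectivity)
    if seed_mode != "seed":
        raise ValueError(f"seed_mode must be 'seed' or 'chained', got {seed_mode!r}")

    vol = np.zeros(mask.shape, dtype=bool)
    out = np.zeros(n, dtype=np.int32)
    for i in range(n):
        qual = corr[i] > r_threshold
        qual[i] = True  # the seed always belongs to its own cluster
        vol[:] = False
        vol[coords[0][qual], coords[1][qual], coords[2][qual]] = True
        labeled, _ = ndimage.label(vol, structure=structure)
        out[i] = np.count_nonzero(labeled == labeled[coords[0][i], coords[1][i], coords[2][i]])
    values[coords] = out
    return LfcdMap(values, mask, r_threshold, connectivity)


def _adjacency(mask: np.ndarray, offsets: np.ndarray) -> sparse.csr_matrix:
    """Sparse voxel adjacency restricted to the mask."""
    idx_vol = -np.ones(mask.shape, dtype=np.int64)
    coords = np.argwhere(mask)
    idx_vol[tuple(coords.T)] = np.arange(len(coords))
    rows, cols = [], []
    for off in offsets:
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < mask.shape), axis=1)
        j = idx_vol[tuple(nb[ok].T)]
        valid = j >= 0
        rows.append(np.arange(len(coords))[ok][valid])
        cols.append(j[valid])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    n = len(coords)
    return sparse.csr_matrix((np.ones(rows.size, dtype=bool), (rows, cols)), shape=(n, n))


def lfcd_oracle(
    session: BoldSession, r_threshold: float = 0.6, connectivity: int = 6
) -> LfcdMap:
    """Brute-force reference: full correlation matrix + per-seed BFS.

    Intended for small grids (up to ~10^4 in-mask voxels).  For each seed,
    breadth-first search over the graph whose nodes are in-mask voxels
    correlating with the seed above threshold and whose edges are the
    chosen spatial adjacency.
    """
    if not 0.0 < r_threshold < 1.0:
        raise ValueError(f"r_threshold must be in (0, 1), got {r_threshold}")
    z, mask = _masked_zscores(session)
    n = z.shape[0]
    if n > 10_000:
        raise ValueError("oracle is restricted to small grids (<= 10^4 in-mask voxels)")
    corr = np.clip(z @ z.T, -1.0, 1.0)
    adj = _adjacency(mask, _neighbor_offsets(connectivity))
    neighbors = np.split(adj.indices, adj.indptr[1:-1])
    out = np.zeros(n, dtype=np.int32)
    for seed in range(n):
        qual = corr[seed] > r_threshold
        qual[seed] = True
        visited = {seed}
        frontier = [seed]
        while frontier:
            nxt = []
            for u in frontier:
                for v in neighbors[u]:
                    v = int(v)
                    if qual[v] and v not in visited:
                        visited.add(v)
                        nxt.append(v)
            frontier = nxt
        out[seed] = len(visited)
    values = np.zeros(mask.shape, dtype=np.int32)
    values[np.nonzero(mask)] = out
    return LfcdMap(values, mask, r_threshold, connectivity)


def log_transform(lfcd: LfcdMap, base: str = "natural") -> np.ndarray:
    """Elementwise log of the cluster-size map; lFCD = 1 maps to 0."""
    vals = lfcd.values[lfcd.mask]
    if (vals < 1).any():
        raise ValueError("encountered in-mask lFCD < 1; map is inconsistent")
    out = np.zeros(lfcd.values.shape, dtype=float)
    if base == "natural":
        out[lfcd.mask] = np.log(vals)
    elif base == "10":
        out[lfcd.mask] = np.log10(vals)
    else:
        raise ValueError(f"base must be 'natural' or '10', got {base!r}")
    return out


def parcellate_map(
    log_map: np.ndarray,
    parcellation: Parcellation,
    mask: np.ndarray,
    subject_id: str = "sub-01",
    condition_id: str = "baseline",
) -> RegionalProfile:
    """Unweighted in-mask mean of the log map within each region.

    Regions without any in-mask voxel get NaN and are flagged missing.
    """
    log_map = np.asarray(log_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    labels = parcellation.label_volume
    if log_map.shape != labels.shape or mask.shape != labels.shape:
        raise ValueError(
            f"shape mismatch: map {log_map.shape}, mask {mask.shape}, labels {labels.shape}"
        )
    n = parcellation.n_regions
    lab = labels[mask]
    vals = log_map[mask]
    sums = np.bincount(lab, weights=vals, minlength=n + 1)[1:]
    counts = np.bincount(lab, minlength=n + 1)[1:]
    missing = counts == 0
    means = np.full(n, np.nan)
    means[~missing] = sums[~missing] / counts[~missing]
    return RegionalProfile(
        values=means,
        region_ids=parcellation.region_ids,
        missing=missing,
        subject_id=subject_id,
        condition_id=condition_id,
    )


def motion_lfcd_check(profiles: ConditionDataset, mfd: np.ndarray | None = None) -> dict:
    """Diagnostic: per-region correlation between regional log(lFCD) and mFD.

    Pools all scans (subjects x conditions) and reports each region's
    Pearson r against mean framewise displacement, plus the mean of signed
    and of absolute coefficients.  Purely descriptive — a small mean
    indicates little residual motion contamination; nothing is gated on it.
    """
    if mfd is None:
        mfd = profiles.mfd
    mfd = np.asarray(mfd, dtype=float).ravel()
    vals = profiles.values.reshape(-1, profiles.n_regions)
    if vals.shape[0] != mfd.size:
        raise ValueError("need one mFD per subject x condition scan")
    if mfd.size < 3:
        raise ValueError("need at least 3 scans to correlate")
    if np.ptp(mfd) == 0:
        logger.warning("mFD has zero variance; motion-lFCD correlations undefined")
        r = np.full(profiles.n_regions, np.nan)
    else:
        zm = (mfd - mfd.mean()) / mfd.std()
        zv = vals - vals.mean(axis=0)
        sd = zv.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (zv / np.where(sd == 0, np.nan, sd)).T @ zm / mfd.size
    with np.errstate(invalid="ignore"):
        return {
            "per_region_r": r,
            "mean_r": float(np.nanmean(r)) if np.isfinite(r).any() else float("nan"),
            "mean_abs_r": float(np.nanmean(np.abs(r))) if np.isfinite(r).any() else float("nan"),
        }
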