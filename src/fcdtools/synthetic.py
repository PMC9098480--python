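"""Synthetic-data generators for every pipeline input.

The generators emulate the structure of a pharmacological resting-state
study — a volumetric parcellation, multi-subject multi-condition BOLD
acquisitions with planted synchronized hubs, realistic motion traces, and
spatially autocorrelated regional gene-expression maps — so every
downstream stage can be exercised and calibrated without any real scans.

All generators are deterministic given their parameters and seed; calls
that create several entities derive one independent sub-stream per entity
from the master seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal
from scipy.spatial.distance import cdist

from .datatypes import (
    CONFOUND_COLUMNS,
    MOTION_COLUMNS,
    BoldSession,
    ConditionDataset,
    GeneExpressionMap,
    Parcellation,
)

DEFAULT_SHAPE = (12, 12, 10)
DEFAULT_N_FRAMES = 120
DEFAULT_TR_S = 2.5


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent 31-bit sub-seeds from a master seed."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) >> 1


def make_parcellation(
    shape: tuple,
    n_regions: int,
    seed: int,
    n_subcortical: int = 0,
    n_cerebellar: int = 0,
    voxel_size_mm: float | tuple = 3.0,
) -> Parcellation:
    """Voronoi partition of a voxel grid around random sites.

    Region ids 1..n_regions are assigned by nearest random site (ties to
    the lowest id), guaranteeing contiguous non-empty regions.  The last
    ``n_subcortical`` + ``n_cerebellar`` ids get those compartment labels;
    the rest are cortical, cycled through seven network names.
    """
    shape = tuple(int(s) for s in shape)
    n_voxels = int(np.prod(shape))
    if n_regions < 1 or n_regions > n_voxels:
        raise ValueError(f"n_regions must be in [1, {n_voxels}], got {n_regions}")
    if n_subcortical + n_cerebellar > n_regions:
        raise ValueError("compartment counts exceed n_regions")
    rng = _rng(seed)
    coords = np.indices(shape).reshape(3, -1).T
    sites = coords[rng.choice(n_voxels, size=n_regions, replace=False)]
    labels = np.argmin(cdist(coords, sites), axis=1) + 1
    label_volume = labels.reshape(shape).astype(np.int32)

    n_cortical = n_regions - n_subcortical - n_cerebellar
    compartments = (
        ["cortical"] * n_cortical
        + ["subcortical"] * n_subcortical
        + ["cerebellar"] * n_cerebellar
    )
    networks = [
        f"net_{i % 7 + 1}" if comp == "cortical" else comp
        for i, comp in enumerate(compartments)
    ]
    table = pd.DataFrame(
        {
            "region_id": np.arange(1, n_regions + 1),
            "name": [f"region_{i:03d}" for i in range(1, n_regions + 1)],
            "compartment": compartments,
            "network": networks,
        }
    )
    vsize = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,)).copy()
    return Parcellation(label_volume=label_volume, region_table=table, voxel_size_mm=vsize)


def make_motion_trace(
    n_frames: int,
    spike_frames: tuple = (),
    spike_mm: float = 0.0,
    seed: int = 0,
    walk_step_mm: float = 0.01,
    walk_step_rad: float = 1e-4,
) -> pd.DataFrame:
    """Smooth random-walk head motion with optional step displacements.

    Translations follow a Gaussian random walk of per-frame step SD
    ``walk_step_mm`` (rotations: ``walk_step_rad``).  Each frame in
    ``spike_frames`` adds a sustained step of ``spike_mm`` on the x
    translation, so framewise displacement at that frame jumps by
    ``spike_mm``.  Frame 0 cannot host a spike: FD of the first frame is
    zero by convention, so a spike there would be undetectable.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    spike_frames = tuple(int(f) for f in spike_frames)
    if any(f <= 0 or f >= n_frames for f in spike_frames):
        raise ValueError("spike frames must lie in [1, n_frames); frame 0 has FD 0 by convention")
    rng = _rng(seed)
    steps = np.concatenate(
        [
            rng.normal(0.0, walk_step_mm, size=(n_frames, 3)),
            rng.normal(0.0, walk_step_rad, size=(n_frames, 3)),
        ],
        axis=1,
    )
    steps[0] = 0.0
    trace = np.cumsum(steps, axis=0)
    for f in spike_frames:
        trace[f:, 0] += spike_mm
    return pd.DataFrame(trace, columns=MOTION_COLUMNS)


def _band_limited_latent(n_frames: int, tr_s: float, rng: np.random.Generator,
                         band=(0.01, 0.08)) -> np.ndarray:
    """Unit-variance latent signal confined to a low-frequency band.

    Built by band-pass filtering white noise with a zero-phase Butterworth
    filter so planted synchrony survives the pipeline's own band-pass.
    Falls back to a slow sinusoid mixture when the series is too short to
    filter stably.
    """
    fs = 1.0 / tr_s
    nyq = fs / 2.0
    low, high = band
    x = rng.standard_normal(n_frames + 200)
    if high < nyq * 0.95 and n_frames >= 30:
        sos = signal.butter(2, [low / nyq, high / nyq], btype="band", output="sos")
        y = signal.sosfiltfilt(sos, x)[100 : 100 + n_frames]
    else:  # pragma: no cover - degenerate sampling rates
        t = np.arange(n_frames) * tr_s
        y = np.sin(2 * np.pi * low * t + rng.uniform(0, 2 * np.pi))
    sd = y.std()
    if sd < 1e-12:  # pragma: no cover
        return np.zeros(n_frames)
    return (y - y.mean()) / sd


def _ar1(shape: tuple, coef: float, rng: np.random.Generator) -> np.ndarray:
    """AR(1) noise with unit marginal variance along the last axis."""
    n = shape[-1]
    innov_sd = np.sqrt(max(1.0 - coef**2, 1e-12))
    out = np.empty(shape)
    out[..., 0] = rng.standard_normal(shape[:-1])
    eps = rng.normal(0.0, innov_sd, size=shape)
    for t in range(1, n):
        out[..., t] = coef * out[..., t - 1] + eps[..., t]
    return out


def tissue_blocks(shape: tuple, block: int = 2) -> tuple:
    """Fixed corner blocks serving as CSF and white-matter 'tissue' masks.

    The generator owns its tissue definition: two ``block``-sized corner
    cubes excluded from the brain mask stand in for the segmented CSF and
    WM compartments a surface pipeline would provide.
    """
    csf = np.zeros(shape, dtype=bool)
    wm = np.zeros(shape, dtype=bool)
    csf[:block, :block, :block] = True
    wm[-block:, -block:, -block:] = True
    return csf, wm


def make_bold_session(
    parcellation: Parcellation,
    hub_regions: tuple = (),
    hub_strength: float = 0.0,
    ar_coef: float = 0.3,
    n_frames: int = DEFAULT_N_FRAMES,
    tr_s: float = DEFAULT_TR_S,
    seed: int = 0,
    subject_id: str = "sub-01",
    condition_id: str = "baseline",
    motion: pd.DataFrame | None = None,
) -> BoldSession:
    """Simulate one BOLD acquisition with a planted synchronized hub.

    Every voxel receives unit-variance AR(1) noise with coefficient
    ``ar_coef``.  Voxels inside ``hub_regions`` are mixed with a shared
    band-limited latent signal: voxel = h * latent + sqrt(1 - h^2) * noise
    with h = ``hub_strength``, so hub pairs correlate at about h^2 (the
    noise variance is 1 - h^2; at h = 1 the noise vanishes and hub
    correlations are exactly 1).  The confound table is computed from the
    fixed CSF/WM corner blocks and the in-mask global mean.
    """
    if not 0.0 <= hub_strength <= 1.0:
        raise ValueError(f"hub_strength must be in [0, 1], got {hub_strength}")
    if not 0.0 <= ar_coef < 1.0:
        raise ValueError(f"ar_coef must be in [0, 1), got {ar_coef}")
    ids = set(parcellation.region_ids.tolist())
    hub_regions = tuple(int(r) for r in hub_regions)
    if not set(hub_regions) <= ids:
        raise ValueError(f"hub_regions {sorted(set(hub_regions) - ids)} not in parcellation")

    shape = parcellation.label_volume.shape
    s_noise, s_latent, s_motion = _child_seeds(seed, 3)
    rng = _rng(s_noise)
    noise = _ar1((*shape, n_frames), ar_coef, rng)
    data = noise.copy()

    latent = _band_limited_latent(n_frames, tr_s, _rng(s_latent))
    hub_mask = np.isin(parcellation.label_volume, hub_regions)
    h = hub_strength
    data[hub_mask] = h * latent + np.sqrt(1.0 - h**2) * noise[hub_mask]

    csf_vox, wm_vox = tissue_blocks(shape)
    mask = ~(csf_vox | wm_vox)
    confounds = pd.DataFrame(
        {
            "csf": data[csf_vox].mean(axis=0),
            "white_matter": data[wm_vox].mean(axis=0),
            "global_signal": data[mask].mean(axis=0),
        },
        columns=CONFOUND_COLUMNS,
    )
    if motion is None:
        motion = make_motion_trace(n_frames, seed=int(s_motion))
    return BoldSession(
        data=data,
        tr_s=tr_s,
        mask=mask,
        confounds=confounds,
        motion=motion,
        subject_id=subject_id,
        condition_id=condition_id,
        voxel_size_mm=parcellation.voxel_size_mm,
        history=["simulated"],
    )


def make_gene_map(
    distances: np.ndarray,
    length_scale_mm: float,
    seed: int,
    region_ids: np.ndarray | None = None,
    gene_name: str = "GENE",
    max_jitter: float = 1e-4,
) -> GeneExpressionMap:
    """Gaussian random field over region centroids with exponential covariance.

    Draws one value per region from N(0, C) with C_ij = exp(-d_ij / L),
    L = ``length_scale_mm``, via Cholesky factorization.  Small diagonal
    jitter is escalated until the factorization succeeds; exceeding
    ``max_jitter`` raises with the jitter used.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.ndim != 2 or distances.shape[0] != distances.shape[1]:
        raise ValueError("distances must be a square matrix")
    if not np.allclose(distances, distances.T) or np.any(np.diag(distances) != 0):
        raise ValueError("distances must be symmetric with zero diagonal")
    if length_scale_mm <= 0:
        raise ValueError("length_scale_mm must be positive")
    n = distances.shape[0]
    cov = np.exp(-distances / length_scale_mm)
    jitter = 0.0
    while True:
        try:
            chol = np.linalg.cholesky(cov + jitter * np.eye(n))
            break
        except np.linalg.LinAlgError:
            jitter = 1e-10 if jitter == 0.0 else jitter * 10
            if jitter > max_jitter:
                raise np.linalg.LinAlgError(
                    f"covariance not positive definite even with jitter {jitter:g}"
                ) from None
    values = chol @ _rng(seed).standard_normal(n)
    if region_ids is None:
        region_ids = np.arange(1, n + 1)
    return GeneExpressionMap(gene_name=gene_name, values=values, region_ids=np.asarray(region_ids))


def make_condition_study(
    n_subjects: int,
    n_conditions: int,
    region_effects: np.ndarray,
    subject_sd: float = 0.2,
    noise_sd: float = 0.3,
    gene_coupling: tuple | None = None,
    seed: int = 0,
    condition_names: list | None = None,
    region_ids: np.ndarray | None = None,
) -> ConditionDataset:
    """Regional log(lFCD) study with known per-condition effects.

    values[s, c, r] = subject_intercept(s) + region_effects[c, r] + noise,
    with subject intercepts ~ N(0, subject_sd^2) and i.i.d. N(0, noise_sd^2)
    noise.  When ``gene_coupling = (gene_map, slope)`` is given, the
    contrast of the last condition against the first is rebuilt as
    slope * z(expression) + sqrt(1 - slope^2) * residual (both
    standardized), so the planted spatial correlation between that
    condition contrast and the expression map equals ``slope`` exactly in
    the effect field.  Subject covariates (sex, genotype), behavioral
    summaries and per-scan mFD values are drawn from neutral distributions.
    """
    if n_conditions < 2:
        raise ValueError("need at least 2 conditions")
    region_effects = np.asarray(region_effects, dtype=float)
    if region_effects.shape[0] != n_conditions:
        raise ValueError(
            f"region_effects must be (n_conditions, n_regions), got {region_effects.shape}"
        )
    n_regions = region_effects.shape[1]
    region_effects = region_effects.copy()

    s_noise, s_subj, s_resid, s_cov = _child_seeds(seed, 4)
    if gene_coupling is not None:
        gene_map, slope = gene_coupling
        if not -1.0 <= slope <= 1.0:
            raise ValueError("gene_coupling slope is a correlation; must be in [-1, 1]")
        expr = np.asarray(gene_map.values, dtype=float)
        if expr.shape[0] != n_regions:
            raise ValueError("gene map length must equal n_regions")
        z_expr = (expr - expr.mean()) / expr.std()
        resid = _rng(s_resid).standard_normal(n_regions)
        z_resid = (resid - resid.mean()) / resid.std()
        # Exactly decorrelate the residual from the expression map so the
        # planted field correlation is slope, not slope + sampling error.
        z_resid = z_resid - (z_resid @ z_expr / (z_expr @ z_expr)) * z_expr
        z_resid /= z_resid.std()
        amplitude = np.abs(region_effects[-1] - region_effects[0]).mean() or 1.0
        contrast = amplitude * (slope * z_expr + np.sqrt(1.0 - slope**2) * z_resid)
        region_effects[-1] = region_effects[0] + contrast

    rng = _rng(s_noise)
    intercepts = _rng(s_subj).normal(0.0, subject_sd, size=n_subjects)
    values = (
        intercepts[:, None, None]
        + region_effects[None, :, :]
        + rng.normal(0.0, noise_sd, size=(n_subjects, n_conditions, n_regions))
    )

    cov_rng = _rng(s_cov)
    covariates = pd.DataFrame(
        {
            "subject": [f"sub-{i + 1:02d}" for i in range(n_subjects)],
            "sex": cov_rng.choice(["F", "M"], size=n_subjects),
            "genotype": cov_rng.choice(["ADH1B*1", "ADH1B*2"], size=n_subjects),
        }
    )
    scores = {
        "stimulant": cov_rng.normal(3.0, 1.0, size=(n_subjects, n_conditions)),
        "sedation": cov_rng.normal(3.0, 1.0, size=(n_subjects, n_conditions)),
    }
    mfd = np.abs(cov_rng.normal(0.12, 0.05, size=(n_subjects, n_conditions)))
    if condition_names is None:
        base = ["baseline", "post_0min", "post_90min"]
        condition_names = (
            base[:n_conditions]
            if n_conditions <= 3
            else base + [f"cond_{i}" for i in range(3, n_conditions)]
        )
    if region_ids is None:
        region_ids = np.arange(1, n_regions + 1)
    return ConditionDataset(
        values=values,
        condition_names=list(condition_names),
        region_ids=np.asarray(region_ids),
        covariates=covariates,
        scores=scores,
        mfd=mfd,
    )
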