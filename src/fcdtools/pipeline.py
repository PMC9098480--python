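"""End-to-end driver: simulate a study, then run every analysis stage.

``simulate_study`` writes all pipeline inputs (parcellation, per-scan BOLD
NIfTI + confound TSVs, gene-expression table, covariates) to a dataset
directory.  ``run_pipeline`` consumes such a directory and executes
denoise -> lFCD -> parcellation -> repeated-measures ANOVA / FDR /
post-hocs / effect maps -> surrogate gene tests, writing TSV/JSON results
and a manifest with checksums of every output.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import fcd, group_stats, preprocess, synthetic, transcriptomics
from .datatypes import ConditionDataset
from .io import (
    PipelineConfig,
    RunManifest,
    read_bold,
    read_gene_maps,
    read_parcellation,
    sha256_file,
    write_bold,
    write_gene_maps,
    write_parcellation,
)

logger = logging.getLogger(__name__)

CONDITION_NAMES = ["baseline", "post_0min", "post_90min"]


def _condition_names(n: int) -> list:
    return CONDITION_NAMES[:n] + [f"cond_{i}" for i in range(3, n)]


def simulate_study(config: PipelineConfig) -> Path:
    """Generate and write every input the analysis pipeline needs.

    The planted structure emulates the study design: a hub whose synchrony
    rises at the middle condition and returns at the last, and one gene
    map spatially coupled (at ``planted_r``) to the middle-vs-first
    condition contrast of the regional effect field.
    """
    data_dir = Path(config.data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    s_parc, s_genes, s_scan, s_study = (int(s) for s in master.generate_state(4, dtype=np.uint32) >> 1)

    parc = synthetic.make_parcellation(
        config.grid_shape,
        config.n_regions,
        seed=s_parc,
        n_subcortical=config.n_subcortical,
        n_cerebellar=config.n_cerebellar,
        voxel_size_mm=config.voxel_size_mm,
    )
    write_parcellation(parc, data_dir / "parcellation.nii.gz", data_dir / "regions.tsv")

    distances = transcriptomics.region_distances(parc, "cortical")
    gene_seeds = np.random.SeedSequence(s_genes).generate_state(len(config.genes), dtype=np.uint32) >> 1
    gene_maps = {
        name: synthetic.make_gene_map(
            distances.matrix,
            config.gene_length_scale_mm,
            seed=int(gs),
            region_ids=distances.region_ids,
            gene_name=name,
        )
        for name, gs in zip(config.genes, gene_seeds)
    }
    write_gene_maps(gene_maps, data_dir / "gene_maps.tsv")

    cortical_ids = distances.region_ids
    hub_regions = tuple(int(r) for r in cortical_ids[: config.n_hub_regions])
    cond_names = _condition_names(config.n_conditions)
    # Hub synchrony rises immediately after administration and relaxes back.
    strength = {name: 0.0 for name in cond_names}
    strength[cond_names[1]] = config.hub_strength
    if len(cond_names) > 2:
        strength[cond_names[2]] = config.hub_strength / 3.0

    scan_seeds = np.random.SeedSequence(s_scan).generate_state(
        config.n_subjects * config.n_conditions, dtype=np.uint32
    ) >> 1
    index_rows = []
    k = 0
    for s in range(config.n_subjects):
        sub = f"sub-{s + 1:02d}"
        for cond in cond_names:
            sess = synthetic.make_bold_session(
                parc,
                hub_regions=hub_regions,
                hub_strength=strength[cond],
                ar_coef=config.ar_coef,
                n_frames=config.n_frames,
                tr_s=config.tr_s,
                seed=int(scan_seeds[k]),
                subject_id=sub,
                condition_id=cond,
            )
            sdir = data_dir / sub
            sdir.mkdir(exist_ok=True)
            bold = sdir / f"{cond}_bold.nii.gz"
            conf = sdir / f"{cond}_confounds.tsv"
            write_bold(sess, bold, conf, sdir / f"{cond}_mask.nii.gz" if k == 0 else None)
            index_rows.append(
                {
                    "subject": sub,
                    "condition": cond,
                    "bold": str(bold.relative_to(data_dir)),
                    "confounds": str(conf.relative_to(data_dir)),
                }
            )
            k += 1
    pd.DataFrame(index_rows).to_csv(data_dir / "sessions.tsv", sep="\t", index=False)

    cov_rng = np.random.default_rng(s_study)
    pd.DataFrame(
        {
            "subject": [f"sub-{i + 1:02d}" for i in range(config.n_subjects)],
            "sex": cov_rng.choice(["F", "M"], size=config.n_subjects),
            "genotype": cov_rng.choice(["ADH1B*1", "ADH1B*2"], size=config.n_subjects),
        }
    ).to_csv(data_dir / "covariates.tsv", sep="\t", index=False)
    score_rows = []
    for s in range(config.n_subjects):
        for c, cond in enumerate(cond_names):
            sedation = 2.0 + (1.5 if c > 0 else 0.0) + cov_rng.normal(0, 0.8)
            score_rows.append(
                {
                    "subject": f"sub-{s + 1:02d}",
                    "condition": cond,
                    "stimulant": 3.0 + cov_rng.normal(0, 0.8),
                    "sedation": sedation,
                }
            )
    pd.DataFrame(score_rows).to_csv(data_dir / "scores.tsv", sep="\t", index=False)
    config.to_yaml(data_dir / "config.yaml")
    return data_dir


def profiles_to_dataset(profiles: list, covariates=None, mfd=None) -> ConditionDataset:
    """Stack per-scan RegionalProfiles into a subjects x conditions x regions array."""
    frame = pd.concat([p.to_frame() for p in profiles], ignore_index=True)
    subjects = sorted(frame["subject"].unique())
    conditions = list(dict.fromkeys(frame["condition"]))
    region_ids = profiles[0].region_ids
    cube = np.full((len(subjects), len(conditions), len(region_ids)), np.nan)
    pivot = frame.set_index(["subject", "condition", "region_id"])["value"]
    for i, s in enumerate(subjects):
        for j, c in enumerate(conditions):
            cube[i, j] = pivot.loc[s, c].reindex(region_ids).to_numpy()
    return ConditionDataset(
        values=cube,
        condition_names=conditions,
        region_ids=region_ids,
        covariates=covariates,
        mfd=mfd,
    )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis on a simulated (or compatible) dataset."""
    data_dir = Path(config.data_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())
    for name in ("sessions.tsv", "regions.tsv", "gene_maps.tsv"):
        manifest.input_hashes[name] = sha256_file(data_dir / name)

    parc = read_parcellation(data_dir / "parcellation.nii.gz", data_dir / "regions.tsv")
    sessions = pd.read_csv(data_dir / "sessions.tsv", sep="\t")
    cond_names = list(dict.fromkeys(sessions["condition"]))

    t0 = time.time()
    profiles, qc_rows = [], []
    mfd_by_scan = {}
    for row in sessions.itertuples():
        sess = read_bold(
            data_dir / row.bold,
            data_dir / row.confounds,
            tr_s=config.tr_s,
            subject_id=row.subject,
            condition_id=row.condition,
        )
        csf_vox, wm_vox = synthetic.tissue_blocks(sess.data.shape[:3])
        sess.mask &= ~(csf_vox | wm_vox)
        denoised, qc = preprocess.denoise(
            sess,
            spike_threshold_mm=config.spike_threshold_mm,
            low_hz=config.low_hz,
            high_hz=config.high_hz,
            fwhm_mm=config.fwhm_mm,
            head_radius_mm=config.head_radius_mm,
        )
        qc_rows.append(qc)
        mfd_by_scan[(row.subject, row.condition)] = qc["mfd_mm"]
        lfcd_map = fcd.compute_lfcd(
            denoised, r_threshold=config.r_threshold, connectivity=config.connectivity
        )
        log_map = fcd.log_transform(lfcd_map, base=config.log_base)
        profiles.append(
            fcd.parcellate_map(
                log_map, parc, lfcd_map.mask, subject_id=row.subject, condition_id=row.condition
            )
        )
    logger.info("denoise+lFCD for %d scans took %.1f s", len(profiles), time.time() - t0)
    manifest.stage_order += ["denoise", "lfcd", "parcellate"]
    manifest.qc = qc_rows
    pd.DataFrame(qc_rows).to_json(out_dir / "qc.json", orient="records", indent=2)
    manifest.register_output("qc", out_dir / "qc.json")

    covariates = pd.read_csv(data_dir / "covariates.tsv", sep="\t")
    subjects = sorted(sessions["subject"].unique())
    mfd = np.array([[mfd_by_scan[(s, c)] for c in cond_names] for s in subjects])
    dataset = profiles_to_dataset(profiles, covariates=covariates, mfd=mfd)
    prof_frame = pd.concat([p.to_frame() for p in profiles], ignore_index=True)
    prof_frame.to_csv(out_dir / "regional_profiles.tsv", sep="\t", index=False)
    manifest.register_output("regional_profiles", out_dir / "regional_profiles.tsv")

    motion_diag = fcd.motion_lfcd_check(dataset)
    anova = group_stats.rm_anova(dataset, alpha=config.alpha)
    anova.to_csv(out_dir / "rm_anova.tsv", sep="\t", index=False)
    manifest.register_output("rm_anova", out_dir / "rm_anova.tsv")
    significant_ids = anova.loc[anova["significant"], "region_id"].tolist()
    posthoc = group_stats.posthoc_pairwise(dataset, regions=significant_ids or None)
    posthoc.to_csv(out_dir / "posthoc.tsv", sep="\t", index=False)
    manifest.register_output("posthoc", out_dir / "posthoc.tsv")
    manifest.stage_order += ["rm_anova", "posthoc", "effect_maps", "gene_tests"]

    contrasts = [(cond_names[0], cond_names[1])]
    if len(cond_names) > 2:
        contrasts.append((cond_names[0], cond_names[2]))
    d_maps = {}
    for pair in contrasts:
        dmap = group_stats.cohens_d_map(dataset, pair, variant=config.d_variant)
        d_maps[f"{pair[0]}_to_{pair[1]}"] = dmap
    pd.concat(d_maps.values(), ignore_index=True).to_csv(
        out_dir / "effect_maps.tsv", sep="\t", index=False
    )
    manifest.register_output("effect_maps", out_dir / "effect_maps.tsv")

    scores = pd.read_csv(data_dir / "scores.tsv", sep="\t")
    behavior = _behavior_block(dataset, scores, cond_names, significant_ids)
    if behavior is not None:
        behavior.to_csv(out_dir / "behavior_correlation.tsv", sep="\t", index=False)
        manifest.register_output("behavior_correlation", out_dir / "behavior_correlation.tsv")

    cortical_ids = parc.ids_in_compartment("cortical")
    distances = transcriptomics.region_distances(parc, "cortical")
    gene_maps = read_gene_maps(data_dir / "gene_maps.tsv", expected_region_ids=cortical_ids)
    cortical_pos = np.searchsorted(dataset.region_ids, cortical_ids)
    effect_maps = {
        name: dmap["d"].to_numpy()[cortical_pos] for name, dmap in d_maps.items()
    }
    gene_seed_base = np.random.SeedSequence(config.seed).generate_state(1, dtype=np.uint32)[0] >> 1
    ensembles = {
        gene: transcriptomics.surrogate_ensemble(
            gmap.values,
            distances,
            n_surrogates=config.n_surrogates,
            seed=int(gene_seed_base) + gi,
            kernel_scales=config.kernel_scales,
            n_bins=config.variogram_bins,
            source_name=gene,
        )
        for gi, (gene, gmap) in enumerate(gene_maps.items())
    }
    family = transcriptomics.test_family(effect_maps, gene_maps, ensembles, alpha=config.alpha)
    family.to_csv(out_dir / "gene_tests.tsv", sep="\t", index=False)
    manifest.register_output("gene_tests", out_dir / "gene_tests.tsv")

    summary = {
        "n_scans": len(profiles),
        "n_regions": int(parc.n_regions),
        "n_significant_regions": len(significant_ids),
        "significant_region_ids": significant_ids,
        "motion_lfcd_mean_r": motion_diag["mean_r"],
        "motion_lfcd_mean_abs_r": motion_diag["mean_abs_r"],
        "gene_tests": family.drop(columns=["n_surrogates"]).to_dict(orient="records"),
    }
    (out_dir / "summary.json").write_text(pd.Series(summary).to_json(indent=2))
    manifest.register_output("summary", out_dir / "summary.json")
    manifest.write(out_dir / "manifest.json")
    return manifest


def _behavior_block(dataset, scores, cond_names, significant_ids):
    """Correlate regional change (middle vs first condition) with sedation change."""
    if len(cond_names) < 2 or dataset.n_subjects < 4:
        return None
    pivot = scores.pivot_table(index="subject", columns="condition", values="sedation")
    subjects = sorted(pivot.index)
    delta_score = (pivot[cond_names[1]] - pivot[cond_names[0]]).loc[subjects].to_numpy()
    delta_profile = dataset.values[:, 1, :] - dataset.values[:, 0, :]
    ids = dataset.region_ids
    if significant_ids:
        pos = np.searchsorted(ids, significant_ids)
        delta_profile = delta_profile[:, pos]
        ids = np.asarray(significant_ids)
    table = group_stats.behavior_correlation(delta_profile, delta_score)
    table["region_id"] = ids[table["region_index"].to_numpy()]
    return table
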