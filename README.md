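# fcdtools

Analysis pipeline for **pharmacological resting-state fMRI**: it maps how an
acute intervention (e.g. an intravenous alcohol clamp) changes local
functional connectivity density (lFCD) across the brain, and relates the
regional pattern of those changes to cortical gene-expression profiles of
GABAergic interneuron subtypes (PVALB, SST, HTR3A) with statistically
calibrated spatial permutation tests.

It is written for imaging neuroscientists who have fMRIPrep-style
preprocessed BOLD data (or none at all — a synthetic-data generator
produces a full study with known ground truth) and want a tested,
reproducible implementation of this analysis chain:

1. **Denoising** — framewise-displacement QC (exclude mFD > 0.3 mm),
   36-parameter confound regression (CSF/WM/global + 6 motion, derivatives,
   squares) with spike regressors for frames with FD > 0.5 mm, zero-phase
   0.01–0.1 Hz band-pass, mask-normalized 6 mm FWHM Gaussian smoothing.
2. **lFCD mapping** — for each seed voxel, the size of the contiguous
   cluster of voxels correlating with the seed at r > 0.6 (face adjacency);
   log-transformed and averaged within parcellation regions.
3. **Group statistics** — region-wise one-way repeated-measures ANOVA
   across conditions, F = MS_cond / MS_(cond×subj) with df (C−1, (C−1)(S−1)),
   BH-FDR across regions, Bonferroni paired post-hocs, paired Cohen's dz
   effect maps, behavioral correlations, subgroup (sex/genotype) contrasts.
4. **Imaging transcriptomics** — Pearson correlation between a cortical
   effect-size map and each gene-expression map, with significance from
   variogram-matched surrogate maps (default 5000 per gene) that preserve
   the gene map's spatial autocorrelation; two-sided permutation p with
   add-one correction, BH-FDR over the gene × contrast family.

See `docs/methods.md` for the full model description, parameter rationale
and limitations.

## Worked example

```python
import numpy as np
from fcdtools import synthetic, preprocess, fcd

# a 12x12x10 study grid with 40 Voronoi regions; regions 17 and 31 carry
# a shared band-limited signal (hub strength 0.9 -> pairwise r ~ 0.81)
parc = synthetic.make_parcellation((12, 12, 10), 40, seed=11)
sess = synthetic.make_bold_session(parc, hub_regions=(17, 31),
                                   hub_strength=0.9, n_frames=120, seed=1)

denoised, qc = preprocess.denoise(sess)
print(qc)           # {'subject_id': 'sub-01', 'condition_id': 'baseline',
                    #  'mfd_mm': 0.035, 'n_spike_frames': 0, 'excluded': False}

lfcd_map = fcd.compute_lfcd(denoised, r_threshold=0.6)
log_map = fcd.log_transform(lfcd_map)
profile = fcd.parcellate_map(log_map, parc, lfcd_map.mask)
print(np.round(profile.values[[16, 30]], 2))          # [4.52 4.49]
print(round(float(np.nanmean(profile.values)), 2))    # 2.22
```

The planted hub regions show mean log(lFCD) ≈ 4.5 — clusters of ~90 voxels,
the whole synchronized hub — against a background average of 2.2 (~9-voxel
clusters produced by smoothing-induced local correlation). The motion QC
shows a quiet scan (mFD 0.035 mm, no spike frames, not excluded).

The same chain runs from the shell on NIfTI/TSV inputs:

```bash
fcdtools simulate --config config.yaml          # write a synthetic study
fcdtools run --config config.yaml --no-simulate # denoise -> lFCD -> stats -> genes
fcdtools lfcd --in bold.nii.gz --confounds conf.tsv \
         --parcellation labels.nii.gz --regions regions.tsv --out profile.tsv
```

`run` writes TSV/JSON results (`rm_anova.tsv`, `effect_maps.tsv`,
`gene_tests.tsv`, `summary.json`, …) plus a manifest with a checksum of
every output; reruns with the same config and seed are byte-identical.

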