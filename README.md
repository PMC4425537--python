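# ratlas-ia — atlas-based bilateral anisotropy analysis of rat-brain concussion

Concussions at different sites on the cortex produce strikingly similar
clinical outcomes, which raises the question of whether disparate cortical
impacts injure the *same* subcortical gray-matter structures.  This package
implements an analysis pipeline built to answer that question in the rat
fluid-percussion injury (FPI) model: diffusion-anisotropy and T2 maps are
computed from raw volumes, registered into a 3D segmented bilateral atlas,
and each brain region's concussed (ipsilateral) hemisphere is compared with
the non-concussed (contralateral) hemisphere within animal.  Regions whose
anisotropy indices shift significantly are rank-ordered, and the sets
detected after rostral and caudal impacts are intersected to find the
common vulnerable nuclei.

It is aimed at preclinical imaging groups who want a transparent, fully
deterministic reference implementation of this workflow, with a synthetic
phantom generator standing in for animal data so that every stage is
testable end to end.

## The model

From each diffusion-weighted acquisition (10 non-collinear directions at
b = 1000 s/mm², one b0; 96×96×60 at 0.313 mm isotropic) a tensor **D** is
fit per voxel by log-linear least squares on

&nbsp;&nbsp;&nbsp;&nbsp;S(g, b) = S₀ · exp(−b·gᵀ**D**g)

With eigenvalues λ₁ ≥ λ₂ ≥ λ₃ (10⁻³ mm²/s) the anisotropy indices are

- **AD** (axial diffusivity) = λ₁
- **RD** (radial diffusivity) = (λ₂ + λ₃)/2
- **ADC / MD** = (λ₁ + λ₂ + λ₃)/3
- **FA** = √(3/2) · √( Σᵢ(λᵢ − ADC)² / Σᵢλᵢ² )

T2 is estimated per voxel from 16 echoes at 11 ms spacing by nonlinear
least squares on y(t) = A + C·e^(−t/T2); the edematous lesion is the
connected component of the T2-weighted hyperintensity within an absolute
intensity window (default 6300–9000), grown from a seed point, with volume
= voxel count × voxel volume.  Subjects are aligned to the atlas by a
6-parameter rigid transform maximizing normalized cross-correlation of the
b0 images; index maps are resampled trilinearly, labels only ever by
nearest neighbour.  Per region the pipeline reports hemisphere means ± SD,
a two-tailed paired t-test across animals, a direction arrow (↑ =
ipsilateral larger), and rank-orders rows by p.  A summary-statistic t-test
(pooled or Welch) reproduces printed tables, and Benjamini–Hochberg
q-values are available alongside the raw p-values.

## Worked example

The numbered scripts under `analysis/` run the whole study on a phantom
cohort (a 24³ desk-scale version of the full acquisition) and write their
tables under `results/`:

```bash
python analysis/01_generate_phantom_study.py
python analysis/02_dti_index_maps.py
python analysis/03_lesion_volumetry.py
python analysis/04_bilateral_region_tables.py
python analysis/05_common_regions.py
python analysis/06_histology_od.py
```

Step 03 prints, for the default seed:

```
lesion volume: 11.93 mm^3 (389 voxels, 6.90% of brain)
ground truth:  11.93 mm^3
median T2 inside lesion: 89.9 ms (healthy tissue: 50 ms)
```

i.e. seeded region growing recovers the simulated 11.93 mm³ edema exactly —
inside the 9–14 mm³ range characteristic of mild-to-moderate contusions.
Step 04 simulates an injured cohort (n = 5) carrying the FA shifts of three
published table rows and prints the rank-ordered bilateral table:

```
           region_name  contra_mean  ipsi_mean arrow          t        p        q
 laterodorsal thalamus     0.437433   0.285603     ↓ -36.552294 0.000003 0.000010
      central amygdala     0.422695   0.585852     ↑  30.859707 0.000007 0.000010
CA1 dorsal hippocampus     0.353121   0.419094     ↑  15.844195 0.000093 0.000093
```

All three seeded regions are detected with the planted direction: the
central amygdala FA rises from ~0.42 to ~0.59 ipsilaterally, the
laterodorsal thalamus falls, and CA1 rises.  Step 05 intersects the
transcribed published tables across injury sites and reports the four FA
regions significant after both insults, flagging the lateral amygdala as
the lone direction-inconsistent exception.

A `ratlas-ia` command-line interface wraps the same stages
(`fixtures`, `dti`, `lesion`, `register`, `run`); see `ratlas-ia --help`.

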