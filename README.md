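# phagoquant

Rule-based quantification of high-content microglial assays, plus the
statistics used for GFP-Trap TMT interactome screens — implemented as a
tested, reusable Python pipeline and validated end to end on synthetic
fields with exhaustive ground truth.

## What it quantifies

**Phagocytosis (beads/cell).** Nuclei are detected by a fluorescence
threshold, holes are filled, objects are smoothed by shrinking and growing
2 px, and candidates are accepted as nuclei by size bounds and an
elliptical fit > 0.8 (Jaccard overlap with the moment-equivalent equal-area
ellipse). Accepted nuclei are expanded by 50 px into disjoint perinuclear
zones; within them, pHrodo particles are found by a top-hat contrast
threshold, smoothed by 2 px, and kept only when their mean intensity is
more than 2-fold over background. The phagocytic index per field is

```
beads/cell = (retained pHrodo spots) / (accepted nuclei)
```

assembled into per-genotype uptake time courses (mean ± SEM) on a
15-minute grid out to 135 min.

**Autophagy readouts.** Puncta-per-cell counting (p62/LC3-style channels),
and tandem mCherry-GFP reporter classification: GFP puncta are greedily
matched to mCherry puncta within a radius; matched pairs are autophagosomes
(GFP⁺ mCherry⁺), unmatched mCherry puncta are autolysosomes (GFP⁻ mCherry⁺,
the GFP quenched after lysosomal fusion), and the AL/AP ratio reports flux.

**NF-κB nuclear translocation.** Per cell, both the count of
NF-κB-positive pixels colocalized with the nucleus mask and the fraction of
NF-κB intensity inside the nucleus.

**Interactome enrichment.** Protein-group tables from an 8-plex TMT
pulldown (4 control vs 4 GFP channels) are filtered (contaminants, reverse
hits, < 2 unique peptides), log2-transformed, and tested per protein with
Welch's *t*:

```
t = (m̄_GFP − m̄_ctrl) / sqrt(s²_GFP/4 + s²_ctrl/4),   df by Welch–Satterthwaite
```

Significance is controlled by permutation-based FDR over balanced label
relabelings at 1% and 5%; interactors are called by **>2.0-fold enrichment
AND 1% FDR**, and a top set by fold enrichment ≥ 3.0. Two-way ANOVA with
Tukey/Sidak corrections and ELISA normalization arithmetic round out the
statistics used for the imaging endpoints.

**Synthetic data.** Because every stage needs falsifiable truth, the
`synthgen` module renders fields of ellipsoidal nuclei, particles whose
per-cell counts follow λ_max·(1 − e^(−k·t)) uptake kinetics, decoy
particles pinned at fold ≤ 2.0, reporter puncta, NF-κB partitioning, and
TMT tables with spiked interactors — under Poisson + Gaussian noise, with
full truth tables.

## Worked example

```python
from phagoquant.pipeline import RunConfig, run_assay
from phagoquant.synthgen import ImagingSimConfig
import pandas as pd

sim = ImagingSimConfig(field_shape=(256, 256), n_nuclei=8, n_decoys=4,
                       time_grid=(0.0, 45.0, 90.0, 135.0))
sim_dir = run_assay(RunConfig(assay="simulate", out_dir="demo_sim",
                              imaging_sim=sim, n_fields=3, rng_seed=11))
out = run_assay(RunConfig(assay="phago", images_dir=str(sim_dir / "images"),
                          metadata_csv=str(sim_dir / "metadata.csv"),
                          out_dir="demo_out", rng_seed=11))
print(pd.read_csv(out / "uptake_curves.csv").to_string(index=False))
```

prints

```
genotype  timepoint     mean      sem  n
isogenic          0 0.000000 0.000000  3
isogenic         45 4.166667 0.363242  3
isogenic         90 6.083333 0.083333  3
isogenic        135 5.125000 0.473242  3
  mutant          0 0.000000 0.000000  3
  mutant         45 3.208333 0.273227  3
  mutant         90 5.250000 0.314576  3
  mutant        135 5.625000 0.381881  3
```

Each row is the mean ± SEM beads/cell over three fields. At t = 0 nothing
has been internalized; by 90–135 min both genotypes approach the plateau
(λ_max = 6), with the slower-uptake "mutant" line (k = 0.018/min) lagging
the "isogenic" line (k = 0.03/min) at 45 min, exactly as the generator's
kinetics dictate. At this small field count the SEM shows why real
experiments average many fields.

The same pipeline is scriptable from a shell:

```bash
phagoquant simulate --config cfg.yaml --out run1 --seed 5
phagoquant phago --images run1/images --meta run1/metadata.csv --out run1_quant
phagoquant interactome --table protein_groups.csv --fdr 0.01 --fdr 0.05 --seed 5
phagoquant report run1_quant
```

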