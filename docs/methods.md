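# Methods

This note documents the models, rules and numerical choices behind
phagoquant, what the synthetic-data generator does and does not emulate,
and the problem sizes the validation suite uses.

## Segmentation ruleset

Nucleus detection follows a fixed rule pipeline: global threshold (Otsu by
default, fixed-value override), 8-connected components, per-object hole
filling, then morphological smoothing — a binary opening with a disk of
radius 2 px ("shrink and grow"), keeping the largest fragment if an object
splits. Candidates are accepted as nuclei when their area lies within
configured bounds and their **elliptical fit** exceeds 0.8.

The elliptical fit is the Jaccard overlap |M ∩ E| / |M ∪ E| between the
mask M and the rasterization E of its moment-equivalent ellipse: same
centroid, orientation from the second central moments, axes rescaled so the
continuous ellipse area equals |M|. It is bounded in [0, 1],
rotation-aware, ≈ 1 for solid ellipses (up to pixelation), ≈ 0.84 for
squares, and well below 0.8 for crosses and stars, which is what makes it a
usable nucleus gate. A single-pixel mask scores 1.0 by convention;
near-collinear masks clamp the minor semi-axis at 0.5 px so the equal-area
ellipse exists. The implementation is tested to 1e-9 against a brute-force
oracle that recomputes moments by direct summation and rasterizes the
ellipse pixel by pixel.

Accepted nuclei are expanded by `zone_radius` (50 px) into **perinuclear
zones**. Overlapping expansions are resolved by nearest-nucleus assignment
(per-nucleus Euclidean distance transforms, running minimum), with ties
going to the lower label; zones are therefore disjoint, contain their
nucleus, and are clipped at field borders. Border-touching nuclei are
scored and flagged rather than discarded (a config flag excludes them).

The area bounds (default 50–2000 px²) are fixtures tuned to the
generator's 20×-like scale, not measurements of any instrument.

## Particle counting and the phagocytic index

Inside the union of zones, particle candidates are found with a white
top-hat (disk radius 6 px, ≥ the largest expected particle) followed by a
contrast threshold. The threshold is `mean + 3·sd` of the top-hat response
over out-of-zone pixels: the top-hat of pure noise has a strictly positive
mean, so thresholding above zero alone floods the detector at realistic
noise. Components are smoothed by a 2-px opening (objects thinner than
that scale are dropped), and each object's `background_fold` is its mean
intensity divided by the background estimate — by default the median
intensity outside all zones, floored at the smallest positive observed
value; an annulus-based estimate is available in config. The brightness
rule is strict: an object is retained iff fold > 2.0, so fold exactly 2.0
is rejected (pinned by test). A particle belongs to the zone holding its
centroid; masks may straddle zone edges.

The phagocytic index pools per image: beads/cell = total retained spots /
total nuclei (per-cell counts are also emitted). Time courses are
summarized as mean ± SEM (sd/√n, ddof = 1) per genotype and timepoint;
single replicates report SEM 0 with n = 1 flagged; missing timepoints stay
missing.

## Puncta, flux and NF-κB readouts

Puncta detection reuses the top-hat strategy at a smaller scale (disk 4 px,
1-px opening, area bounds 2–80 px²) plus a minimum mean top-hat response of
20 intensity units. The absolute floor is what lets the detector stay
offset-invariant (the top-hat removes any flat background) while still
rejecting the faint rim residuals that a dim diffuse cell body leaves where
its boundary curvature is below the structuring radius; like any fixed
fluorescence threshold it assumes the acquisition's intensity scale and is
configurable.

Flux classification matches GFP puncta to mCherry puncta of the same cell
greedily in order of increasing distance, each punctum used at most once,
within `match_radius` (3 px). Matched pairs are autophagosomes; unmatched
mCherry puncta are autolysosomes; unmatched GFP puncta are biologically
unexpected and reported separately as anomalies. The bookkeeping
AP + AL = |mCherry| and AP + unmatched = |GFP| holds exactly. The AL/AP
ratio is undefined when AP = 0 (emitted as NaN).

NF-κB translocation reports two readouts per cell: the count of
NF-κB-positive pixels (Otsu threshold per field, fixed override) inside the
nucleus mask — the colocalization readout — and the fraction of NF-κB
intensity inside the nucleus relative to nucleus ∪ zone. The pipeline is
single-plane: volumetric "voxel" counting is deliberately flattened to
pixels, so absolute counts are not comparable to a 3D analysis even though
orderings and fractions are.

## Synthetic data: what is emulated, what is not

The generator renders, per field: ellipsoidal nuclei (semi-axes drawn from
configured ranges, uniform orientation) over a flat background of 100 a.u.
with nuclear intensity 1000 a.u.; a dim cell body (axes ×1.9, +8% of
background) around each nucleus; bright particles as discs of radius 3–5 px
whose per-nucleus counts are Poisson with mean λ_max·(1 − e^(−k·t)) on a
0–135 min grid with 15-min steps; decoy discs at folds ≤ 2.0 (ceiling
pinned exactly at 2.0 to probe the filter boundary); reporter puncta
(radius 2 px) that are dual-channel or mCherry-only in exact per-cell
numbers; and NF-κB signal split as f·S uniform over the nucleus and
(1 − f)·S over a 12-px cytoplasmic annulus clipped to the cell's own zone.
The NF-κB channel carries no flat camera offset, so the noise-free
intensity fraction recovers f exactly. Noise is Poisson shot noise
(1 photon per intensity unit), additive Gaussian read noise (sd 2 a.u.) and
an optional linear background gradient, applied after rendering.

Ground truth must stay well-posed for counting, so the generator enforces
separation invariants: nucleus centroids at least the sum of their
semi-major axes apart; particles non-overlapping with a 2-px clearance (so
rasterized discs can never touch under 8-connectivity); puncta at least
12 px apart center-to-center (below that, a small-structuring-element
detector cannot resolve neighbours once noise dilates them) and at least
4 px from zone bisectors (so ownership survives the ~1-px nucleus-boundary
shifts of re-segmentation). When a freshly drawn layout leaves one zone too
cramped for its Poisson-drawn count, the layout (not the count model) is
redrawn from the continuing RNG stream, at most 20 times; systematic
overcrowding still raises a placement error naming the violated constraint.
Layout redraws occur in well under 1% of fields at default densities, so
their effect on the count distribution is negligible.

Uptake kinetics are a deliberate modeling choice: the acquisition grid is
fixed (15-min steps to 135 min) but no kinetic law is prescribed anywhere,
so a two-parameter saturating exponential with per-cell Poisson counts is
used — concave, monotone, and matching how uptake curves look in practice.
Default rates (k = 0.03/min for the fast line, 0.018/min for the slow one,
λ_max = 6 beads/cell) and all per-cell count distributions and effect sizes
are fixtures: the generator defines test conditions with known truth, it
does not estimate any real experiment. It also makes no attempt at
photorealism — no PSF convolution, no 3D stacks, no autofluorescence
texture, no cell motion — so passing round-trips demonstrate correctness of
the rule pipeline, not robustness to every property of real micrographs.

TMT tables emulate a 4-vs-4 reporter design: per-protein log2 baselines
N(20, 2), channel noise N(0, 1) by default, spiked interactors shifted by
`interactor_log2fc` in the GFP group only, flagged contaminant/reverse rows
disjoint from spikes, and unique-peptide counts 1 + Poisson(5) with spiked
rows floored at 2 so the truth is learnable.

## Interactome statistics

Preprocessing removes contaminant and reverse rows and proteins with fewer
than two unique peptides, then log2-transforms. Rows containing a zero in
any used channel are dropped with a logged count (a small-offset option
exists in config); dropping avoids inventing pseudo-counts.

The test statistic is Welch's *t* with an optional s0 variance fudge added
to the denominator (s0 = 0 by default; nothing in the workflow being
reproduced prescribes one). FDR is estimated by permutation: all balanced
relabelings of the eight channels excluding the observed labeling and its
complement (68 for 4-vs-4; a random subset without replacement when more
than `n_permutations` exist). Including the identity would floor the FDR
estimate at 1/70 ≈ 1.4%, making a 1% level unreachable by construction.
For each candidate threshold τ (the observed |d| values),
FDR(τ) = mean over permutations of #{|d_perm| ≥ τ} divided by
#{|d_obs| ≥ τ} (median available in config), clipped to [0, 1] and
monotonized to be non-increasing in τ by a running minimum; a protein is
significant at level α iff its |d| reaches the smallest τ with monotonized
FDR ≤ α. This estimator is slightly anticonservative in the extreme tail
(a null maximum that exceeds every permuted value yields FDR 0), which is
visible as occasional single-protein calls on pure-null tables; calibration
is measured, not assumed, in the validation suite. Interactor calling is
the conjunction {2^log2fc > 2.0} ∩ {significant at 1% FDR}, with fold
enrichment computed as 2^(difference of group means of log2 intensities) —
whether the original fold was computed on raw or log2 means is not stated
anywhere, and the log2-mean version is the variance-stabilized choice. The
top set takes the k = 50 largest folds among proteins with fold ≥ 3.0,
stable-sorted by (−log2fc, id).

## ANOVA, multiple comparisons, normalization

Balanced two-way designs use the textbook partitioned sums of squares
(SS_A + SS_B + SS_AB + SS_resid = SS_total to 1e-9, verified against a
brute-force oracle); with one observation per cell the interaction becomes
the residual. Unbalanced designs fall back to Type II sums of squares via
an OLS fit (statsmodels). Degenerate all-equal input yields SS = 0 with the
table flagged. Tukey HSD computes adjusted p values from the studentized-
range distribution on the residual df with Tukey–Kramer standard errors;
Sidak is p_adj = 1 − (1 − p)^m capped at 1. Cytokine concentrations are
rescaled as conc × reference / protein_content, with the reference set per
assay type (100 µg for microglia monocultures, 500 µg for cocultures).

## Problem sizes and numerics in the validation suite

The test suite validates segmentation recovery on 50 default-noise fields
of 30 nuclei (512×512); uptake recovery on 2 genotypes × 10 timepoints ×
20 fields of 20 nuclei (384×384), with the 100-replicate ANOVA power check
run on beads/cell records drawn from the generator's count model directly —
the replication exercises the statistics, and the count layer is identical
to what drives rendering, which the image-pipeline sweep covers once in
full; flux round-trips at (AP, AL) ∈ {(5,5), (4,6), (10,2)} on 6-cell
fields; NF-κB ordering on 100 seeded field pairs; FDR calibration on 100
null tables of 2000 proteins. All seeds are fixed; reruns are bit-identical
(CSV output uses a fixed float format). `scripts/acceptance.py` recomputes
the same quantities at moderately reduced field counts and derives every
seed from its `--seed` argument.

## Known limitations

- No watershed splitting: touching nuclei are merged (the generator's
  separation invariant sidesteps this; real clumped cultures would not).
- Spot counting saturates when particles overlap heavily; the generator
  enforces resolvable truth, so saturation behavior is untested.
- The NF-κB colocalization count depends on the positivity threshold
  (Otsu by default); only the ordering and fraction readouts are
  threshold-robust.
- Fold enrichment and FDR variants (raw-vs-log2 means; mean-vs-median
  permuted counts; s0) are configurable but the defaults above are the ones
  validated.
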