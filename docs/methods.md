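# Methods

## Scope and model

`frlquant` quantifies immunogold labeling of AMPA-type glutamate
receptors at excitatory synapses, as measured on SDS-digested
freeze-fracture replicas (SDS-FRL), and the membrane-vs-intracellular
partition of receptor labeling on pre-embedding immunogold sections.
Because no public raw dataset exists for this kind of material, the
package pairs the measurement pipeline with a synthetic-scene generator
whose parameters are the published group statistics of a wild-type vs
APP/PS1 (Alzheimer's-model) comparison in hippocampal CA1 at 1, 6 and
12 months of age.  The generator provides ground truth; the pipeline is
validated by parameter recovery against it.

## Replica quantification pipeline

The measurement rules implemented in `quantify` are the standard SDS-FRL
workflow:

1. **Demarcation.** The postsynaptic specialization (PSD) appears on the
   exoplasmic fracture face (E-face) as a cluster of intramembrane
   particles (IMPs).  Its outline — "connecting the outermost IMPs" — is
   implemented as the convex hull of the IMP point set.  Convexity is a
   deliberate reading: it is deterministic and parameter-free, whereas
   any concave (alpha-shape) demarcation would introduce a free scale
   parameter the verbal rule does not define.
2. **Particle assignment (30-nm rim rule).** A gold particle is synaptic
   if it lies inside the hull or within 30 nm of its edge, inclusive.
   The 30 nm allowance reflects the physical reach of the
   primary + secondary antibody bridge between the gold and its antigen.
   The particle's *center* is the reference point; the distance is
   center-to-outline.  The radius is configurable (`rim_nm`).
3. **Inclusion rules.** A fracture-truncated ("incomplete") PSD is
   analyzable only if it retains at least 30 IMPs (`imp_min`).  A
   cluster counts as a verified glutamatergic synapse only when
   co-labeled by more than two GluN1 particles, i.e. a count of ≥ 3
   (`glun1_min`); "more than two" is read strictly.  The GluN1 rule is
   an exclusion filter by default; `glun1_filter=False` switches it to
   annotate-only, since the published wording is ambiguous on whether
   failing clusters were dropped or merely flagged.
4. **Density.** Per synapse, density = pan-AMPAR count / hull area, in
   particles/μm².  Internally every length is in nm; areas cross to μm²
   only at reporting boundaries (1 μm² = 10⁶ nm²).
5. **Background.** Non-specific labeling is estimated by pooling gold
   counts over P-face regions (pooled count / pooled area).  It is
   reported but *not* subtracted from synaptic densities, matching the
   published choice (at 2.3/μm² and a 0.046 μm² PSD the expected
   spurious count per synapse is ≈ 0.1, a ≲ 0.5 % effect, and the
   rim-contamination simulation bounds the recovery bias below 1.5 %).
   A subtraction option is deliberately absent from the default path.
6. **Pooling checks.** Complete vs incomplete synapses, and animals,
   are tested for poolability with a Kruskal–Wallis test at α = 0.05
   ("pool" when p ≥ 0.05).  The published analysis pooled both after
   finding no differences; the check reproduces that gate without
   assuming normality.

Particle assignment is purely geometric: particles are not pre-filtered
by their nominal fracture face, because face attribution at the
demarcation edge is ambiguous on real replicas.  This is what lets
P-face background leak into the 30-nm rim, so the rim-contamination
bound is a real test rather than a tautology.

## Synthetic scene generator

Each scene is one fractured synapse:

* **PSD area** A ~ lognormal, moment-matched to mean 0.046 μm², SD
  0.018 μm² (the published wild-type spine PSD size at 12 months; the
  same distribution is used at 1 and 6 months, where no value is
  printed).
* **IMP placement.** IMPs are a Poisson process (default 3,500
  IMPs/μm², a typical order of magnitude for E-face PSD clusters; the
  source material reports none) placed uniformly in a disk whose radius
  is inflated by a Monte-Carlo-calibrated shrinkage factor so that the
  *convex hull* of the IMPs has expected area A.  The shrinkage factor
  (hull area / disk area, ≈ 0.93 at ~170 points) is estimated once per
  expected-count and cached; the residual calibration bias on the mean
  demarcated area is ≈ 0.2 %.
* **Receptor gold.** A per-scene density D ~ lognormal with the
  published group mean and CV = SEM·√n/mean derived from the published
  SEM and n of that genotype × age × compartment cell (e.g. wild-type
  spines, 12 months: 459.51/μm², CV ≈ 0.367).  Poisson(D × hull area)
  pan-AMPAR particles (10-nm gold) are placed uniformly *inside* the
  hull.  Placing them strictly inside — rather than smearing into the
  rim — makes count/area an unbiased estimator of D, so parameter
  recovery is well-posed; rim behavior is still exercised by the P-face
  background.
* **GluN1 co-label.** Poisson(5) 5-nm particles per synapse inside the
  hull.  A mean of 5 leaves ~12 % of synapses below the ≥ 3 co-label
  threshold, so the inclusion filter is exercised without biasing the
  density (GluN1 and pan-AMPAR counts are independent).
* **Background.** Poisson at 2.3/μm² on a P-face frame surrounding the
  scene (frame width set by `pface_margin_nm`, default 250 nm, inner
  edge 10 nm outside the generation disk).
* **Incomplete synapses.** With probability 0.2 (no published fraction;
  a plausible rate for random fracture planes) the scene is cropped by
  a random chord retaining 50–85 % of the IMP projection, and flagged
  incomplete.
* **Group structure.** Datasets assign animals round-robin (default 3,
  the number measured per group).  No animal-level random effect is
  simulated by default: the published analysis pooled animals after
  finding no inter-animal differences, and the pooling check reproduces
  that on the synthetic data.

Cells with no published PSD area (all interneuron-shaft cells, and the
12-month APP/PS1 spines, whose PSDs are smaller) carry an area mean
calibrated by simulation so that the simulated median particle count
matches the published median for that cell, with the area CV held at
the published spine value (0.018/0.046 ≈ 0.39).  The calibration
(`calibrate_area_to_median`, bisection over 200k-replicate medians) is
shipped; its outputs are frozen as constants in the presets.

The model implies a count–area correlation: with density CV ≈ 0.37 and
area CV ≈ 0.39, Pearson r between count and area is ≈ 0.65
(closed-form from the moment structure, including Poisson noise).  The
published correlations (0.74 wild type, 0.66 APP/PS1) constrain but do
not identify the joint distribution, so r is validated as a band
[0.55, 0.85], not an equality.

All randomness flows from one explicit seed through a single
`numpy` Generator; identical seeds give bitwise-identical scenes.

### What the generator does *not* emulate

Antibody labeling efficiency as a separate parameter (absorbed into the
group mean density); spatial clustering of receptors inside the PSD
(labeling is uniform — consistent with the qualitative "no apparent
clustering" observation, but untested against real point patterns);
curvature of fracture faces and tangential fractures (scenes are flat);
animal-level variance components.  Passing recovery tests therefore
demonstrates that the *pipeline* measures what it claims on data with
known truth — not that real replicas satisfy the generative
assumptions.

## Rendered micrographs and detection

`render` draws an 8-bit grayscale emulation of a platinum/carbon
replica: mid-gray background (128) with band-limited texture (σ ≈ 5
gray levels, 6-nm correlation), IMPs as unidirectionally shadowed bumps
(paired Gaussian highlight/shadow, amplitude 26, emulating 60°
unidirectional platinum shadowing), gold as near-black (12)
anti-aliased disks of the class diameter, plus additive Gaussian noise
(default σ = 8 gray levels).  Default sampling 0.5 nm/px (valid range
0.25–2).

The detector is a scale-normalized Laplacian-of-Gaussian filter bank
with dark-blob polarity, three scales per requested diameter (around
σ = d/(2√2·px)), per-scale local maxima above a response threshold of
25 gray levels (a full-contrast gold disk responds at ≳ 40, IMP shadow
lobes at ≲ 15), diameter estimation by log-parabolic interpolation
across scales, and greedy non-maximum suppression strongest-first.
The suppression radius is the accepted blob's estimated radius plus
half the smallest requested diameter: plain half-diameter suppression
leaves secondary fine-scale responses on the rims of 10-nm particles
(precision ≈ 0.4); the extent-aware radius removes them (F1 ≈ 0.96 at
default noise) while still allowing two touching 5-nm particles to be
resolved.  Size classes split at the 7.5-nm midpoint, boundary assigned
upward.  Touching particles closer than the suppression radius merge
into one detection; this is a known limitation.

Detection-vs-truth scoring uses greedy nearest-neighbor matching
(default tolerance 10 nm, one large-gold diameter), checked against a
maximum-cardinality assignment oracle.

IMP-cluster segmentation (`segment_imp_cluster`) thresholds local
texture energy (windowed SD of the lightly smoothed image, window
16 nm) at 1.5× the image median, takes the connected component at the
seed click (snapping up to 30 nm to tolerate imprecise clicks), closes
it morphologically (12-nm radius), and returns bright local maxima
inside it as IMP centers.  On default renderings the hull of the
returned IMPs overlaps the true demarcation with Jaccard ≈ 0.9.
Detection is validation-only: the quantification path consumes
coordinate tables directly.

## Pre-embedding partition

Each digitized profile is a closed membrane outline with silver-enhanced
gold particles inside it.  A particle is membrane-associated iff its
distance to the outline is ≤ ε = 25 nm (no published criterion exists
for silver-enhanced 1.4-nm gold; 25 nm is the method's typical
localization accuracy, and ε is configurable and reported in outputs).
Group comparisons are two-sample t-tests on animal-level percentages,
one test per compartment family (total / spines / shafts — membrane and
intracellular percentages are complementary, so one test carries each
family), Holm–Šidák-adjusted across the three families.

The synthetic genotype presets mix spine and shaft profiles with the
per-animal spine share chosen so the pooled membrane fraction equals
the published overall value (wild type: 15 of 40 cells are spines,
pooled 61.1 %; APP/PS1: 9 of 40, pooled 27.9 %), because the printed
per-compartment percentages are inconsistent with an equal mix.

## Statistics

* Group summaries per genotype × age × compartment: synapse n, median
  and range of particle counts, mean ± SEM / median / range of
  densities — the layout of the published summary table.
* Two-way ANOVA of density on genotype × compartment within one age,
  Type II sums of squares (the published cell sizes are unequal:
  111/109/135/173 at 12 months), with Bonferroni-adjusted pairwise
  genotype contrasts within each compartment.  Observations enter at
  the synapse level, consistent with the published n being synapse
  counts.  On balanced data the decomposition matches the classical
  closed-form sums of squares to 1e-10 (tested).
* Assumption checks (Levene across groups, Shapiro–Wilk per group) are
  advisory and do not gate the ANOVA, mirroring the published workflow.
* Holm–Šidák: step-down adjustment adj₍ᵢ₎ = 1 − (1 − p₍ᵢ₎)^(m−i+1) over
  ascending p, with enforced monotonicity; cross-checked against
  statsmodels.

## Numerical choices and problem sizes

* Rasterization oracles run at 0.25 nm/px with pixel centers at
  (i + 0.5)·px; image convention throughout (origin top-left, y down,
  0-based pixels).
* The 30-nm rule and ε-membrane rule are inclusive (≤).
* Degenerate demarcations (< 3 IMPs or collinear) yield excluded
  records with reason "degenerate demarcation", not exceptions, inside
  the table builder; the geometry layer itself raises.
* Hull-shrinkage calibration: 600 Monte-Carlo replicates per cached
  expected-IMP count; fixed internal seed, so presets are reproducible
  across processes.
* Validation problem sizes: density recovery runs at the published
  per-cell n (62–173 synapses); calibration checks use 2,000 scenes
  (mean-area SE ≈ 0.0004 μm²); the background estimate pools ≈ 600 μm²
  of P-face (Poisson SE ≈ 0.06/μm²); the type-I-error simulation uses
  400 replicates of a 4 × 40-synapse null design (binomial SE ≈ 1.1
  percentage points on the rejection rate); the detector benchmark uses
  100 mixed-class particles per noise level.
* The type-I error of the full generate → quantify → ANOVA chain is
  5.3 % at nominal α = 5 % (600-replicate estimate), i.e. the lognormal
  skew of the densities does not meaningfully inflate the test at these
  cell sizes.

## Known limitations

Convex demarcation cannot represent genuinely concave PSDs
(perforated/horseshoe synapses will be over-demarcated, biasing their
density downward).  The detector is tuned to the renderer's contrast
model and is not expected to transfer to real micrographs without
re-tuning the response threshold.  Touching gold particles merge.  The
generator's independence assumptions (density ⊥ area, GluN1 ⊥ pan-AMPAR)
are conveniences, not established properties of real synapses; only
means, dispersions and medians are calibrated.  Tangential-fracture
corrections, 3-D geometry, and nearest-neighbor pattern analysis of
intra-synaptic receptor arrangement are out of scope.
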