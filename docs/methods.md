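# Methods

## Scope and model

`picscan` quantifies tumor–immune interaction in enrichment-free
liquid-biopsy slide images through five linked procedures: rare-event
detection by distributional thresholds, neighbor-pair finding on label
masks, contact-interface membrane enrichment scoring, ion-count
phenotyping, and per-mL enumeration. Because patient whole-slide images are
not desk-scale artifacts, every stage is validated against a synthetic
slide generator whose ground truth is exact; the generator is first-class,
tested code, not a fixture.

## Synthetic slides

Cells are disks with annular membrane rings (default ring width 2 px) — the
simplest geometry whose perimeter partition has a closed-form oracle, which
is what the contact-scoring stage needs for verification. Four channels are
rendered at 16 bits: DAPI (nuclear), CK (cytokeratin), CD45 (leukocyte
membrane), and brightfield. Channel values are background + the max of
overlapping object amplitudes (brightfield: background − a dark membrane
ring for vesicles), plus additive Gaussian noise clipped to [0, 65535].
Per-object brightness is jittered by a mean-preserving lognormal factor
(CV 0.1) to emulate staining variability; no point-spread function, 3-D
structure, or staining chemistry is simulated, and nuclei are modeled as
filling the cell footprint (real nuclei do not, so DAPI-derived masks of
real cytoplasm-rich cells will be tighter than these).

Default geometry: 0.5 µm/px; WBC radii 3.5–5 µm, CTC 5–8 µm, LEV 1.5–3.5 µm
plus a few sub-cutoff vesicles (0.5–1.1 µm) so the size filter has
something to reject. Intensities (above background): DAPI 12000, CK 8000,
WBC CD45 ring 6000, diffuse CD45 of immune-like tumor events 5000;
backgrounds 300 (fluorescence) / 10000 (brightfield); noise SD 50 / 100.

The default slide plants 1500 WBCs and ~20 CK+ events on a 2048² canvas.
This ratio is statistical, not cosmetic: the CK threshold is
mean + 6 SD over *all* segmented cells, and with a CK+ fraction p at
contrast Δ the SD inflates like Δ√p. The rule only has headroom when
p ≲ 1.5%, which mirrors the real platform where a few million WBCs dwarf a
handful of CTCs (millions of cells per slide, not 10⁴, motivate the scale
but are not literally rendered).

Planted pairs come in three relationships. `gap`: center distance
r₁ + r₂ + g (default g = 1 µm), guaranteeing ≥ 1 px of background between
masks. `overlap`: overlapping disks with a circumferentially uniform ring
(fold 1 by construction). `pic`: the WBC ring is multiplied by a fold
f > 1 on a wedge of full angle θ (default 60°) facing the partner, and the
partner is placed at the center distance whose *geometric* contact arc (at
1 px adjacency) equals θ, so the planted wedge and the measured contact
region coincide and the planted f is the quantity the scorer should return.
Placement is rejection sampling with a bounded retry budget (default 100);
infeasible requests raise a placement error naming the pair.

## Detection

The published pipeline segments cells with a pre-trained neural model; the
model itself is not the contribution, so the segmenter here is a classical
stand-in behind a narrow interface (label mask + region table): Gaussian
smoothing (σ = 1), global Otsu on DAPI, distance-transform watershed.
Two numerical guards matter:

- the Otsu threshold is floored at background median + 5 robust SDs
  (1.4826·MAD), because on a blank slide Otsu happily splits pure noise;
- the watershed peak window (`min_distance`, default 4 px) must stay
  narrower than the smallest nucleus radius; with a wider window a small
  WBC touching a much larger CTC sits inside the big cell's
  distance-transform ridge and the pair merges into one region.

Thresholds follow the platform's SD conventions: events with mean DAPI
below µ − 3σ of all nucleated cells are flagged (never deleted) as
acellular; CTC candidates have mean CK strictly above µ + 6σ of all
retained cells (candidate sets shrink monotonically in k). LEVs are
connected components of the *unsmoothed* CK channel at the same CK
threshold — smoothing is deliberately skipped because vesicles near the
2.5 µm cutoff are only a few pixels across and smoothing erodes them below
size — retained iff equivalent circular diameter
2·√(area/π)·pixel_scale ≥ 2.5 µm, mean DAPI below the same nucleated-cell
cutoff (so no event is both CTC and LEV), and brightfield ring score
≥ τ = 2, where the score is (interior mean − 2 px boundary-band mean) /
background SD. A missing brightfield channel skips the ring check with an
explicit flag, mirroring samples acquired without brightfield.

Phenotype is anchored to the observed leukocyte distribution: an event is
immune-like (im) iff its mean CD45 is strictly above µ_WBC − 2σ_WBC
computed over detected WBCs (retained non-candidates); ties go to
epithelial-like (epi). The 2-SD anchor, like the ring τ, is a configurable
convention — the original calls were made by human analysts.

## Neighbors and the chance-overlap null

A tumor event and WBC are neighbors iff their masks overlap or are
8-connected adjacent (4-connectivity is a config option). Counts are
normalized per 10⁶ nucleated cells on the analyzed slide; the denominator
convention is ours since no published formula exists. As an added null
model (not part of the published procedure), the expected number of chance
adjacencies under homogeneous random placement is
n_t·n_w·π(r_t + r_w)²/A, verified against Monte-Carlo placement in the
tests; it lets synthetic experiments report interaction excess over chance.

## Contact-interface scoring

The WBC perimeter is the set of mask pixels with a 4-neighbor outside,
ordered by polar angle about the centroid (exact for star-convex masks;
disk-like cell masks qualify). Perimeter *length* is the Euclidean polyline
length of the closed trace, which tracks 2πr within ~5% for digital disks —
raw pixel counts systematically underestimate circumference. Contact
positions are those within 1 px (Chebyshev) of the partner mask; an
entirely-contact (engulfed) or entirely-non-contact (gap) profile is a
degeneracy error since the ratio is then undefined.

Intensity is sampled at the boundary pixel itself (band width 1). A wider
band averaging the in-mask 8-neighborhood is available, but with a 2 px
membrane ring it pulls in sub-membrane interior signal and biases fold
recovery low by up to ~12% at f = 3, so the narrow band is the default.
Fold change = contact mean / non-contact mean (means, not medians; ε-guard
10⁻¹² on the denominator); it is invariant under multiplicative gain but
*not* under additive offsets — the ~300-count fluorescence background
dilutes recovered folds by 2–6%, which is within the 10% recovery target
and is the same compression a real camera offset would cause. Asymmetry is
the resultant-vector length of intensity-weighted unit directions from the
centroid (0 = uniform, →1 = single narrow arc).

Classification gates (`PicThresholds`): pic iff fold ≥ 1.3 AND asymmetry
≥ 0.04 AND contact arc fraction ∈ [0.05, 0.9]; no adjacency → gap; else
passive overlap. These are calibrated tunables, not published constants
(annotation was originally by human review): on the synthetic generator at
default geometry they give 100% sensitivity at planted f = 1.5 and 0%
false positives at f = 1 over 200 seeded pairs each. The asymmetry gate is
deliberately permissive because the closed-form asymmetry of a f = 1.5,
60°-arc ring is only ≈ 0.07.

## Group comparison

`mann_whitney` computes U by midrank summation. The exact two-sided null
distribution is used when n₁n₂ ≤ 200 and the pooled sample is tie-free;
otherwise a normal approximation with tie correction, applying a 0.5
continuity correction to the p value only. The reported z — and therefore
the effect size r = |z|/√(n₁+n₂) — is the *uncorrected* standardized U, so
that it reduces to the closed form (U − n₁n₂/2)/√(n₁n₂(N+1)/12) in the
tie-free case; the rank-biserial correlation 2U/(n₁n₂) − 1 is emitted
alongside because the literature is split on which "r" a Mann–Whitney
effect size denotes. Note the ceiling: with n₁ = 93, n₂ = 16 even complete
separation yields r ≈ 0.61 under this definition.

## Phenotyping

Ion counts are transformed by log(1 + x) (counts include zeros, so an
offset is required). Clustering is agglomerative Ward on Euclidean distance
over per-marker z-scored log values, cut at k = 2; the cluster with the
higher mean CD3 + CD4 signature is always relabeled cluster 1 so labels are
stable across runs. Gating is a fixed decision tree over
CD45/CD3/CD4/CD8a/CD20/CD56/CD14/CD68 positivity (CD3+CD8a+ takes the
cd8_t branch before CD4, so double positives gate as cd8_t — a disclosed
tie-break). Default positivity is raw count > 10 per marker; the
midpoint-between-cluster-means alternative is provided
(`derive_gate_thresholds`) but degenerates for markers neither cluster
expresses (the midpoint lands in the noise floor), which is why it is not
the default. Gate labels are invariant under strictly monotone per-marker
rescaling with correspondingly transformed thresholds.

IF↔IMC coordinate matching is greedy nearest-neighbor under a micron
tolerance (each ROI used at most once; ties break to the lowest id; an
optional affine callable reconciles frames). Enrichment of in-contact
events in cluster 1 uses Fisher's exact test (two-sided by the
probability-mass criterion) with the sample odds ratio ad/bc (∞ allowed).

The synthetic ion-count generator draws negative-binomial counts
(dispersion 5) from two planted profiles — CD4-T-like (CD45 60, CD3 45,
CD4 35, CD8a 2, …) and epithelial-like (CK 70, immune markers ~1–2) — with
default group sizes 42 in-contact vs 143 standalone and class mixing 85% /
20% CD4-T-like. It stands in for real CyTOF data and omits spillover,
acquisition dropout, and continuous phenotype gradients, so a perfect ARI
here shows the machinery is correct, not that real IMC data cluster this
cleanly.

## Enumeration

Events/mL = count × (total nucleated cells / cells plated on analyzed
slides) / blood mL — the plated-fraction extrapolation standard for this
platform (default draw 8 mL, ~3×10⁶ cells per slide); the exact published
formula is unstated, so this convention is documented rather than claimed.
Whether "total CTCs" includes in-cluster (PIC) CTCs is also unstated, so
both denominators are emitted; the 3–4% PIC-fraction check uses the
inclusive one, under which both PIC-positive example patients fall in
[3, 4]%. Fractions with zero denominators are NaN, never 0. Percentages
round half-up to integers to match reporting style. A small eight-patient
per-mL enumeration table ships with the package as worked-example data.

## Problem sizes and determinism

Defaults keep every stage desk-scale: the benchmark slide is 2048² px with
~1540 objects (seconds to generate and segment), fold recovery uses 50
pairs per fold on 160² canvases, the group test 93 + 16 pairs × 20
repetitions, and the phenotype stage 185 events — sizes chosen so the whole
validation suite runs in a few minutes on one core while keeping every
statistical claim testable. All randomness flows through
`numpy.random.default_rng` seeds; identical config + seed reproduce slides
bit-for-bit.

## Known limitations

- Disk-shaped cells and wedge-shaped enrichment are idealizations; the
  polar-angle perimeter ordering assumes star-convex masks and raises on
  multiply-connected regions rather than guessing.
- The segmentation stand-in is deliberately simple; precision/recall
  ≥ 0.95 on synthetic lawns does not transfer to real tissue-like clutter,
  which is why the segmenter sits behind a swappable interface.
- Passing planted-truth recovery shows the estimators are unbiased under
  the generator's assumptions (additive Gaussian noise, multiplicative
  jitter, no PSF); real-image performance additionally depends on
  segmentation quality and background structure the generator does not
  emulate.
- The chance-overlap null assumes homogeneous plating; real slides show
  density gradients, which the per-10⁶-cells normalization only partially
  absorbs.
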