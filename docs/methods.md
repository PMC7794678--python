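# Methods

`swardmap` implements a desk-scale version of an image-based pipeline for
estimating and mapping the species composition of grass-clover swards. This
note documents the models, the defaults and why they were chosen, what the
synthetic generators do and do not emulate, and the numerical conventions.

## Problem setting

Grass-clover mixtures are fertilised according to their clover proportion,
but the biomass composition of a sward cannot be observed at field scale.
The pipeline estimates it from top-down colour images in four steps:

1. per-pixel semantic segmentation of the canopy into soil / clover / grass
   / weed, with a second cascade stage splitting clover into red and white
   clover;
2. composition metrics from the segmentation: canopy coverage (vegetation
   pixels / all pixels) and per-species fractions of the vegetated canopy;
3. a linear calibration from canopy fractions to relative dry-matter
   biomass fractions, validated leave-one-site-out;
4. spatial interpolation of per-image metrics from a distance-triggered
   vehicle survey to a 5 x 5 m field map by ordinary kriging.

Training a full-scale convolutional segmentation network is out of scope
here; the segmenter is a pluggable interface with (a) a ground-truth-backed
oracle with a controllable corruption rate, used by all pipeline tests, and
(b) a compact trainable reference (fixed convolutional filter bank + 
multinomial logistic output) for desk-scale learning experiments.

## Synthetic scenes (`swardmap.scene`)

Training data for sward segmentation is composited rather than annotated:
procedurally drawn sprites are placed on a speckled soil background in
painter's order until a target fraction of pixels is vegetated. Sprites are
drawn per species with within-species variation in shape, scale and hue:
grass as thin curved tapering blades; clovers as trifoliate rounded
leaflets with a pale (white clover) or dark (red clover) leaf marking plus
occasional flower heads; weeds as a lobed teal-green rosette. Placement
position and rotation are uniform; z-order equals placement order, and the
labels record only the *visible* canopy, so occlusion is consistent between
image and labels by construction.

Choices and caveats:

* **Stopping rule.** Leaf area index of a 2-D composite is unobservable
  once sprites overlap, so the generator stops on projected visible
  coverage, which the emitted labels certify exactly. The cumulative placed
  sprite area / scene area is recorded as an LAI-like statistic.
* **Scale.** Field protocols resolve about 6 px/mm; at that resolution a
  clover leaflet is hundreds of pixels across. Test scenes use small
  sprites (default ~22 px canvas) on 96-256 px scenes so that a scene
  composes in ~0.1 s; the geometry and label algebra are scale-free.
* **Realism.** No shadows, no perspective, no radiometry; species are
  separable mostly by colour and coarse texture. Passing tests therefore
  demonstrate the correctness of the pipeline's *label algebra, metrics and
  statistics*, not segmentation accuracy on photographs.
* A hard cap of 10,000 placements guarantees termination; an unreachable
  coverage target warns and records the achieved coverage.

## Class weighting (`swardmap.weights`)

Pixel classes are heavily imbalanced, so cross-entropy training weights each
class by rarity:

    w_c = w_ce * ln(N_sum / N_c)

with `N_c` the class pixel count, `N_sum` the total, and emphasis `w_ce`
defaulting to 2.1 (the value at which the published training-weight vector
is internally most consistent under a natural log; purely a diagnostic
default, configurable). The weight is 0 for a class filling every pixel and
grows for rare classes; zero-count classes get a configurable cap (default:
the largest observed weight) instead of infinity.

Two refinements mirror training practice: red/white clover leaf weights
start from the combined clover count and are scaled by within-clover rarity
(`x N_species_total / (2 N_s)`), keeping the clover canopy's total emphasis
controlled while balancing the species; all named weed species share the
weight of the combined weed coverage.

Stage translation: stage 1 sees the four top classes with an all-on loss
mask; stage 2 sees red-vs-white labels with the loss masked ON only for
clover pixels of known species — unknown-species clover trains stage 1 but
not stage 2.

## Segmentation logic (`swardmap.segment`)

* **Multi-scale fusion** averages per-pixel class *probabilities* (not
  logits) over scales 100/75/50%, after bilinear upsampling of each scale's
  map to native resolution and per-pixel renormalisation. Argmax ties break
  to the lowest class index.
* **Cascade**: stage-2 species replace stage-1 clover pixels only, so
  collapsing species back to "clover" reproduces the stage-1 map exactly —
  an invariant tested on random inputs.
* **Oracle segmenter**: predicts the scene's true prospect labels with a
  fraction of pixels flipped to a uniformly drawn other class (one-hot
  probabilities). At corruption 0 the full pipeline reproduces scene truth
  bit-exactly, which anchors every downstream test.
* **Reference segmenter**: per-pixel features from a fixed convolutional
  bank (RGB, Gaussian-smoothed colour at sigma 1/2/4, local standard
  deviation, green-excess index) feeding a multinomial logistic layer
  trained on subsampled pixels (default 1500/scene) with class-weighted
  cross-entropy and stage-2 loss masking. On held-out synthetic scenes it
  reaches a stage-1 mean IoU around 0.9; the repo gate is > 0.70 on 10
  held-out scenes after training on 50.

## Composition metrics (`swardmap.metrics`)

Pure pixel counting: coverage = non-soil / all pixels; species fractions are
relative to the vegetated canopy. An empty canopy leaves the fractions
undefined (flagged NaN, never 0) so empty frames cannot bias calibration.
Biomass-sample crops follow the fixed-frame protocol: the frame region is
resampled to 3000 px square, extended by a 200 px context margin on all
sides (reflection-padded at image edges), and the margin is discarded after
segmentation; boxes are half-open `[r0, r1) x [c0, c1)`.

## Calibration (`swardmap.calibration`)

Quadrat samples (0.5 x 0.5 m) are hand-sorted into grass / white clover /
red clover / weeds, dried and weighed; fractions under 5 g fresh with no dry
weighing are assigned a 25% dry-matter content. Dry-matter fractions are
`p_f = dry_f / sum(dry)`; the dry yield scales to kg/ha (1 g per 0.25 m^2 =
40 kg/ha).

The calibration itself is ordinary least squares with intercept from canopy
fraction to biomass fraction (no weighting — nothing in the protocol
motivates one), reporting R^2; per-site/per-cut decompositions refit within
each group (groups with n < 3 are omitted with a note). Leave-one-site-out
validation fits on all sites but one and reports the held-out mean absolute
error in percentage points.

The paired-data generator draws canopy clover fractions Uniform(0.02, 0.9)
(pure stands are rare), applies `intercept + slope * canopy + site offset +
N(0, sigma)` clipped to [0, 1] with defaults slope 0.9, intercept 0.05,
sigma 0.05 and 4 sites of ~200-240 samples — the scale of a multi-site
plot-trial campaign. Secondary fractions (weeds, individual clover species)
receive extra attenuation noise, reflecting that their vertical layering in
the sward decouples canopy from biomass. Canopy coverage saturates with
yield as `1 - exp(-yield/800 kg ha^-1)`, so coverage is informative below
~2000 kg/ha and flat above. Under these defaults the clover calibration
shows R^2 ~ 0.95 and LOSO MAE ~ 4 points; real-world values depend on
segmentation errors the generator does not model.

## Field mapping (`swardmap.fieldmap`)

* **Survey**: serpentine tracks with spacing either fixed or drawn per
  track from a (lo, hi) range — the realistic model of a "typical 6-12 m"
  track distance; along the drive, an image fires whenever the Euclidean
  distance to the last image exceeds the 5 m trigger. An optional border
  pass samples the field boundary first. The path is walked at a
  configurable fine step (default 1 m), so the >5 m rule yields 6 m
  along-track image spacing.
* **Variogram**: empirical semivariance binned in lags, weighted
  least-squares fit (weights sqrt(pair count)/lag, emphasising the short
  lags that drive kriging; long lags of a single realisation are
  trend-dominated). Families: spherical (default), exponential, gaussian.
  A constant field degenerates to a pure-nugget model with a warning.
* **Ordinary kriging**: per 5 x 5 m cell (grid snapped to 5 m multiples,
  value at the cell centre, cells clipped to the boundary polygon), solved
  from the k = 16 nearest samples with the unbiasedness constraint via a
  Lagrange multiplier; weights sum to 1 to machine precision and the
  predictor is exact at sample locations when the nugget is zero. Singular
  local systems fall back to inverse-distance weighting with a warning.
  Inverse-distance (power 2) is the alternate method; on smooth synthetic
  fields at survey densities (~150-200 images/ha) its map RMSE is within
  25% of kriging's, which operationalises the observation that the two give
  comparable species maps at these densities.
* **Synthetic truth fields** are random-Fourier-feature approximations of a
  Gaussian-covariance process (practical range = correlation 0.05),
  emulating smooth within-field clover variation; per-image metric noise of
  0.05 matches the order of the calibration's per-sample prediction error.
  Real fields additionally show management artefacts (tractor-track
  striping, headlands) that neither the field generator nor the
  interpolator corrects.
* Coordinates are assumed projected to a metric plane; maps are written as
  single-band float TIFF with a JSON georeferencing sidecar and a PNG
  quicklook.

## Raw-image ingest (`swardmap.ingest`)

Demosaicing uses the gradient-corrected linear method (fixed 5 x 5 kernels,
all four 2 x 2 Bayer layouts, reflective borders); a constant mosaic maps to
the constant grey image and the operator is linear before clipping.
Flat-field correction divides by a per-channel gain raster estimated as the
blurred mean image of an acquisition set (default blur sigma = min(H, W)/16
— strong enough to suppress scene content from tens of images, weak enough
not to distort a low-frequency vignette), normalised to channel mean one.
Correction is multiplicative (standard flat-fielding) and approximately
idempotent: re-estimating a profile on corrected images gives near-unit
gain. A gray-world white balance is included as a clearly-labelled rough
approximation of a manually calibrated colour profile.

## Campaign tables (`swardmap.tables`)

The bundled plot-trial and survey summary tables are treated as raw inputs;
the report tooling recomputes per-site sample totals (239/196/240/240,
grand total 915), total mapped area (225.3 ha), total image count, image
density consistency and the median mapping capacity (16.85 ~ 17 ha/h). One
survey row (farm B, field 4, May) is internally inconsistent — its image
count contradicts its own area and density cells by a factor ~4 and
duplicates the neighbouring row — so it is flagged, and the image total is
reported both raw (31,050) and with flagged rows excluded (29,848).

## Known limitations

* Scene realism is deliberately minimal (see above); the reference
  segmenter's IoU on synthetic scenes says nothing about photographs.
* Simulated survey densities for track spacings at the narrow end
  (6-8 m) exceed the 122-200 images/ha range typical of real campaigns,
  because the idealised trigger never misses and tracks cover the whole
  field; real effective spacings are wider.
* Kriging uses a local neighbourhood (k = 16); for strongly clustered
  samples a larger neighbourhood may be needed.
* No reprojection or datum handling; no correction for periodic sampling
  artefacts aligned with field tracks.

## Problem sizes used by the test suite and acceptance script

Scenes are 96-160 px with ~22 px sprites (50-60 scenes per experiment);
calibration uses 4 sites x 200-220 samples and 200 replicates for CI
coverage; surveys run on 1-ha (recovery) and 4-ha (variogram range) square
fields at ~150-210 samples/ha. These sizes keep the full suite and the
acceptance script in the tens of seconds while leaving every statistical
check well-powered.
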