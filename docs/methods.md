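# Methods

## Overview

`gatedlung` quantifies lung function and radiation-induced lung injury
from paired respiratory-gated micro-CT volumes of the mouse thorax.  The
measurement chain is: optional edge-preserving filtering → Hounsfield-unit
(HU) calibration from in-image air/water references → seeded
region-growing lung segmentation inside a carina-anchored ROI → per-phase
volume and mean CT number → functional residual capacity (FRC) and tidal
volume (VT) → longitudinal and group statistics.  Because no public
reference dataset exists for this acquisition protocol, the package ships
a synthetic thorax phantom with exact ground truth; every quantitative
claim made by the test suite is a claim about recovery of that generator
truth.

## Lung-function model

Lung parenchyma is treated as a two-component air/tissue mixture on a CT
scale anchored at air = −1000 HU and water/tissue = 0 HU.  A voxel with
local air fraction f then has CT number −1000·f, so the mean CT number
over the segmented lung measures its mean air fraction, and

    FRC = V_exp  · CT#_exp  / CT#_air
    VT  = V_insp · CT#_insp / CT#_air − FRC

with CT#_air = −1000 HU by convention (overridable in `RunConfig`).  FRC
is the air content at end-expiration; VT is the inspiratory air content
minus FRC.  On the phantom the mixture model is exact by construction, so
with perfect segmentation and calibration the FRC formula reproduces the
generator's air content to float precision (tested to 1e−9 relative).
Negative VT is permitted but flagged: it indicates phase misassignment.

## The thorax phantom

The phantom voxelizes, at 0.075 mm isotropic spacing by default, a
soft-tissue body cylinder (+40 HU) containing two ellipsoidal lung lobes,
a pure-air trachea descending to a carina where it branches into main
bronchi entering each lobe, a water-equivalent calibration insert (0 HU),
and a bone rod (+1500 HU).  The two respiratory phases share one geometry
and differ only in the parenchymal air fraction (defaults: 0.55 at
end-expiration, 0.70 at peak inspiration — mid-range values for healthy
anesthetized mice; the protocol's source study reports no lung HU ranges,
so these are stated defaults, not fitted ones).  Grey values are emitted
on a raw scale through configurable air/water anchor values so that
calibration is exercised for real.  Truth (lung mask, per-phase air
volumes, FRC, VT) is summed from the exact fraction fields before noise.

Lesions are spheres that must intersect the lung: both pneumonitis and
fibrosis reduce the parenchymal air fraction by a severity factor in
[0, 1] at both phases; fibrosis can additionally dilate the airway tube
within the lesion (enlarged airways inside dense scar).  Lesion effects
are phase-symmetric because the source observations are qualitative; no
kinetics are invented.

Noise is additive Gaussian in HU-equivalent units (converted through the
raw-scale slope), applied after geometry.  Projection-domain noise, beam
hardening, cardiac motion, lung motion between phases (the geometry is
static; only the mixture fraction changes) and realistic airway trees are
deliberately not modeled.  Consequently, passing recovery tests
demonstrates correctness of the measurement chain under the stated image
model — not robustness to reconstruction artifacts or anatomical
variability beyond the randomized lobe sizes and air fractions.

## Calibration and filtering

Calibration is per image: the mean raw value over a tracheal-air ROI maps
to −1000 HU and over a water ROI to 0 HU, giving an affine,
order-preserving rescale.  For phantoms the ROIs travel in image
metadata; for external data they are supplied in the manifest/config.

The bilateral filter weights each neighbor by the product of a spatial
Gaussian (sigma in mm, default 0.075 = one voxel; neighborhood truncated
at 3 spatial sigmas) and a range Gaussian on intensity difference
(default 100 HU).  The range sigma is far below the lung/soft-tissue step
(~600 HU), so edges are preserved while 25 HU noise is suppressed; in the
infinite-range limit the filter reduces exactly to truncated Gaussian
smoothing (tested against `scipy.ndimage.gaussian_filter`).  The kernel
is a compiled (numba) loop with a pure-numpy fallback.  Filtering is
applied before calibration, matching a reconstruction-side filter; since
both the filter's Gaussian limit and the calibration are affine-
compatible, the order is immaterial in that limit and recorded in config
otherwise.

## Segmentation

The bounding ROI spans the grid below a superior face placed
round(2 mm / spacing_z) voxel planes above the carina landmark (27 planes
at 0.075 mm).  The lung is the maximal connected component of voxels
with HU ≤ −160 containing the seed, restricted to the ROI.  Choices that
must be fixed for exact oracle tests: the threshold is inclusive;
connectivity defaults to 26-neighbor (6 selectable); voxel indices are
0-based; boxes are half-open [lo, hi).  The ROI intentionally admits the
proximal airway below its superior face and no airway stripping is
performed — a documented limitation that adds a ~2 mm trachea stub
(≲1% of end-expiratory air content, cancelling exactly in VT).

Automatic seeding takes the centroid of HU < −400 voxels in the ROI and,
because the centroid of two lobes falls in the mediastinum, snaps to the
nearest sub-threshold voxel when needed.

A leak is declared when the mask touches more than 2 ROI faces or fills
more than 90% of the ROI.  On leak, the touched faces are stepped inward
by 0.5 mm and the growth repeated up to `max_retries`; an unresolved leak
is not an error but a flagged result, and group summaries never hide
flagged subjects.  The leak rule is an explicit, configurable stand-in
for the manual ROI adjustment a human operator would perform; no
published failure criterion exists for this protocol.

A consequence of threshold segmentation worth noting: consolidation
severe enough to push tissue above −160 HU (severity ≳ 0.7 at the default
expiratory fraction) leaves the segmentation entirely, so the masked mean
CT number is monotone in lesion severity only while lesions remain
segmentable; measured FRC keeps decreasing throughout.  This mirrors how
dense focal fibrosis can be under-represented in threshold-based CT
analysis.

## Gating simulation

The respiratory trace is a per-cycle linear rise, linear fall, and
baseline plateau; defaults are a 600 ms period (~100 breaths/min) with
the end-expiratory plateau occupying 0.8 of the cycle, cycle-period
jitter and additive noise both optional and seeded.  The plateau default
is chosen so the fixed ~350 ms second-trigger delay lands inside the
plateau across 400–1000 ms periods; with shorter plateaus the delayed
trigger can overrun the pause at the fast end of that range.

Trigger detection is causal.  During the first observed cycle there is no
amplitude reference, so the detector fires at the first confirmed local
maximum (a 5% drop from the running max) — just after the peak, still
within the ±5%-of-cycle peak-inspiration window.  Thereafter it fires at
the first rising sample crossing 0.9× the running amplitude estimate
(mean of the last 3 confirmed cycle peaks), subject to a 250 ms
refractory period.  Ground-truth phase labels come from the generator's
cycle structure: peak inspiration within ±5% of the cycle around the
peak, end-expiration inside the plateau, transition otherwise.

## Statistics

Image metrics are compared with classical one-way ANOVA
(F = MSB/MSW, df (k−1, N−k)) plus Tukey's HSD, using the Tukey–Kramer
standard error for unequal n; heteroscedastic outcomes use Welch's ANOVA
(Satterthwaite df) and the Brown–Forsythe F* with its matched df, with
Dunnett's T3 post hoc (pairwise Welch t with Satterthwaite df, adjusted
through the studentized maximum modulus).  All statistics are computed
from their defining formulas; distribution functions are evaluated by
scipy (incomplete-beta F CDF, quadrature-based studentized range).  The
studentized maximum modulus has no scipy implementation and is evaluated
by Monte Carlo with a fixed seed (default 1e6 draws; the seed and draw
count are parameters).  α = 0.05 throughout.

Test oracles are independent routes: a label-permutation p-value, a
Monte-Carlo studentized-range distribution, two-group algebraic
identities (F = t², q = √2·|t|), and cross-checks against
`scipy.stats.f_oneway`, `scipy.stats.tukey_hsd` and `pingouin`.

Longitudinal deltas are value(endpoint) − value(week 12), endpoint
meaning each animal's latest measured week (groups may end at different
weeks); negative means reduction.  Group percent change is reported both
as the percent change of group means and as the mean of per-animal
percent changes, since the two differ under animal-level variability.
Missing animals are handled by per-timepoint complete-case analysis.

## Simulation studies and problem sizes

`gatedlung.validate` runs the qualification studies:

- **Phantom recovery** — seeded populations of 128³ phantoms with
  randomized air fractions (expiration 0.45–0.62, inspiratory increment
  0.10–0.20) and ±10% lung size.  Noise-free, FRC/VT recover within 2%
  of truth with Dice ≥ 0.99; at 25 HU noise with bilateral filtering,
  within 5% with Dice ≥ 0.95.  The test suite uses 20 phantoms per
  condition and the acceptance script 8, sizes chosen to keep the
  studies at a few minutes on one CPU.
- **Effect detection** — replicate three-group cohorts (control, sham,
  treated; n = 6) are simulated at the measurement level: per-animal FRC
  with 15% biological CV (typical inter-animal spread of inbred mouse
  lung volumes) times a 2% measurement CV matching the pipeline's
  characterized recovery error.  A 50% treated-group FRC reduction is
  detected by ANOVA + Tukey in well over 80% of 200 replicates; with no
  imposed effect the rejection rate over 2000 replicates stays near 5%.
  Image-level simulation per replicate would add nothing here: the image
  chain's error is already characterized by the recovery study and
  enters as the measurement CV.

## Numerical conventions

- Volumes are mL (mm³/1000); spacing is mm per array axis in (z, y, x)
  order; z increases toward superior.
- Histograms use half-open bins with out-of-range values clipped into
  the end bins, so counts always sum to the masked voxel count.
- All randomness flows from user-supplied seeds through
  `numpy.random.default_rng`; cohort generation derives per-animal
  streams from (seed, group index, animal index) so results are stable
  under regrouping.
- CSV reports embed the configuration hash and seed in a header comment;
  reruns with identical config and seed are byte-identical.

## Known limitations

- The phantom's static geometry means phase differences are purely
  density differences; real lungs deform.
- No lobe separation, vessel exclusion, or airway-tree extraction.
- The leak rule and the quantitative abnormality flag (mean CT more than
  2 control SDs above the control mean) are artifact-level stand-ins for
  human judgment calls.
- Tukey's unequal-n handling is Tukey–Kramer; exact unequal-n Tukey is
  not implemented.
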