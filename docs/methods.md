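# Methods

This note documents the models, parameters and numerical choices behind
`retclust`, and what the synthetic experiments do and do not establish.

## Scan geometry and coordinate conventions

Macular cubes span 6.00 × 6.00 mm, acquired as 128 B-scans of 512 A-scans.
All analysis happens on the standardised 512 × 512 raster in right-eye
format with zero disc-to-fovea tilt: row 0 is superior retina, column 0
temporal retina, retinal x increases nasally and y superiorly. The analysis
grid averages 8 × 8-pixel blocks into 64 × 64 cells of exactly
93.75 × 93.75 µm, anchored at pixel (0,0); a cell is valid when at least
50% of its 64 pixels are valid (the source material excludes bad pixels but
states no block-level rule; 50% is this package's choice). Visual-field
coordinates are degrees with y > 0 the superior field and x > 0 the
temporal field; optics invert the vertical axis, so field (x, y) projects
onto retina (x, −y). Lateral conversion uses 0.288 mm/° (configurable).

## Standardisation chain

Fixed order: boundaries → thickness → resize → right-eye orientation →
rotation to zero tilt → (ORC only) displacement correction.

* Thickness = (lower − upper boundary) × axial scale; default axial scale
  1.953 µm/px (2.0 mm per 1024 px). NaN boundaries mark segmentation
  errors; those pixels are invalid and never re-enter.
* Resize 128→512 rows uses pixel-centre-aligned cubic convolution
  (Keys, a = −0.5), which reproduces constant and linear profiles exactly
  away from clamped edges. Rotation and displacement use cubic-spline
  resampling (`scipy.ndimage.map_coordinates`).
* Validity propagation is conservative: an output pixel is invalid if any
  source pixel in the 4 × 4 interpolation support is invalid or outside the
  field (no extrapolation). Valid-pixel counts therefore never increase.
* Displacement correction pulls ORC content centrifugally: the value at
  eccentricity e is resampled from e + d(e) along the same ray, aligning
  outer-retina content with its inner-retinal partners. The default d(e)
  is a meridian-averaged piecewise-linear profile peaking at 1.5° near 2°
  eccentricity and reaching 0 by 8°; per-meridian tables are supported.
  Whether the original analysis displaced the ORC outward or its partners
  inward is not documented; the outward convention is fixed here and
  exposed in configuration.

## Synthetic cohorts

The generator defines the study conditions under which everything is
tested.

**Demographics.** Age is truncated-normal 50.4 ± 16.9 y on [20, 86];
45% male; tilt 6.9 ± 3.4°. Spherical equivalent is built as
SE = −0.55 + 0.058·(age − 50.4) − 0.6·[male] + ε, ε ~ N(0, σ) with σ chosen
so the marginal SD is 1.94 D, then truncated to [−6, +6] D. The couplings
(corr(age, SE) ≈ 0.5; males 0.6 D more myopic) are deliberate: backward
elimination only behaves realistically under collinearity. From
omitted-variable algebra, dropping SE then shifts the ORC age coefficient
by b_SE·γ ≈ 0.437 × 0.058 ≈ 0.025 µm/y (≈ 30% of −0.078, comfortably over
the 10% reinstatement rule), and dropping sex shifts the ORC SE
coefficient by ≈ 0.10–0.14 µm/D (≈ 25–30%), while for GCIPL/INL (true sex
effect 0) the same shift is noise-scale (≲ 5%) so sex is correctly
excluded. Both removal orders therefore reproduce the expected per-layer
matching pattern.

**Layer models.** Baseline thickness is a piecewise-linear radial template
per layer (GCIPL/INL: foveal pit, perifoveal peak near 1.2 mm, peripheral
decline; ORC: foveal maximum declining outward). Effects are linear:
age slope, SE slope, sex offset, referenced to 50 y. Ground-truth defaults
(µm/y, µm/D, µm): GCIPL −0.112 / +0.513 / 0; INL −0.039 / +0.258 / 0;
ORC −0.078 / +0.437 / −1.953. Each eye receives a constant individual
offset (SD 4.35 / 1.45 / 6.20 µm per layer, calibrated so that OLS standard
errors on n = 548 cohorts match the intended values) plus spatially
correlated measurement noise: unit-variance smoothed white noise with a
250 µm correlation length, scaled by the per-layer noise SD (2.0 / 1.5 /
2.5 µm by default). Large rasters generate the field on a coarse grid and
upsample bilinearly; the field is smooth at that scale, so the error is
far below the noise amplitude.

**Defects.** An arcuate defect is an annular band (default 1°–8°
eccentricity, full hemifield sweep from the nasal horizontal) on the named
retinal hemifield(s). GCIPL thins by `gcipl_depth`, the INL by
`inl_ratio` × depth (default 0.3), the ORC gains `orc_delta` (default 0).
The field projection loses `vf_depth` dB, optionally tapered deeper
nasally (used to synthesise ring defects whose arcuate test requires
nasally-dominant loss).

**Visual fields.** The 10-2 lattice is the 68-point odd-degree grid with
x² + y² < 90. Pattern deviation = defect projection + noise; total
deviation equals pattern deviation (no generalised depression is
simulated). MD is the unweighted mean of total deviations and PSD the
sample SD of pattern deviations — simplified versions of the proprietary
indices, which is why synthetic PSD keeps growing in advanced loss instead
of saturating beyond ≈ −20 dB MD as the real index does. Probability
flags use fixed thresholds (p<5%: ≤ −3 dB, p<2%: ≤ −4.5, p<1%: ≤ −6,
p<0.5%: ≤ −8), configurable.

What the generator does **not** emulate: OCT speckle and B-scan structure,
microcystic macular oedema, segmentation-error geometry (dropout is
uniform when requested), per-individual anatomical shape variation beyond
a constant offset, measurement floors, and the PSD saturation above.
Passing tests therefore establish algorithmic correctness and sensitivity
under idealised but calibrated conditions, not clinical performance.

## Visual-field classification

Defect clusters are connected components (8-connectivity) of points
flagged p < 5% or worse containing ≥ 3 points with ≥ 1 at p < 1% or worse;
encroaching points count toward the minimum. Fields type as C (no
qualifying cluster, regardless of MD), S/I (all defect points in one
hemifield with ≤ 1 point encroaching), or R. Because rows y = ±1 are
mutually adjacent, a ring defect can form a single component; typing
therefore evaluates hemifield *parts* of each cluster, a part qualifying
under the same ≥3/≥1-at-p<1% rule. R requires a qualifying arcuate part in
each hemifield, where "arcuate" is operationalised as: the part reaches
the nasal half (x < 0) and its nasal-half mean pattern deviation is ≤ its
temporal-half mean. Non-arcuate two-hemifield cases take the hemifield of
the larger part (ties: more negative mean pattern deviation, logged). MD
bins are 3 dB wide with boundaries closed on the worse side.

## Normative model and matching

OLS (statsmodels) of whole-scan mean thickness on age, SE and sex
(female = 0), n ≥ 10, collinear designs rejected. One elimination round:
remove the largest-p covariate, refit, compute |Δβ|/|β_pre| × 100 for each
retained coefficient (intercept excluded, absolute values); any change
≥ 10% reinstates the removed effect. The final covariate set drives
matching: ± 7.5 y, ± 2.00 D, and same sex where sex survived. The matched
participant's own record is excluded from its pool. With small simulated
pools a participant at the demographic margins can match nobody; the
implementation then relaxes sex matching and, if still empty, widens the
windows in 1.5× steps with warnings — the nearest-available-normals
fallback. Deviations are raw µm differences (glaucoma − normative mean),
never percent-of-normal.

## Clustering

*Linkage.* Within-groups average linkage with squared Euclidean distance:
the next merge minimises the mean pairwise squared distance over **all**
point pairs inside the union. Sufficient statistics (member count, vector
sum, sum of squared norms) give each candidate cost in O(d); a cached
row-minimum scheme with rescans keeps the full merge sequence at roughly
O(n²). Ties break on the smallest slot pair, which makes the sequence
deterministic; a numba-compiled loop handles large grids with a pure-numpy
fallback verified to produce identical sequences.

*Starting count.* Gaussian likelihood with cluster means and pooled
variance, p = k·d + 1 parameters, BIC = −2 log L + p ln n, evaluated on
tree cuts k = 1..k_max (default 10). On continuous data the raw BIC
improves for every added mean, so k₀ uses the classic two-stage
auto-clustering rule: a coarse bound from the BIC ratio of change (stop
when the next improvement is < 4% of the 1→2 improvement), then
refinement by merge distance — among candidate ks, the one whose merge
jump ratio R(k) = d(k→k−1)/d(k+1→k) clearly dominates (by > 1.15×) wins,
otherwise the larger of the top two candidates.

*Refinement.* Cluster statistics are the mean and (population) SD of the
scalar per-cell subcohort mean deviations. While any pair has
d′ < 1, the smallest-d′ pair merges and all statistics are recomputed;
final solutions satisfy min pairwise d′ ≥ 1 (asserted) or k = 1. Two
zero-variance clusters have d′ = 0 when equal and +∞ otherwise. Labels are
ordinal by descending mean (label 1 most positive); invalid cells carry 0.

*Features.* Two modes exist. The default pipeline mode clusters each grid
location by its vector of per-participant deviations (missing entries
imputed with the cell mean), with d′ always computed on the scalar cell
means. The scalar mode (cluster on the subcohort-mean value itself) is
available by omitting the feature matrix. The vector mode is the default
because on smooth scalar fields any value band can be split into
sub-bands with d′ ≈ 2.7 (band-splitting a Gaussian is scale-invariant), so
scalar clustering pins k at k_max and fragments genuine defects; with
vector features, partitions of a homogeneous region have nearly equal
scalar means and the d′ rule collapses them, yielding the small cluster
counts the method is meant to produce.

## Agreement and severity

A cluster is defective iff its mean is negative **and** below the mean
deviation over all valid cells. Agreement between two binarised layers is
computed over commonly valid cells: percentage agreement 100(a+d)/n and
Cohen's κ = (p_o − p_e)/(1 − p_e) with chance agreement from the
marginals; κ is undefined (N/A) when either map is single-category —
which in practice means a layer produced no defective cluster at all. The
κ p-value uses the large-sample null SE (Fleiss); Spearman correlations
use mid-rank ties with the t-approximation p-value. Per participant, the
within/outside difference uses the defective-GCIPL mask of that
participant's (defect-type × MD-bin) stratum; participants whose stratum
lacks a defective GCIPL cluster contribute no difference (excluded and
counted). Cross-layer correlations are Spearman r over the 64 × 64 grid,
per participant.

## Experiment problem sizes

The validation studies run at sizes chosen to be statistically decisive on
a single CPU:

* regression recovery: 50 cohorts × n = 548, maps synthesised at a reduced
  32 × 128 raster (only whole-scan means enter the fit; the intercept
  shift from raster resolution is irrelevant to slopes);
* planted-defect recovery: 50 replicates of 20 glaucoma + 80 healthy eyes
  at 512 × 512, 10 µm GCIPL depth, INL ratio 0.3, untouched ORC, 2 µm
  noise, 1 dB field noise; glaucoma demographics bounded (35–70 y,
  −4..+2.5 D) so matched subgroups exist at this pool size;
* severity gradient: 80 glaucoma + 100 healthy eyes, depth uniform on
  2–14 µm with field depth 1.8 × structural depth, giving MD spanning all
  four bins; ORC null bounds from 2000 permutations (99% band).

Cohort-scale maps are synthesised directly in standardised geometry; the
standardisation chain itself is validated by its own unit and property
tests (including the mirrored-eye consistency check) and runs end to end
in the demo pipeline, which preprocesses raw-raster maps.

## Known limitations

Simplified MD/PSD (no proprietary weighting, no saturation); additive
defects without measurement-floor behaviour; a single constant
interindividual offset rather than shape variation; hemifield-part defect
typing is one reading of criteria written for clinical readers; the
displacement profile is a stylised meridian average; agreement is computed
only over cells valid in both layers.
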