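# Methods

## The quantity being computed

The package quantifies PSMA-avid tumor burden on PET as a
reference-normalized volume–uptake product. For lesion *i*:

    PSMAscore_i = V_i · SUVmean_i / SUVmean_ref        [mL]

where *V<sub>i</sub>* is the segmented uptake volume, SUV<sub>mean,i</sub>
the mean standardized uptake value over the lesion mask, and
SUV<sub>mean,ref</sub> the mean uptake of a healthy reference organ. The
SUV ratio is dimensionless, so the score carries units of millilitres:
it is a normalized total-lesion-uptake analogue of total lesion
glycolysis in FDG PET. Anatomic compartment scores (prostate/prostate
bed, nodal, osseous) are sums of their lesion scores; the composite is
the sum of the compartments, hence exactly the sum over all accepted,
classified lesions — compartment grouping is score-neutral, which the
test suite asserts as an additivity invariant.

Response is the signed percent change `100·(after − before)/before` of
each score between a baseline and a follow-up scan, and of serum PSA.
Per compartment, response is correlated with PSA response by sample
Pearson correlation over pairwise-complete patients, with two-tailed
significance from `t = r·√((n−2)/(1−r²))` on *n* − 2 degrees of freedom.

## Reference uptake

Both standard PET reference tissues are computed as plain arithmetic
means over supplied masks: the liver and the blood pool (aorta). No
trimming or robustification is applied — the quantity is defined as
SUVmean. The normalizer defaults to the blood pool, with the liver
available by configuration; either is defensible and the package does
not hard-code a per-compartment choice. Organ masks are inputs, not
inferred: automated CT organ segmentation is out of scope, and the
mask format (one integer label volume plus a JSON sidecar naming the
labels and the bifurcation plane) keeps the contract explicit.

## Lesion detection and segmentation

The detector is deliberately classical and parameter-light, tuned for
sensitivity rather than specificity, with a reviewer step downstream
to remove false positives:

- **Detection.** Optional Gaussian smoothing (FWHM in mm, default off),
  then 26-connected components of voxels with SUV ≥
  `max(detect_abs, detect_rel · SUVmean_bloodpool)`; one seed — the
  hottest voxel — per component. Default `detect_rel = 2`,
  `detect_abs = 0`. Voxels of the reference organs themselves are
  excluded in the full pipeline, since their physiologic uptake is not
  disease. On a noise-free phantom every lesion whose uptake clears
  the threshold is found (100% recall), which is the detector's
  testable contract.
- **Segmentation.** Adaptive threshold
  `T = max(f · SUVmax, SUVmean_bloodpool)` with `f = 0.4` — the common
  peak-relative convention for PET delineation, floored at the
  reference level so the mask can never descend into blood-pool-level
  background. SUVmax is taken over the supra-detection-threshold
  component containing the seed; the lesion mask is the connected
  component of supra-*T* voxels containing the seed. Raising *f* can
  only shrink a mask (tested as a set-containment property). Lesions
  under `min_volume_ml = 0.1` mL are discarded as single-voxel noise.
  When two seeds' masks would overlap (components of nested superlevel
  sets), seeds are processed hottest-first and later masks keep only
  their unclaimed connected piece, so lesion masks are pairwise
  disjoint by construction.
- **Review.** An accept/reject map keyed by lesion id mirrors
  physician review; absent ids default to accept, rejected lesions are
  excluded from every score.
- **Compartment classification.** Arg-max fractional overlap of the
  lesion mask with the prostate-bed, skeleton, and nodal-region masks;
  ties break with fixed priority osseous > nodal > prostate/bed. Nodal
  lesions split by centroid axial position against the common-iliac
  bifurcation plane: strictly above → non-regional, at/below →
  regional. Regional and non-regional nodes pool into a single nodal
  compartment for scoring. A lesion overlapping no compartment mask is
  left unclassified, warned about, and excluded from scores.
  Coordinates are physical mm with the origin at the first voxel
  centre.

This stage replaces a proprietary learned detector/segmenter. It is
described and tested as what it is — a threshold detector with
peak-relative adaptive segmentation — and no claim is made that it
reproduces any particular platform's contours on clinical scans; the
scoring, response, and correlation stages are independent of detector
internals.

## Response conventions

- A compartment percent change is **missing** when the patient had no
  baseline disease there (nothing to score a change against); missing
  is distinct from zero throughout.
- Baseline present, follow-up absent → the disease resolved: follow-up
  score 0, change −100%.
- Baseline absent/zero, follow-up positive → **new disease**: no
  percent is defined, the row is flagged and excluded from
  percent-change statistics.
- PSA response is carried as the signed change (negative = decline), so
  concordant decline gives positive correlations.
- Patients with unknown PSA are dropped pairwise from PSA-involving
  statistics but retained in imaging-only summaries.
- Scores and percents are kept at full precision internally; display
  rounds percent changes half-away-from-zero to integers and scores to
  one decimal.

## Correlation flags

A compartment correlation is **suppressed** (reported as not
calculated) when fewer than two complete pairs exist or either column
is constant. Separately, a column whose modal value exceeds 75% of
entries is flagged **low-variance**: in a cohort of near-complete
responders the prostate/bed column is almost constant at −100, and a
correlation against a near-degenerate predictor is computed but should
not be interpreted. With |r| = 1 the t statistic diverges and p is
reported as exactly 0 with a `perfect` flag.

## Synthetic data

The phantom generator emulates a whole-body scan at the level the
analysis needs, not anatomic realism: a uniform background (SUV 1), a
liver plateau (SUV 5) and a periaortic blood-pool plateau (SUV 1.5) as
reference regions, a stylized spine, prostate-bed and periaortic nodal
region for classification, and spherical lesions of uniform uptake.
Spheres are deliberate: the analytic volume 4/3·π·r³ is an exact
oracle, against which segmented volumes agree within voxelization
error (≤ 15% at 8–10 mm radius on a 2 mm grid). Noise is additive
Gaussian on SUV, truncated at zero. What phantoms do **not** model:
attenuation/reconstruction physics, partial-volume blur, heterogeneous
lesion uptake, realistic organ shapes — so passing phantom tests
demonstrates correctness of the measurement chain, not clinical
detection performance.

The cohort generator emulates the statistical structure of a treated
metastatic cohort of about 30 patients: per-compartment disease
prevalence (0.90 prostate/bed, 0.83 regional nodal, 0.30 non-regional
nodal, 0.60 osseous), log-normal baseline burden with medians 21.6 /
4.0 / 2.0 / 2.2 and log-sd 1.2 (spanning roughly 0.1–150, the range
observed clinically), a multiplicative treatment effect that is a
mixture of complete response (probability 0.55) and a log-normal
residual (median 0.08, log-sd 1.0) so the median decline is 100%, and
imaging intervals log-normal around 8 months clipped to 3–30. PSA is
linked to composite burden by

    PSA = s · (composite + c0)^β · exp(σ·ε),  ε ~ N(0,1)

with defaults s = 0.5, c0 = 0.5, β = 1, σ = 0.3. The power law with
multiplicative noise is the simplest strictly-positive link whose
noise-free limit (σ = 0, c0 = 0, β = 1) forces PSA percent change to
equal composite percent change exactly — pinning the downstream
correlation at r = 1 to machine precision, the identifiability check
for the entire chain. The link asserts association, not PSA
physiology. With σ = 0.1 and 200 patients, log-log regression recovers
β within ±0.1, which the suite checks as a parameter-recovery test.

## Packaged cohort fixtures

The per-patient tables of the 30-patient study cohort are transcribed
verbatim into two CSVs (clinicopathologic data with % PSA reduction;
signed percent change per compartment, composite, and PSA) and
checksum-verified on load. The percent cells are integer-rounded as
printed; recomputed correlations therefore differ from the published
row (0.95 / 0.38 / −0.06 / 0.61) by up to a few hundredths, and the
reproduction report checks agreement within ±0.05. Known internal
inconsistencies of the printed tables are preserved, not repaired: one
patient's compartment scores sum to 69.82 where the printed composite
is 69.72; the transcribed intervals have median 7.5 months where the
narrative rounds to 8; four patients with nodal disease at baseline
have no nodal percent cell; and the abstract's ranges disagree with
the table cells, so only the table is treated as data. Baseline
per-patient scores are not printed, so baseline score–PSA correlations
are exercised on synthetic cohorts only.

## Numerical and design choices

- 26-connectivity for all 3D component operations.
- Half-away-from-zero integer rounding for displayed percents (the
  printed tables' own rounding is inconsistent at the ±1 level, so
  integer-percent comparisons use ±1 tolerance).
- Tables round-trip CSV bit-exactly (`%.17g` writing, round-trip float
  parsing).
- Config files reject unknown keys.
- Deterministic generators: a spec plus seed reproduces outputs
  byte-for-byte; detection seed order is sorted by descending peak
  intensity, then index.
- Test problem sizes (48×48×64 phantoms at 2 mm, cohorts of 25–200)
  are chosen so the whole suite runs in seconds while keeping
  voxelization error well inside the tolerances being asserted.

## Limitations

No DICOM ingestion, no PET–CT registration, no automated organ
segmentation, no lesion-level longitudinal matching between scans, no
multiple-testing correction (none is part of the analysis being
implemented), and no claim of concordance with proprietary clinical
software on real scans.
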