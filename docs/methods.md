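# Methods

## Scope and model

`occlureg` is an in-silico re-creation of a plate-based accuracy study: how
does the number and spatial distribution of paired reference landmarks affect
the rigid reconstruction of the maxillary–mandibular (intercuspal) relation
from separate optical scans? Everything downstream of the physical hardware
is modelled: landmark geometry, the two measurement channels, sphere-center
extraction, group-wise rigid registration, and the trueness/precision/
reliability statistics. Physical fabrication, scanner physics (occlusion,
specularity, meshing), plaster deformation and surface-based
iterative-closest-point registration are out of scope; only the concave
center landmarks are modelled, not tooth surfaces.

## Plate geometry

Each plate carries nine hemispherical concaves (default radius 3 mm) on its
right, front and left faces; the two plates' concaves form nine vertically
aligned pairs. The true inter-concave spacings of such plates are not
standardized, so the layout is fully parameterized with plausible defaults:
face width 60 mm, lateral concaves 20 mm apart along each face, front
concaves 15 mm apart, patient-right labels (FDI 1x/4x) at negative X, and
90 mm between the plates' reference faces. Every length is overridable
(including explicit per-concave centers) so conclusions can be checked for
layout sensitivity.

The default layout additionally staggers concave heights (lateral concaves
rise 2 mm per posterior step; the off-center front pair sits 1 mm up). Pair
members stay vertically aligned, but the nine reference distances D_R span
90–98 mm rather than collapsing to a single value. A printed plate does not
place all nine concaves at exactly one height, and distance variety is what
makes the reliability (ICC) analysis non-degenerate: with identical true
distances the between-pair variance would be zero by construction and the
ICC meaningless. The stagger is a parameter (`height_stagger`, mm) and can
be set to 0.

The observation coordinate system mirrors the measurement convention:
maxillary landmarks 12, 0, 22 span the z = 0 plane, landmark 0 is the
origin, X runs along the 12→22 line, and the frame is right-handed with Z
pointing from the mandibular toward the maxillary plate (disambiguated via
0' when present). Inter-landmark distances are invariant to this choice; it
matters only for presenting coordinates.

Rigid motions are represented as rotation matrices plus translations.
Claimed rotations are validated (orthogonality and det = +1 within 1e-10),
not silently re-orthogonalized; an explicit `repair=True` flag projects a
near-rotation onto SO(3).

## Measurement simulation

Device accuracy figures are interpreted as 1-σ isotropic Gaussian noise —
the simplest reading consistent with a single published number, and
configurable:

| parameter | default | meaning |
|---|---|---|
| `sigma_contact` | 0.024 mm | per-coordinate noise of one contact probe |
| `sigma_scan` | 0.059 mm | per-point noise of one scanned surface sample |
| `n_probe_repeats` | 3 | contact probes averaged into the standard data |
| `n_scan_repeats` | 3 | sphere fits averaged into the fitting data |
| `points_per_concave` | 300 | surface samples per concave per scan |
| `cap_half_angle_deg` | 75° | sampled portion of each hemisphere |
| `operator_subsample_fraction` | 0.7 | fraction of points an operator keeps |
| `n_repetitions`, `n_operators` | 15, 2 | the repeated-measurement design |

The cap half-angle default of 75° reflects that real scans lose the concave
rim; 90° would be the full hemisphere. Sampling is uniform in cap area
(cos θ uniform on [cos α, 1]).

Each (jaw, operator, repetition) scan session draws one random rigid scanner
pose — rotation uniform over SO(3) via normalized Gaussian quaternions,
translation uniform in a ±50 mm cube — and the session's three replicate
clouds share that pose, since the repeats model re-fitting the same scan,
not re-scanning. The operator effect is an independent random subsample
(default 70%) of each cloud before fitting, mimicking manual selection of
the concave region in scan software; there is no systematic inter-operator
bias term by default, which is the minimal mechanism yielding non-trivial
but high inter-operator reliability. Fractions may be set per operator to
probe asymmetric operators.

All randomness flows from one master seed through named `SeedSequence`
substreams keyed by (purpose, jaw, operator, repetition, concave), so any
part of a run can be regenerated independently and the whole run is
reproducible from its configuration alone.

## Sphere fitting

Two stages, both exact on noiseless data:

1. **Algebraic**: ‖p − c‖² = r² is linear in (c, r² − ‖c‖²); solved by
   least squares. Rank < 4 (fewer than four points, or a coplanar cloud)
   raises a degenerate-fit error.
2. **Geometric**: Levenberg–Marquardt on the orthogonal-distance residuals
   ‖pᵢ − c‖ − r with analytic Jacobian, gradient tolerance 1e-10, capped at
   100 iterations; non-convergence is flagged, not fatal, and the result
   never has a larger objective than its initialization.

The geometric fit is the reported one. Free-radius fitting is the default
(matching a generic "best-fit sphere" feature extraction); a fixed-radius
variant (`fixed_radius_fit`) holds r at the design radius, which is known by
construction, and optimizes only the center — Monte-Carlo tests confirm it
is never worse on average. On narrow caps (45°) with realistic noise the
free-radius fit stays finite and convergent, with inflated center error, and
is regression-tested for that.

## Registration and evaluation

Alignment is per jaw against the standard set — the standard encodes the
articulator-frame jaw relation, so aligning both jaws to it places them in a
common frame. The estimator is the closed-form equal-weight Kabsch solution
(centroid subtraction, 3×3 cross-covariance, SVD, determinant sign
correction); no scaling term, because plates and casts are treated as one
rigid body. Any three-point configuration is planar, so the degeneracy test
is collinearity (second singular value of the centered source < 1e-9), under
which the optimum is a continuum and a typed error is raised. The order of
landmark ids never changes the result (equal weights), and pre-composing the
source with a rigid motion changes the estimate by exactly that factor.

Seven canonical reference groups are compared (three-pair groups 1–3,
four-pair groups 4–7; group 1 = {14–44, 0–0′, 24–34}, group 4 =
{14–44, 12–42, 22–32, 24–34}, group 7 = {12–42, 11–41, 21–31, 22–32}, etc.).
For each unit, distances D_M of the pairs *not* used for alignment are
compared with the reference distances D_R taken from the simulated contact
standard (a flag switches to noiseless nominal ground truth for oracle
studies). Trueness RMSE is computed per (operator, repetition, group) over
the held-out pairs; precision RMSE per (operator, group) and repetition as
the RMS deviation from the per-pair repetition means. Group summaries report
mean ± sd of the per-repetition RMSE vectors, pooled over operators for
trueness and per-operator-then-pooled for precision; this aggregation is a
stated, configurable default since summary conventions vary.

## Statistics

One-way ANOVA (F = MS_between/MS_within) and Tukey HSD (studentized range
with the pooled within-group mean square; Tukey–Kramer standard error at
unequal n) compare the seven groups' RMSE values. Reliability uses two-way
single-measurement ICCs: absolute agreement, two-way mixed, for
intra-operator matrices (held-out pairs × 15 repetitions, per operator and
group) and consistency, two-way random, for inter-operator matrices
(per-pair repetition means × 2 operators, per group). The mixed/random
distinction affects interpretation, not the point-estimate formulas for
these single-measure forms. Confidence intervals follow the standard F-based
derivations (exact for consistency; Satterthwaite-approximate for absolute
agreement). Degenerate inputs (constant matrices, zero within-group
variance with zero between-group variance) raise typed errors rather than
returning NaN. Normality and variance-homogeneity pre-checks are not
re-implemented; `experiment_statistics` accepts a hook for stock routines
(e.g. `scipy.stats.shapiro`, `levene`) and written reports note their
absence. Implementations are validated in the test suite against independent
references (`scipy.stats.f_oneway`, `scipy.stats.tukey_hsd`,
`pingouin.intraclass_corr`).

## Numerical and design notes

* Zero-noise configurations propagate exactness end to end: every trueness
  and precision RMSE is 0 within 1e-9 mm, and reliability saturates at
  ICC = 1 (the D_M matrices then have pure row structure with no residual).
* Within one experiment the contact-probe error of the standard set is
  systematic (one draw serves all 210 units), so experiment-level mean
  trueness varies noticeably across seeds while the *ordering* of groups —
  spread groups beating front-concentrated ones — is stable; the ordering
  check in the acceptance suite therefore aggregates 100 independently
  seeded experiments.
* Problem sizes in the test suite: unit and property tests run reduced
  designs (fewer repetitions, 50–150 points per concave) chosen to exercise
  the same code paths; the end-to-end ordering and recovery checks run the
  full default conditions (300 points, 15 × 2 design, study noise levels).
* Sphere-center recovery at the default conditions was characterized with a
  development-time Monte-Carlo oracle (brute-force Nelder–Mead minimization
  of the same objective, independent of the package's LM code path):
  3D center RMSE ≈ 0.019 mm at 300 points/σ 0.059 mm/75° cap, and 3-fold
  averaging shrinks it by ≈ 1/√3. The regression bound in the tests
  (0.024 mm) is that measurement plus headroom.

## What the generator does and does not show

The synthetic data reproduce the *statistical structure* of the study design
(device noise magnitudes, repeat averaging, arbitrary scan poses, operator
subsampling, the full factorial layout), not the physical error sources of a
real laboratory: no plate print shrinkage, no plaster deformation, no
scanner mesh artifacts, no systematic operator bias, and a guessed (though
configurable) plate geometry. Passing tests demonstrate that the pipeline's
estimators are correct and that the leverage-driven ordering of
reference-point distributions follows from registration geometry alone; the
absolute RMSE magnitudes depend on the assumed noise model and layout and
are not calibrated to any particular physical apparatus.
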