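# Methods

## Model and procedure

A lesion pattern is a binary indicator field z(x) ∈ {0, 1} on a regular 3D
voxel grid in Montreal Normal Brain geometry. Its second-order spatial
structure is summarized by directional empirical semivariograms

γ(h) = 1/(2 n(h)) Σ (z(xᵢ) − z(xᵢ+h))²,

evaluated at pure axis-aligned shifts h = 1..max_lag voxels along each of
the three grid axes. Because pairs are exact shifts on a regular grid, no
angular or distance tolerance is involved and the computation is exact: the
implementation aligns the array with a shifted copy of itself and counts
mismatching pairs (for binary data the squared difference is an XOR). Pairs
that would cross the array boundary are simply not formed, so the pair count
at lag k along an axis of length n_d is (n_d − k) × (number of voxels in the
perpendicular plane). The whole array is the domain: background zeros
outside the brain are legitimate 0-valued data, and no brain-mask cropping
is applied. For a {0,1} field γ is bounded by 0.5, and for an i.i.d.
Bernoulli(p) field E[γ(h)] = p(1−p) at every positive lag — the analytic
anchor used by the tests.

Each directional variogram is condensed by fitting the exponential model

γ(h) = c (1 − exp(−3|h|/a)),

whose range a (mm) is the distance at which the model reaches ~95% of its
sill c. The fit is unweighted nonlinear least squares on the lag-1..max_lag
points only; γ(0) = 0 is not appended as a data point, and pair-count
weighting is deliberately not applied (mirroring a plain `nls` call; a
weighted variant would change the published parameter values).

The three directional parameter pairs are reduced to the pattern coordinates
ā = ln(mean(aₓ, a_y, a_z)) and c̄ = ln(mean(cₓ, c_y, c_z)): the logarithm of
the arithmetic mean. This is deliberately not the mean of the logs — by
Jensen's inequality the two differ whenever the directions disagree, and the
published worked-example values are reproduced only under log-of-mean
semantics (0.62610 vs 0.57461 for the mild phantom's range coordinate).

## Parameters

- **threshold** (default 0.5, unitless): probability maps are binarized by
  strict `>`; values exactly equal to the threshold become background. The
  strict inequality follows the documented behavior of the original tool
  ("values above" the threshold become lesion); whether its `nls`-era
  implementation treated exact ties identically is unrecorded, which only
  matters for probability maps containing the exact threshold value.
- **max_lag** (default "auto"): number of one-voxel-wide distance classes.
  Auto = floor(15 mm / coarsest voxel spacing), clamped to the volume, since
  lag distances beyond ~15 mm carry little lesion-correlation information
  (1.5 mm voxels → 10 lags, 1 mm → 15). Lag distances use the per-axis
  spacing, so anisotropic voxels yield different distance grids per
  direction; this is the geostatistically correct reading when the original
  tool's convention for anisotropic voxels is unstated (its published use
  case is isotropic 1 mm MNB space, where the two conventions coincide).
- **guess_a / guess_c** (default "auto"): starting estimates for the fit.
  Auto uses half the maximum lag distance for a and the mean of the upper
  half of the γ values (the near-plateau region) for c — scale-free choices
  that converge across all synthetic and phantom regimes. The original
  tool's numeric defaults are unpublished, so exact replication tolerances
  must absorb optimizer-start differences.
- **plot size** (default 1200×900 px) and LDP axis spans (ln a ∈ [0, 3],
  ln c ∈ [−12, −4]): the spans are a cohort-derived plotting convention,
  kept as overridable defaults; points outside are drawn with a logged
  warning rather than dropped.

## Numerical choices

- The least-squares surface of the exponential model is flat in a both as
  a → 0 and a → ∞, so a single Levenberg–Marquardt run can stall on a
  plateau (observed on noise-perturbed sills: ~1/3 of draws ended in a
  small-a local minimum with ~30× the residual). The fitter therefore runs
  LM from the user start plus a deterministic ladder of range starts
  (5–100% of the maximum lag distance) and keeps the valid solution with
  the lowest residual sum of squares. Tolerances are tightened to 1e−15 so
  exact model points are recovered to machine precision.
- Positivity of (a, c) is enforced by fitting unconstrained and flagging
  non-positive or non-improving solutions as non-converged, matching the
  behavior of an unconstrained `nls`. Non-converged fits are reported with
  a diagnostic message; the batch pipeline logs and skips the file rather
  than aborting, as does an all-zero mask (degenerate sill) or a file whose
  header is not explicitly 3D (a trailing singleton 4th dimension is
  squeezed with a warning instead).
- The `.var` container dialect is tab-delimited ASCII with one fixed header
  line, 5-decimal numeric fields and ASCII hyphen-minus signs; IDs are
  consecutive in input order. The LDP plots are rendered from the file on
  disk, not from in-memory state, so the plots always reflect what was
  persisted. The pipeline contains no random state and is byte-deterministic
  given its inputs.

## Synthetic data

The `fixtures` module generates the test volumes: i.i.d. Bernoulli fields
(analytic expectations available in closed form) and unions of ellipsoids
with seeded uniform centers — crisp binary blobs whose size, count and
anisotropy are controlled, emulating thresholded lesion masks (e.g.
z-stretched lesions via a larger z semi-axis). Scenes used in tests and in
the acceptance script are 40³–48³ voxels at 1 mm with 4–30 lesions of
1.5–3.5 mm semi-axes, a ladder chosen to span mild-to-severe lesion loads
at volume fractions of roughly 0.1–3%; these boxes are small relative to a
whole 181×217×181 head volume, so their sill coordinates sit higher than
real-cohort values. The generator does not attempt realistic lesion
morphology (confluence, periventricular clustering, surface roughness) or
MRI signal/segmentation noise; passing tests demonstrate correctness of the
variography, fitting and plumbing, and the qualitative monotonicities
(range grows with lesion size, sill with lesion load, directional ranges
track geometric anisotropy) — not clinical validity on real masks. The
module also houses the brute-force triple-loop variogram used purely as an
independent oracle against the shift-based implementation.

## Known limitations

- Replication of the published BrainWeb phantom parameter table requires
  downloading those phantoms; the dedicated test runs the full pipeline on
  `data/brainweb/` volumes when present and fails with instructions when
  not, since the volumes cannot be redistributed here.
- Only axis-aligned directional variograms are computed (no omnidirectional
  or oblique directions, no variogram maps), only the exponential model is
  fitted, and no spatial normalization or segmentation is performed —
  inputs must already be masks or probability maps in template space.
- Exact tie handling at the binarization threshold and the original tool's
  unpublished fit starting values are the two places where bit-level
  agreement with it cannot be guaranteed; both are documented above.
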