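# Methods

This note documents the models, conventions, numerical choices and known
limitations of `vertekin`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`.

## Coordinate and pose conventions

All geometry lives in a lab frame with X anterior, Y left, Z superior
(millimetres). A pose is a proper rigid transform `p ↦ R p + t` with
`det R = +1` enforced to 1e-9 (tiny orthonormality drift is re-projected
via SVD so long compositions stay closed). Angles cross the API in
degrees; internals use radians via `scipy.spatial.transform.Rotation`.

Three frame constructions are used:

* **Bead frame** (3-bead): origin at the first bead, x̂ toward the second,
  ẑ normal to the bead plane, ŷ = ẑ × x̂. Which three beads and the axis
  assignment are conventions, fixed here for determinism; a `least_squares`
  mode instead applies the Kabsch fit over all beads of a level.
* **Anatomic frame**: ŷ along right→left landmarks, x̂ the anterior
  landmark direction orthogonalized against ŷ, ẑ = x̂ × ŷ (always
  right-handed). Degenerate landmark configurations raise instead of
  silently producing a skewed frame.
* **Euler export**: intrinsic Y-X′-Z″ for flexion trials, X-Z′-Y″ for
  lateral bending. At the middle-angle singularity (|middle| within 1e-6
  rad of 90°) the third angle is set to zero and the result flagged; the
  flagged factorization still reproduces the rotation.

## DRR rendering

A volume is a scalar attenuation grid (arbitrary linear units/mm) with
voxel spacing and origin; arrays are indexed `[iz, iy, ix]` (x fastest,
the SimpleITK/NumPy convention). A radiograph pixel is the line integral
of trilinearly interpolated attenuation along the ray from the point
source through the pixel center, evaluated by uniform per-ray sampling
between the ray's entry and exit of the volume box (slab test). The
default step is half the smallest voxel spacing; halving it changes a
smooth phantom's DRR by < 0.5 % relative RMS, so tests use 0.5 mm on the
0.5 mm-voxel phantoms. The intensity model is deliberately a pure line
integral with no Beer–Lambert exponential: NCC is invariant to monotone
linear intensity maps, so the choice cannot affect registration; an
exponential transform exists behind a flag for visual realism.

The biplane rig is parameterized by interbeam angle, SID, and elevation
around a shared isocenter (55°/8° cervical-style, 90° lumbar-style); the
interbeam angle between central rays is exact even with non-zero
elevation (the tilt is folded into the second ray's construction).
Synthetic geometry is calibrated by construction — real-rig calibration
and intensifier distortion are out of scope.

## Registration objective

The similarity for one frame is the mean over the two views of the
Pearson NCC between the rendered DRR and the observed image. Two practical
refinements are enabled by default:

* **Pose-following ROI**: rays are cast only inside the detector window
  covering the projected bounding box of the posed volume (+8 px margin),
  which is both faster and local.
* **Silhouette masking**: the correlation is restricted to pixels the
  rendered bone actually covers. With several bones in the field of view,
  full-image NCC is dominated by the un-modelled neighbours — on our
  phantom a 1.25° misalignment of one vertebra changed full-image NCC by
  only 0.004, and the optimizer drifted onto the neighbouring level.
  Masked NCC restores a sharp, correct optimum (score ≈ 1.0 at truth,
  tracked error ~0.01 mm). Full-image scoring remains available
  (`roi_margin_px=None, silhouette=False`).

Optimization is Nelder–Mead over a 6-vector of offsets relative to the
running pose — 3 translations (mm) and 3 intrinsic rotations (degrees)
about the bone's local axes, so one simplex unit ≈ 1 mm ≈ 1° — re-centered
each frame. Defaults: initial step 1 mm/1°, `xatol` 1e-4, `fatol` 1e-6,
500 iterations, 2 restarts from the incumbent. The restarts matter: from a
(2 mm, 2°) offset a single simplex run can collapse prematurely (~0.4 mm
residual) while one restart recovers the optimum to 1e-4 mm. Tracking
seeds each frame with the previous optimum; frames listed in a
re-initialization map take the supplied pose instead and are flagged, and
a frame whose score drops more than 0.1 below the running median of
previous scores is flagged unconverged — the automated analogue of visual
inspection catching frames that need manual shape-matching.

## RSA chain

Bead detection thresholds at the Otsu level, labels connected components,
takes background-subtracted intensity-weighted centroids (sub-pixel) and
merges components closer than a minimum separation. Correspondence is
established against predicted positions (projected priors or the previous
frame) by linear assignment. Triangulation is the standard two-view DLT
with an exact 3×4 camera matrix derived from the projection geometry
(consistent with the perspective projection to < 1e-9 px); near-parallel
ray pairs (condition number > 1e8) raise. On noise-free synthetic renders
the full loop — render beads → detect → triangulate → pose — recovers a
known motion to ~0.003 mm / 0.02° at a 0.25 mm detector pitch, comfortably
inside the 0.05 mm / 0.1° budget the tests enforce.

The packaged validation block is **synthetic**: six beads forming two
orthogonal 3-bead frames with 12–18 mm spacing, the known offset computed
exactly from the coordinates (the physical block's coordinates are not
published, so its error table is context, not a target). Per frame the
two frames are rebuilt from tracked beads and the error transform
`known⁻¹ ∘ observed` is decomposed into per-axis rotations and
translations; rigid common-mode motion of all six beads cancels exactly.

## Trial statistics

Filtering is `scipy.signal.butter` + `filtfilt` with reflective (`even`)
padding of length 3·order — zero-phase, so the effective magnitude is the
squared single-pass response. The digital design is bilinear-prewarped to
hit −3 dB exactly at the cutoff (the MATLAB convention); at 9 Hz
(fs 60 Hz, cutoff 3 Hz, order 4) the two-pass attenuation is
`1/(1+r⁸)` with `r = tan(π·9/60)/tan(π·3/60) ≈ 3.22`, i.e. ≈ 8.7e-5 —
the same order as, but smaller than, the unwarped analog value 1.5e-4.
A single-pass causal mode exists behind a flag.

The ASTM aggregation uses population (n-denominator) variance inside
precision so that for a single trial `RMSE² = bias² + precision²` holds
exactly, and for any trial mix `RMSE² ≥ bias² + precision²` (Jensen). A
`ddof=1` switch selects the sample-variance convention (which breaks the
identity, and is therefore not checked against it). Rotation differences
are taken on exported Euler components, not on rotation matrices.

Interrater SEM: sessions averaged within rater; SD (ddof = 1) across rater
means per bead and axis; SEM = RMS of those SDs. With persistent per-rater
offsets of SD 0.12 mm the estimator recovers 0.12 ± 0.02 mm.

## Monte Carlo error propagation

Per replicate, every bead coordinate of every level receives an
independent Gaussian perturbation (static model: mean 0, SD 0.12 mm;
dynamic model: mean 0.03 mm, SD 0.21 mm on all axes — rotation-block
values are not meaningfully applicable to point perturbations). Perturbed
3-bead frames are compared with the reference frames; the intersegmental
error of each adjacent pair (cranial level in the caudal level's frame) is
conjugated into the caudal anatomic basis, decomposed into the Y-X′-Z″
angles and per-axis translations, and pooled across both level pairs over
10,000 replicates. Pooled population statistics make
`RMSE² = bias² + precision²` exact per component; a per-level aggregation
mode (average the per-pair moments) exists behind a flag and differs only
in precision by the between-pair mean spread. One seeded generator drives
a run; draws are consumed in a documented (replicate, level, bead, axis)
order, so results are bit-reproducible by seed. Degenerate perturbed
geometries are redrawn, capped at 1 % of replicates (never triggered at
these noise levels).

Two second-order facts are worth knowing. First, the frame construction
is nonlinear (unit vectors, cross products), so zero-mean bead noise
leaves a small genuine bias of order σ² — about 0.009 mm on the
superior-inferior axis at σ = 0.12 mm — which shrinks quadratically with
σ; tests assert biases round to ≤ 0.01 at two decimals rather than
pretending exact unbiasedness. Second, precision scales linearly with σ
(doubling 0.12 → 0.24 mm doubles every component to within 2 %), and
rotational precision shrinks as bead spacing grows (lever-arm effect);
with the packaged ML-elongated layout the flexion/extension axis is the
least precise rotation, as expected for beads placed along that axis.

The packaged cervical geometry (three levels, four anterior beads each,
10–15 mm spacing mainly along ML) is a synthetic stand-in for unpublished
cadaver bead coordinates; near-zero biases are geometry-robust, absolute
precision/RMSE magnitudes are specific to this geometry.

## Synthetic phantom and motion

The phantom is geometric, not anatomical: per level an ellipsoidal
vertebral body with a cortical shell, a dense posterior-element box, an
off-axis knob (so axial rotation is identifiable), smoothed trabecular
texture, and four anti-aliased bead spheres. Adjacent levels are made
morphologically distinct (body axes, posterior extent, knob azimuth vary
with level) because identical twin levels allowed the tracker to lock
onto a neighbour — real vertebrae are never identical. The fidelity
target is "enough structure for NCC to have a sharp optimum", verified by
the loop-closure tests, not radiographic realism: no scatter, beam
hardening, soft tissue, or intensifier distortion.

Motion scripts use a cubic smoothstep from 0 to the range of motion
(default 25° over 3 s at 60 Hz, matching reported trial scale), the caudal
level fixed and motion distributed linearly up the column; each level
rotates about a posterior pivot so rotation carries a consistent small
translation arc. Peak angular velocity is `1.5·rom/duration` (12.5°/s at
defaults). Tests run 5–10-frame excerpts of this motion for speed; the
full 3 s trial is a parameter, not a different code path.

Trial images are sums of per-level DRRs (line integrals are additive)
plus optional Gaussian pixel noise. The loop-closure tests track against
the bead-consistent (unmasked) level volume: with noise-free images a
bead-masked CT's *only* NCC mismatch is the bead spots themselves, which
then dominate the objective and pull the optimum off by 1–2° — an
artifact of perfectly clean synthetic images, not of the masking step
(real radiographs are noisy and soft-tissue-laden, so bone structure
dominates). Bead masking itself (replace voxels within a radius of each
centroid by the median of the surrounding shell) is verified separately.

## Problem sizes

Default test scale: 64³–96³ volumes at 0.5 mm voxels, 80–100 px detectors
at 1 mm pitch (0.25 mm pitch for the RSA sub-pixel chain), 5–10-frame
trials, 10,000 Monte Carlo replicates. These sizes were chosen so the
whole suite exercises every pipeline at full numerical fidelity while a
complete run stays comfortably interactive.

## Known limitations

* Single-bone optimization only; bones are tracked independently.
* No GPU rendering; the ray caster is vectorized NumPy.
* The dynamic bead-error model treats the validation-block translation
  bias/precision as an isotropic per-coordinate Gaussian; correlated or
  non-Gaussian tracking errors are out of scope.
* Synthetic geometry is calibrated and distortion-free by construction;
  nothing here validates a physical calibration.
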