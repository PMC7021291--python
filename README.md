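# vertekin

Validation toolkit for biplane videoradiography of the spine: automated
2D/3D shape-matching of vertebrae onto biplane radiographs, bead-based
radiostereometric analysis (RSA), ASTM-style method-comparison statistics,
and Monte Carlo propagation of bead-digitization error into 6-DOF
kinematic error — all runnable end to end on synthetic phantoms.

## Who this is for

Biomechanics labs that track individual vertebrae (e.g. C4–C6, L3–L4)
during dynamic flexion or lateral bending with a calibrated two-view X-ray
rig. Two measurement chains are implemented and compared:

* **Shape-matching**: a digitally reconstructed radiograph (DRR) of the
  bone's CT volume is rendered at a candidate pose by ray casting and
  scored against both radiographs with normalized cross-correlation (NCC);
  Nelder–Mead simplex optimization over the 6-DOF pose maximizes the mean
  of the two per-view scores, frame after frame, from a single manually
  placed initial pose.
* **RSA**: implanted 1.6 mm tantalum beads are detected in both views,
  triangulated to 3D, and a bead-based coordinate system per vertebra
  gives the reference kinematics.

Agreement between the chains is summarized per motion component with the
ASTM convention, every trial weighted by its frame count
(`w_t = n_t / Σn`):

    bias      = Σ w_t · mean(d_t)
    precision = sqrt( Σ w_t · var(d_t) )
    RMSE      = sqrt( Σ w_t · mean(d_t²) )

Rotations are exported as intrinsic Euler sequences — Y-X′-Z″ for flexion
and X-Z′-Y″ for lateral bending — and filtered with a zero-phase 4th-order
Butterworth low-pass at 3 Hz (60 Hz sampling).

Because RSA itself is imperfect, two Monte Carlo simulations propagate its
bead-level error into kinematics: a **static** model (bead-centroid
identification on CT; zero-mean Gaussian, SD = 0.12 mm, the interrater
SEM) and a **dynamic** model (radiographic bead tracking; Gaussian with
mean 0.03 mm and SD 0.21 mm, the validation-block bias and precision).
Each of 10,000 replicates perturbs every bead coordinate, rebuilds the
vertebral frames, and expresses the intersegmental frame error in the
anatomic coordinate system (X anterior, Y left, Z superior).

## Worked example

```python
from vertekin import RsaErrorSimulation, static_error_model, dynamic_error_model, mc_report

static = RsaErrorSimulation(static_error_model()).run(seed=1)    # SD 0.12 mm
dynamic = RsaErrorSimulation(dynamic_error_model()).run(seed=2)  # 0.03 ± 0.21 mm
print(static.summary())
```

which prints

```
RSA error Monte Carlo (static model, 10000 replicates, mean 0 mm, SD 0.12 mm)
           LB(X)  FE(Y)  AR(Z)  AP(X)  ML(Y)  SI(Z)
Bias        0.01  -0.01   0.01   -0.0   0.00  -0.01
Precision   1.14   2.80   1.14    0.5   0.28   0.17
RMSE        1.14   2.80   1.14    0.5   0.28   0.18
```

Rows are the ASTM statistics; columns are lateral bending, flexion/
extension and axial rotation (degrees), then anterior-posterior,
medial-lateral and superior-inferior translation (mm), pooled over the
two adjacent level pairs of the packaged three-level cervical geometry.
The biases are statistically indistinguishable from zero — zero-mean bead
noise leaves no systematic kinematic error, so precision and RMSE
coincide — while flexion/extension rotation is the least precise
component: the packaged beads are spread mainly along the medial-lateral
axis (an anterior surgical approach), giving that rotation axis the
shortest lever arms. `mc_report([static, dynamic])` assembles both blocks
into one grid.

Tracking a synthetic trial end to end:

```python
from vertekin import (ShapeMatcher, OptimizerSettings, RigidTransform,
                      make_phantom, make_motion, render_trial, make_biplane_geometry)

phantom = make_phantom(seed=0)                       # 3 levels, 4 beads each
geoms = make_biplane_geometry(55.0, 1520.0, 8.0,     # 55° interbeam, 8° elevation
                              pixel_pitch=1.0, image_size=(100, 100))
script = make_motion("flexion", rom_deg=25.0, duration_s=10/60)
frames = render_trial(phantom, script, geoms)
model = ShapeMatcher(phantom.level_volumes[0], geoms, frames,
                     settings=OptimizerSettings(xatol=1e-3), step_mm=0.5)
result = model.fit(RigidTransform.identity())
print(result.summary())
```

```
Shape-matching trial (flexion, 10 frames @ 60 Hz)
  NCC score: min 1.0000  median 1.0000  max 1.0000
  converged: 10/10  reinitialized: 0
```

On this noise-free trial the tracked poses agree with the scripted ground
truth to ~0.01 mm / 0.04° per frame. A `vertekin` command-line interface
(`synth`, `track`, `rsa`, `compare`, `mc`, `block`, `report`) wraps the
same library for shell pipelines; see `vertekin --help`.

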