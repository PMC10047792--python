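# eitshape

Implicit neural shape reconstruction for 2D electrical impedance
tomography (EIT), with a finite-element forward solver, a
monotonicity-test baseline, and Gauss-Newton conductivity
reconstruction guided by the predicted shapes.

## The problem

EIT reconstructs the conductivity σ inside a body Ω from
current/voltage measurements on boundary electrodes.  The forward
model is the elliptic PDE

    ∇·(σ∇u) = 0  in Ω,    σ ∂u/∂ν = g  on ∂Ω,    ∫_∂Ω u = 0,

with 0 < σ₁ ≤ σ ≤ σ₂ < ∞.  The inverse problem is severely ill posed.
This package targets the *shape* variant: the background conductivity
is known (σ = 1) and the goal is to decide, for any point p ∈ Ω,
whether p lies in the homogeneous background or inside an anomaly.

Experiments live on the unit disk with L = 16 point electrodes at
angles 2πk/L.  Currents are injected through adjacent source–sink
pairs; for each of the 16 injections the voltage difference across
every adjacent electrode pair not touching the drive pair is recorded:
13 values per injection, 208 in total (L·(L−3) in general).

## The classifier

A point is classified by three small fully connected residual
networks:

* **measure encoder** — maps the 208 normalised measurements m to an
  embedding me ∈ R^(64·scale) (six residual blocks,
  208 → 128s → 128s → 128s → 64s → 64s → 64s);
* **point encoder** — maps a normalised point p ∈ R^d (d = 2 or 3) to
  an embedding pe of the same size (two blocks, d → 32s → 64s);
* **decoder** — maps the sum pe + me through two blocks
  (64s → 32s → 2) and a softmax to (q_background, q_anomaly); the
  point is called background iff q_background > q_anomaly.

Each residual block is Linear → LeakyReLU(0.01) → Linear plus a
shortcut (identity, or a single linear map when sizes differ), with a
final LeakyReLU.  Because the network answers queries at *continuous*
coordinates, one trained model can be evaluated at the centroids of an
arbitrarily fine mesh ("super-resolution") without retraining, and the
measurement embedding is computed once per experiment no matter how
many points are queried.

Training data are simulated: phantoms with 1–4 random circular
inclusions on background 1, their clean 208-entry measurement vectors,
balanced point clouds (equal numbers of background and anomaly
points), and fresh Gaussian measurement noise with standard deviation
max(|m|)·δ/100 at noise level δ% in every epoch.  The loss is binary
cross-entropy; the optimizer is Adam at 5e-4, with the moments reset
and the learning rate multiplied by 2/3 every ten epochs.

Two classical methods are implemented for comparison:

* **monotonicity ball test** — σ₁ ≤ σ₂ implies Λ(σ₁) ≥ Λ(σ₂) for the
  Neumann-to-Dirichlet operator Λ; a small test ball is flagged as
  inside the anomaly iff the corresponding NtD difference is positive
  semi-definite.  Sharp at zero noise, but already at δ = 1% the PSD
  test fails everywhere.
* **IRGN** — iteratively regularized Gauss-Newton least squares with
  a Tikhonov penalty, in three modes: *standard* (every triangle),
  *constrained* (only triangles the classifier flags), and *piecewise*
  (one scalar per connected flagged component).

## Worked example

```python
import numpy as np
from eitshape import (
    DomainSpec, build_disk_mesh, make_fixtures, rasterize, measure,
    label_points, triangle_centroids, irgn_constrained, irgn_standard,
)

mesh = build_disk_mesh(DomainSpec(), h=0.08)      # ~900 triangles
phantom = make_fixtures()["one_inclusion"]        # sigma=2 disk, r=0.3, at (0.4, 0)
truth = rasterize(phantom, mesh)
m = measure(truth)                                # 208 voltage differences
print(len(m))                                     # 208

mask = label_points(phantom, triangle_centroids(mesh)).astype(bool)
standard = irgn_standard(m, mesh, truth=truth)
constrained = irgn_constrained(m, mesh, mask, truth=truth)
print(round(standard.l2_error_vs_truth, 3))       # 0.211
print(round(constrained.l2_error_vs_truth, 3))    # 0.027
print(round(constrained.sigma[mask].mean(), 3))   # 1.997
```

The constrained reconstruction, told *where* the anomaly is, recovers
its conductivity (true value 2) to a fraction of a percent and cuts
the area-weighted L2 error by an order of magnitude relative to the
unconstrained Gauss-Newton fit — the quantitative reason to feed the
classifier's shape prediction into the reconstruction.

Training a classifier (desk scale; see `docs/methods.md` for sizes):

```python
from eitshape import DatasetConfig, ImplicitClassifier, NetworkConfig, TrainConfig, build_dataset
cfg = DatasetConfig.small(master_seed=11)            # 2,000 train / 200 val phantoms
train = build_dataset(cfg, mesh, "train")
val = build_dataset(cfg, mesh, "val")
results = ImplicitClassifier(train, val, NetworkConfig(scale=2),
                             per_channel_normalization=True).fit(
    TrainConfig(epochs=700, batch_size=64, points_per_sample=32, initial_lr=1e-3,
                master_seed=7, lr_decay_every=160, val_interval=50))
print(results.summary())                             # best val accuracy 0.8806
```

At this desk scale the classifier reaches ≈0.88 validation accuracy at
zero noise (evaluated at the triangle centroids of the mesh), decreasing
weakly monotonically as validation noise grows to 5% — the full-scale
recipe (16,384 phantoms, ~2.5·10⁵ optimizer steps) is what pushes this
into the high nineties.

A command-line interface mirrors the pipeline
(`eitshape generate-data / train / evaluate / super-res /
baseline-monotonicity / irgn / fixtures`).

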