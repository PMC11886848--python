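# ctrldiff

Controlled SE(3)-equivariant diffusion for small-molecule generation.
`ctrldiff` jointly generates the **3D coordinates, atom types, formal
charges and bond orders** of small organic molecules (H/C/N/O/F by
default), and adds ControlNet-style conditioning on a reference structure
through zero-initialized layers.  It also ships the standard molecular
generation benchmark suite: validity, connectivity, novelty, uniqueness,
and Wasserstein distances of valency, bond-length and bond-angle
distributions.

It is aimed at researchers in generative chemistry who want a compact,
fully inspectable implementation of joint discrete/continuous molecular
diffusion — every component, including the automatic differentiation, is
plain numpy and small enough to read in an afternoon.

## The model

A molecule is a labelled 3D graph G = (R, X, C, Y): coordinates R ∈ ℝ^{n×3}
(Å, kept in the zero centre-of-mass subspace), atom types X, formal
charges C, and a symmetric bond-order matrix Y.  The forward corruption
process factorizes per modality:

    q(G_t | G_{t-1}) = N_CoM(α_t R_{t-1}, σ_t² I)
                       · C(X_{t-1} Q_x,t) · C(C_{t-1} Q_c,t) · C(Y_{t-1} Q_y,t)

Coordinates receive variance-preserving Gaussian noise confined to the
CoM-free subspace (dimension 3(n−1)); each discrete channel is corrupted
by a marginal-mixing kernel Q(α) = αI + (1−α)𝟙mᵀ, where m is the
dataset marginal of that channel.  Each modality follows its own
power-cosine schedule

    ᾱ(t) = cos²( (π/2) · ((t/T + s)/(1 + s))^ν )

with a per-modality exponent ν, so discrete channels can be corrupted at
a different rate than coordinates (ν = 1 recovers the plain cosine
schedule).

The denoiser is a graph transformer whose scalar path (attention,
feed-forward, layer norm on nodes and edges) consumes only rotation
invariants, while coordinates are moved exclusively by three equivariant
primitives: a relaxed-EGNN update (atoms move along difference vectors
with invariant scalar weights), a radial position MLP, and an E(3)
norm-rescaling layer, with CoM re-projection after every update.  The
predicted categorical distributions are therefore exactly SE(3)
invariant and the predicted clean coordinates exactly equivariant.

Sampling runs the Bayes posterior of each channel backwards from a
rotation-invariant prior (CoM-free Gaussian coordinates, marginal
categories).  Conditioning follows the ControlNet recipe:

    y_c = F(x; θ) + Z( F(x + Z(c; θ_z1); θ_c); θ_z2 )

with the base parameters θ frozen, a trainable copy θ_c, and zero
initialized layers Z so the conditioned model is bit-identical to the
unconditional one at construction.

## Worked example

Train a small model on the built-in fixture set (five common small
molecules plus five linear alkanes), sample from it, and score the
samples against the training set:

```python
import ctrldiff as cd

mols = cd.generate_fixtures("minimal") + cd.generate_fixtures("chains", k=5)
model = cd.MoleculeDiffusion(mols, schedule=cd.NoiseParams(T=100),
                             arch=cd.LayerConfig(width=64, n_layers=2, n_heads=4))
results = model.fit(steps=2000, seed=0)
print(results.summary())

generated = results.sample(20, seed=1)
print(results.evaluate(generated).to_json())
```

Output:

```
Controlled equivariant molecule diffusion
=============================================
training molecules      10
parameters              104531
layers / width / heads  2 / 64 / 4
diffusion steps T       100
schedule exponents      nu_r=1.0 nu_x=1.5 nu_c=1.5 nu_y=1.5
optimizer steps         2000
loss (smoothed) start   2.8900
loss (smoothed) final   1.4099
control branch          none

{
  "schema": 1,
  "validity_pct": 40.0,
  "connected_pct": 5.0,
  "novelty_pct": 100.0,
  "uniqueness_pct": 87.5,
  "valency_dist": 0.7327935222672062,
  "bondlen_dist": 0.488017322250919,
  "angle_dist": 38.105677079030784,
  "n_evaluated": 20,
  "n_valid": 8,
  "toolkit": "rdkit 2024.09.2"
}
```

The summary reports the smoothed training loss halving over the run; the
metric report shows what a two-minute CPU model learns: 40 % of the 20
samples already sanitize as valid molecules and none reproduce a
training compound, but connectivity and geometry are still far from the
training distribution — competitive sample quality needs orders of
magnitude more data and training, not a different pipeline.  To
condition generation on a lead compound, attach the control branch
(`results.add_control()`) and pass `condition=<reference molecule>` to
`sample()`; at initialization this reproduces unconditional sampling
exactly.

The same pipeline is scriptable from the shell:

```bash
ctrldiff fixtures --set minimal --out train.sdf
ctrldiff preprocess --in train.sdf --out kept.sdf --report report.json
ctrldiff split --n 1000 --ratios 0.7,0.2,0.1 --seed 0
ctrldiff train --config run.yaml
ctrldiff generate --checkpoint ckpt.npz --dataset kept.sdf --n 100 --out gen.sdf
ctrldiff evaluate --generated gen.sdf --reference kept.sdf --out metrics.json
```

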