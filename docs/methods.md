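# Methods

This note records the model, its assumptions, the parameters that matter,
and the design decisions taken where the design was genuinely open.  It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Data model and units

A molecule is a fully labelled 3D graph: per-atom element type over a
fixed vocabulary (default {H, C, N, O, F}), per-atom formal charge over
{−1, 0, +1}, a symmetric bond-order matrix over {none, single, double,
triple, aromatic} with a "none" diagonal, and coordinates in ångström.
Hydrogens are explicit everywhere and no implicit-valence filling is ever
performed: when a generated graph is judged for validity, the sanitizer
sees exactly the generated atoms, charges and bonds.  The charge channel
is retained even though small-organics benchmarks are almost entirely
neutral, because the corruption process treats charges as a first-class
categorical channel; its marginal simply concentrates on 0.

The fixture generator produces idealized-geometry molecules (methane,
water, ammonia, ethane, ethene; linear alkanes; a pentavalent-carbon
negative control; a two-fragment disconnection control) so every metric
has constructed ground truth.  These fixtures emulate the statistics of a
benchmark set of small organics — element composition, explicit
hydrogens, realistic bond lengths and angles — but not its diversity:
ten molecules cannot represent 10⁵ heteroatom-rich structures, so
passing tests demonstrate correctness of the machinery, not
generation quality on real data.  Dataset preprocessing implements the
two published filter criteria generically: a sanitizer parseability check
and an encode→decode→re-encode identity check on the canonical string
encoding (the original pipeline names an InChI-based consistency check
without specifying its algorithm; the canonical-SMILES round-trip is the
same contract expressed with one toolkit).  Published removal counts are
toolkit-version dependent and are reported, not promised.

Splitting floors the validation and test fractions and assigns the
remainder to train, after a seeded shuffle — deterministic and exact on
round sample sizes (70/20/10 on 1000 records gives 700/200/100).

## Corruption process

Coordinates: variance-preserving Gaussian diffusion restricted to the
zero centre-of-mass subspace (dimension 3(n−1)); the projection is what
makes translations unambiguous and the prior rotation-invariant.  The
per-coordinate marginal variance of the projected noise is σ²(1 − 1/n),
which the tests verify by Monte Carlo.

Discrete channels: marginal-mixing kernels Q(α) = αI + (1−α)𝟙mᵀ.  This
family is closed under composition (Q(a)Q(b) = Q(ab)), so the t-step
kernel is available in closed form and the reverse-step Bayes posterior
q(x_{t−1}|x_t, x_0) ∝ Q_t[x_{t−1}, x_t]·Q̄_{t−1}[x_0, x_{t−1}] is cheap;
the network prediction of x_0 is marginalized over exactly.  Charges are
noised independently of atom types (separate kernel), matching the
product form of the joint corruption.  Bond noise is sampled on the upper
triangle only and mirrored; the diagonal stays "none".

Schedule: ᾱ(t) = cos²((π/2)·((t/T+s)/(1+s))^ν) per modality.  Defaults
T = 500 (desk-scale runs use T = 20–100), s = 0.008, ν_r = 1 for
coordinates and ν = 1.5 for the three discrete channels, which corrupts
the discrete structure more slowly early in the chain — the motivation
for a per-modality exponent is that a single schedule lets one data type
be destroyed much faster than the other.  ᾱ is clamped to
[10⁻⁵, 1−10⁻⁵] away from the endpoints to keep posteriors
non-degenerate; the categorical channels take ᾱ_T = 0 exactly so the
t = T prior is exactly the marginal.  The raw schedule value at t = T is
0 for every ν (the cosine argument reaches π/2 exactly).

All randomness fans out from one integer seed through a counter-based
seed sequence, so modality draws are independent and every run is
reproducible.

## Denoising network

A graph transformer over node features (atom type ⊕ charge one-hots ⊕ an
8-dimensional sinusoidal embedding of t/T — the conditioning mechanism
for the timestep is our choice, as is everything about layer sizes) and
edge features (bond one-hot ⊕ squared distance).  Scalar features flow
through multi-head attention with an edge-derived additive bias,
per-node and per-edge feed-forward blocks, and layer normalization
(batch statistics would break permutation/rotation symmetry; coordinates
get their own norm layer instead).

Coordinates are updated only by equivariant primitives, with CoM
re-projection after every update:

* relaxed-EGNN: Δr_ij = (‖r_i−r_j‖², ‖r_i‖², ‖r_j‖², cos(r_i, r_j));
  r_i ← r_i + (1/(n−1)) Σ_j φ(h_i, h_j, Δr_ij, e_ij)(r_j − r_i) with a
  tanh-bounded scalar message φ.  The ‖r_i‖² and cosine features are only
  well defined because all coordinates live in the CoM-zero frame.  The
  normalized (mean) aggregation is an implementation choice over the raw
  sum: it bounds the per-layer coordinate displacement so stacked layers
  cannot amplify the coordinate scale geometrically — with the raw sum a
  two-layer untrained network already produced coordinate magnitudes two
  orders above the data scale.  The standalone `regnn_update` operation
  retains the pure-sum form.
* radial MLP: r_i ← Π_CoM(mlp(‖r_i‖)·r_i/(‖r_i‖ + ∂)); the learnable map
  sees only norms.  The ∂ guard sits in the denominator (the published
  form is typographically ambiguous between guarding the norm and
  post-division addition; the denominator guard is the numerically safe
  reading).
* E(3) norm: R ← γ·R/(n̄ + ∂) with n̄ the mean coordinate norm and a
  learnable scalar gain γ per layer.

The cosine feature is guarded by adding 10⁻⁸ to each norm in the
denominator, which degrades smoothly to 0 as either atom approaches the
origin.  In the layer, the rEGNN move and the radial update share one
residual, so zeroing their output weights passes coordinates through
unchanged — a property the tests pin down.  The clean-coordinate head is
the final (projected) coordinate state; type/charge heads are linear maps
on node features, the bond head a linear map on symmetrized edge features
evaluated on i < j only, so the bond distribution is symmetric by
construction.

Because every learnable map consumes invariants and coordinates move
along difference vectors and radial directions, the categorical outputs
are exactly SE(3)-invariant and the coordinate output exactly
equivariant; the test suite measures both to machine precision, far
inside the contractual 10⁻⁴/10⁻⁶ bands.

Default desk-scale architecture: width 64, 2 layers, 4 heads, edge width
32, ∂ = 1.  The parameter count is a pure function of the architecture
and vocabulary sizes, asserted against an independent tally.

The network and training loop run on a small reverse-mode automatic
differentiation engine over float64 numpy arrays written for this
package (`ctrldiff/_autograd.py`); its gradients are verified against
central finite differences.  At these model sizes (≈10⁵ parameters,
molecules of ≤ a few dozen atoms) a training step costs ≈10 ms on one
CPU core, which is entirely adequate for the package's scope.

## Conditioning

The conditioned model is y_c = F(x; θ) + Z(F(x + Z(c; θ_z1); θ_c); θ_z2)
with θ frozen, θ_c a full trainable copy of the base stack (the base
here is a flat transformer, so there is no UNet half to split), and both
Z layers zero-initialized.  The condition c — the published workflow
names a lead compound as the only conditioning datum — is a reference 3D
molecular graph embedded with the frozen input embedding and centred;
atom-count mismatches are handled by zero-padding with a mask (or
truncation with re-centring).  The first zero layer feeds the condition
into the control branch's node features and, through a zero-initialized
scalar gate, its coordinates; the second zero layer combines the control
branch's outputs with the base outputs per head — in logit space for the
distribution heads (then softmax, so the combination always yields valid
distributions) and through a scalar gate for coordinates (the only
linear map on vectors commuting with rotations, preserving
equivariance).

Consequences, all pinned by tests: at construction the conditioned
output is bit-identical to the frozen model for any condition; the
frozen parameters never change during training; at the very first
optimization step θ_z2 receives gradient while θ_z1's gradient is
blocked by the still-zero θ_z2 — the standard zero-convolution
warm-start behaviour.  Conditioning strength is not annealed over
timesteps; it emerges from training the zero layers.

## Training and sampling

Loss: λ_r·MSE(r̂_0, R_0) + λ_x·CE + λ_c·CE + λ_y·CE (bonds on i < j),
defaults λ = (1, 1, 1, 2) — the doubled bond weight reflects that edges
dominate molecular identity.  Timesteps are drawn uniformly on {1..T}
per example.  Optimizer: Adam at 10⁻³ with global gradient-norm clipping
at 1 (the original work states no optimizer, batch size, epoch count or
T; all are config defaults).  Runs abort on non-finite loss with a
diagnostic and log a JSON-lines trace.

Sampling starts at the invariant prior and walks the per-channel
posteriors down to t = 0; the final step takes the categorical argmax
and the coordinate posterior mean, making the last decision
deterministic.  Atom counts at generation follow the empirical training
histogram.  The sampler accepts any `predict(state, t)` callable, which
is how the tests drive it with a plug-in oracle that always predicts a
fixed molecule: the sampler must then reproduce that molecule's discrete
channels essentially always, and its coordinates to the final-step noise
floor.

## Numerical choices and degenerate inputs

* ᾱ clamp 10⁻⁵ (above); posterior normalizations guard against 0/0 with
  10⁻³⁰⁰ floors that never bind for clamped schedules.
* Norm computations add 10⁻¹² inside square roots so autodiff gradients
  stay finite at the origin.
* Single-atom molecules: the CoM-free subspace is trivial (all-zero
  coordinates), the bond channel is empty, and the network and sampler
  handle both.
* Softmax/log-softmax subtract a detached maximum for stability.
* SDF coordinates carry 4 decimal places; round-trip tests use that
  tolerance, while XYZ round-trips hold to 10⁻⁶ Å.

## Evaluation suite

Validity: the complete generated graph must sanitize unmodified — no
largest-fragment extraction, no bond re-perception, no post-processing.
Connectivity: a single component covering all atoms.  Novelty and
uniqueness use canonical SMILES of the sanitized graph as the canonical
key; unsanitizable molecules receive a sentinel key and are excluded
from both numerator and denominator.  Denominators: validity and
connectivity over all generated molecules, novelty and uniqueness over
the valid subset (the benchmark protocol this suite follows restricts
diversity metrics to valid compounds); both counts appear in the JSON
report.  Valency sums bond orders with aromatic = 1.5.  The three
distance metrics are first Wasserstein distances — per-atom-type valency
distributions weighted by generated atom-type frequency, per-bond-type
length samples (Å) weighted by generated bond-type frequency, and pooled
bond angles (degrees) over all bonded triples at each central atom.  The
continuous W1 uses the quantile formula, the discrete one the CDF
formula on a numeric support; both are cross-checked in the tests
against a brute-force optimal-transport linear program.  Published
benchmark tables for these three distances carry unstated units; this
package reports raw W1 values in the units above and makes no claim of
matching any particular published scaling.

## Known limitations

* Desk-scale only: no GPU path, no EMA, no mixed precision, no
  distributed training.  Reproducing benchmark-scale sample quality
  (~10⁵ training molecules) is out of scope.
* The fixture generator covers a tiny, hand-constructed slice of
  chemical space; metrics on it validate bookkeeping, not chemistry.
* Conditioning has a single mechanism (reference-structure injection
  through zero layers); no protein-pocket featurization.
* No learned or continuous-time (SDE) noise schedules.
* The equivariance group is SE(3) (rotations + translations);
  reflections are not quotiented out, and no spherical-harmonic feature
  machinery is included — coordinates move only through scalar-gated
  vector updates.
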