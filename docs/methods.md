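# Methods

This note documents the models, the synthetic data, the numerical choices
and the design decisions behind `browaug`, and what the tests do and do not
demonstrate.

## Translocation physics

DNA translocation through a solid-state nanopore is modeled in one
dimension by the Langevin equation

    m dv/dt + α v − F = A(t),      F = V_b · λ,

where `m` is the effective mass of the molecule, `α` the drag coefficient,
`F` the electric driving force (bias voltage times DNA charge density) and
`A(t)` the stochastic thermal force. The refined, unraveling-chain form
replaces `m` and `α` by functions `m(t)`, `α(t)` of the translocated
fraction, reflecting that only the chain segment before the pivot point
moves.

**Integrator.** Explicit Euler–Maruyama:
`v[k+1] = v[k] + (dt/m)(F − α v[k] + A_k)` with `A_k ~ N(0, σ_A)` i.i.d.
per step; `σ_A` (`thermal_intensity`) is the standard deviation of the
*discretized* thermal force per step, so no additional `√dt` scaling is
applied. At `mass = 0` the overdamped closed form `v[k] = (F + A_k)/α` is
used. Positions are cumulative sums of `v·dt` from 0, so the integration
identity `positions[k+1] − positions[k] = velocities[k+1]·dt` holds
exactly. In the overdamped noiseless limit the velocity is `F/α` at every
step and a constant-drag translocation of a chain of length `ℓ` takes
`ℓα/F` time to within one `dt`; both are tested exactly.

**Units.** The simulator is dimensionless: the source model does not fix
units or magnitudes for `m, α, λ, V_b`, and only the qualitative statistics
matter for the augmentation — overdamped velocity fluctuations are white
(lag-1 autocorrelation ≈ 0 across replicates) and the position variance
grows linearly in step index (Brownian scaling), both verified by Monte
Carlo.

**Unraveling schedule.** The published chain-segment calculation of
`α(t)` lives in the polymer-physics literature and is not reproduced here;
`UnravelingSchedule.affine_drag` is an explicit stand-in, affine in the
translocated fraction and configurable, flagged as such. Any positive
callable pair can be supplied. The schedule is validated (drag > 0,
mass ≥ 0 on a probe grid of [0, 1]) before integration; integration stops
at the chain length or a step cap.

## Brownian-motion augmentation

The walk `i0[0] = 0`, `i0[n] = i0[n−1] + Z[n]`, `Z[n] ~ N(1, σ)` models the
virtual instantaneous position of the DNA; its pre-clamp moments are
`E[i0[n]] = n` and `Var[i0[n]] = nσ²`. Negative entries are replaced by 0.
Entries above `L−1` are clamped to `L−1`: real traces are zero-padded at the
tail, so the clamp holds the padding value, which is how a fixed-length
output coexists with event lengths that genuinely vary under the walk.
`i0[0] = 0` is chosen so that σ = 0 yields the exact identity rather than a
one-sample shift. Interpolation is linear only (deliberately — the index
variation is small and the scheme vectorizes); every output sample is a
convex combination of its two bracketing input samples, which is tested
pointwise against a brute-force loop. `Z` is Gaussian as an explicit
modeling simplification; the draw is isolated in `draw_indexes` so other
distributions can be substituted.

**Equivalent uniform stretch.** The control condition replaces the walk
with a global stretch whose factor std equals the empirical standard
deviation of the walk's relative event-length change
`i0[E−1]/(E−1)` over many draws (closed form `σ/√(E−1)`; the estimator
computes it by Monte Carlo from actual walk endpoints, not from the
formula). The equivalent stretch is derived at the *event* length, not the
padded trace length — the length variation that matters is that of the
event. When the control is layered on a recipe that already stretches, the
stds combine in quadrature (independent multiplicative stretches compose,
and their relative-length variances add to first order).

**Batch driver.** Per-trace order: stretch → Brownian → magnitude →
baseline → noise. The order is a package choice (it is not fixed by the
protocol); additive measurement noise goes last so it is not warped.
Classic-augmentation defaults (stretch 0.1, noise 0.05, magnitude 0.08,
baseline 0.05) are exposed configuration: the original training recipe
keeps its exact magnitudes in its training code rather than in print, so
these are documented placeholders. Stretch factors are clipped below at
0.05 to stay positive. All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning: one independent substream per trace,
so batches are reproducible per epoch seed and fresh across epochs.

## Synthetic barcode traces

The generator emulates the structure of real 3-bit DNA-barcode events:
baseline 0; a negative-going event drop of depth `base_drop` (1.0 —
traces are generated already normalized, the unfolded-DNA level being the
unit); two flanking indicator dips; three equal bit slots between them with
a dip present iff the bit is 1; with probability `fold_prob` a contiguous
sub-segment additively deepened by `base_drop` (a folded strand doubles the
blockade); with probability `reverse_prob` the event time-reversed; i.i.d.
Gaussian measurement noise over the whole trace. Events sit at the head of
the length-`L` array (onset jitter ≤ 20 samples) with the tail
zero-padded, as in the real padded dataset. Labels are defined on the
forward read and are *not* changed by reversal: orientation invariance is
part of the classification task. A rule-based dip counter (`decode_bits`,
run-length scan below `−(base_drop + dip_depth/2)`, nearest-slot
assignment) recovers the bit pattern of every clean noiseless trace in both
orientations; this label↔morphology bijection is tested 16/16.

Datasets draw per-experiment systematic offsets — dip depth, noise level
and event length each scaled by `1 + jitter·N(0,1)` (clipped to stay
physical) and shared by all traces of an experiment — so experiment
identity is statistically detectable, emulating the pore-to-pore confound
the split protocol guards against. `jitter = 0.08` is the default study
condition: large enough that a classifier can exploit experiment identity,
small enough that barcodes remain decodable. Traces are assigned to
experiments round-robin within each class (seeded order) so per-label
experiment shares are near-equal and feasible held-out splits always exist
at desk scale.

**What the generator does not emulate:** pore capacitance/access-resistance
filtering of the current (explicitly out of scope), contamination and
incomplete-fragment events (the generator produces clean events directly),
correlated (non-Gaussian, non-white) measurement noise, and real
morphological diversity of folds. Passing tests therefore demonstrate the
correctness of the machinery and the internal consistency of the
comparison design on idealized data — not classifier accuracy on real
nanopore reads.

## Dataset protocol

For each label, all experiment subsets (up to 3 experiments — a cap that
bounds the combinatorics; the enumeration is otherwise exhaustive) whose
share of that label's traces lies within the test-fraction bounds
(default 4–15 %) are enumerated, and one is selected uniformly at random —
ties among feasible combinations are unweighted. The per-label draws are
*coupled* through a single shared uniform variate: each label's marginal
selection is uniform over its own feasible list (which is what the
protocol specifies and what the uniformity test checks), while labels with
identical feasible lists select the same experiments. The coupling keeps
the union of test experiments small. Traces of a selected experiment whose
own label did not select it are excluded from the dataset entirely —
keeping them in training would place that experiment on both sides of the
split; the count is recorded in the `constraint_report`, never silent.
Validation carving is per-label stratified (a label with fewer than
`1/frac` traces warns and contributes at least one trace); oversampling
duplicates minority-class indices uniformly with replacement up to the
majority count, retaining all originals. Indices are 0-based, ranges
half-open. Padding defaults to value 0 (the normalized baseline);
truncation of over-length traces is opt-in, never silent.

## Classifier family

The family is specified declaratively (`ArchitectureSpec`): a stem
convolution, an optional soft attention mask, a sequence of residual
blocks, and a dense head ending in 8-way softmax (barcode) or a single
sigmoid unit (sensing). The attention mask's internal wiring is a design
choice made here: a parallel convolution over the stem features squashed
per position to [0, 1] by a sigmoid and multiplied elementwise into the
features. A residual block is two same-padding convolutions with a skip
path through a kernel-1 convolution, then max pooling and dropout; with
the skip and attention disabled the family reduces to the plain
convolutional baseline, with strictly fewer parameters (tested), and the
2×2 ablation {Brownian augmentation on/off × attention on/off} is runnable
at desk scale.

The engine is pure NumPy with manual backprop and Adam; rectifiers have a
small leak (slope 0.1) so units cannot go permanently dead — tiny networks
under heavy augmentation can otherwise collapse at initialization. Max
pooling requires the window to divide the feature length and raises a
shape error naming the offending block otherwise. Dropout and
initialization draw from a per-model seeded generator, so training is
bit-deterministic: the same seed reproduces the loss history exactly.
Training re-augments the training set each epoch, selects the weights of
the epoch with minimum validation loss, and aborts with the accumulated
history if the loss goes non-finite. Epoch training accuracy is
accumulated over training-mode minibatches (dropout active), the usual
convention.

Two presets exist. The **desk-scale** config (stem 16 filters, blocks
16/32 with pools 4 and 5, head 64; ~85k parameters) is what every test and
benchmark uses; it trains on one CPU in ~10 s per 20-epoch run at 400
traces. The **full-scale** config exists for structural experiments only:
the published full-size design does not fix every filter/unit count in
running text, so it is a best-effort reconstruction and no accuracy claims
attach to it.

## Benchmark design

The harness reproduces the comparison *design*: three arms — the classic
per-epoch recipe alone, classic + Brownian walk (σ = 0.9, the fixed
comparison value), and classic + the equivalent uniform stretch — each run
over ≥ 3 replicate seeds on synthetic datasets of 400 traces (50 per
class, 8 experiments), split with held-out experiments, validation-carved
(10 %) and oversampled to balance. Within a replicate all arms share the
dataset, the split and the model initialization, so arms are compared
paired. The report records per-replicate test accuracy, best epoch and
training accuracy, per-arm mean, standard deviation of the mean and 90th
percentile (linear interpolation between order statistics), and a
provenance block (seeds, config dicts, dataset SHA-256 hashes) sufficient
to re-run any cell bit-identically.

The harness asserts completion, above-chance accuracy (chance 1/8 plus
three binomial standard errors at the realized test size) and that the
control's realized event-length variance matches the Brownian arm's within
10 % — it does **not** assert that Brownian beats the alternatives: at
desk scale on synthetic data that ordering is stochastic, so it is
reported, not asserted. Replicate failures are recorded as rows with an
`error` field, never dropped.

## Numerical and degenerate-input conventions

- σ = 0 anywhere (walk, noise, stretch std) degenerates to exact identity
  paths; these are tested bit-exact.
- Walk clamping bounds: `[0, L−1]`; the lower clamp is the protocol's rule,
  the upper clamp is this package's choice (the padding-tail argument
  above).
- Interpolation validates its index range and refuses out-of-range input:
  clamping is `draw_indexes`' job, not the interpolator's.
- Sigmoid inputs are clipped to ±60 and log arguments to 1e-12 to avoid
  overflow without affecting results at working precision.
- Monte-Carlo tolerances in tests are set from the estimators' standard
  errors (typically 4 SE, or 5 % where a relative bound is the contract).
- Problem sizes in tests (replicate counts, dataset sizes, epochs) are
  desk-scale choices: large enough for the stated tolerances, small enough
  to iterate quickly.

## Known limitations

- The unraveling `m(t), α(t)` are stand-ins, not the literature's
  chain-segment calculation.
- The augmentation estimates position directly from the measured current;
  the pore's electrical filtering is not modeled (a stated simplification
  of the method itself).
- Synthetic-data conclusions do not transfer to real-data accuracy claims;
  the package makes none.
- The NumPy engine is desk-scale by design: no GPU, no batch-norm, no
  throughput claims; its contract is determinism and structural fidelity
  of the family.
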