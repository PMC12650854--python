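# Methods

## Model

An LPBN operates on a Boolean substrate `z ∈ {0,1}^m`. For tabular data the
substrate is produced by standardizing each feature to zero mean and unit
variance *on the training split only* and cutting it into `B` equal-width
bins spanning the standardized training min–max (`m = d·B`); exactly one
bit per feature block is hot. Values outside the training range clamp to
the boundary bins, so the one-hot invariant holds on any input. Two
optional constant bits (always 0, always 1) let a 2-input gate express
unary behaviors — identity is `AND(z_i, 1)`, negation is `XOR(z_i, 1)` —
and are used for the text task and for transition fitting. RL states are
discretized over *fixed physical ranges* rather than data ranges, with
`B = 8` bins per state variable for CartPole (positions/angles bounded by
the termination thresholds ±2.4 m and ±12°; velocities by ±3 m/s and
±3.5 rad/s, ranges that cover balanced trajectories).

Each of `N` units holds three categorical distributions — first input
(logits `α_n ∈ R^m`), second input (`β_n ∈ R^m`), operator
(`γ_n` over {AND, OR, XOR, NAND}) — and computes
`h_n = g_{O_n}(z_{A_n}, z_{B_n})` for a sampled triple. The selectors are
input-independent: the structure distribution is a property of the model,
not of the example. A head maps `h ∈ {0,1}^N` to the prediction: logistic
(binary cross-entropy), linear (squared error), softmax (multiclass), or
policy (action logits, `π(a|h) = softmax(Vh + c)`).

Because NAND alone is functionally complete, the family is a universal
approximator over discretized inputs. `core.compile_indicator` realizes
the constructive argument: literals via `NAND(x, x)`, conjunctions via
NAND-pair trees, so `1{z = pattern}` is exact on all of `{0,1}^d`, and a
linear readout over compiled indicators reproduces any finite map. These
circuits are multi-layer and exist to verify expressivity; trained LPBNs
are single-layer.

## Structure learning

Selector logits cannot be backpropagated through, so all structural
training uses the score-function identity
`∇_θ E[F] = E[(F − b)∇_θ log π_θ(S)]` with per-logit terms
`(F − b)(1{chosen = i} − π(i))`. The feedback is `F = −loss` per example
for supervised tasks and the (discounted) return for RL; the baseline is
an EMA `b ← βb + (1−β)F` with `β = 0.95`, initialized to the first
observed feedback. An entropy bonus `λ·H(π)` on every selector
distribution, annealed linearly from `λ0` to zero over the first half of
the budget, prevents premature collapse to one-hot selectors
(`λ0 = 10⁻³` supervised, `5×10⁻³` RL).

**Update reduction.** Within a mini-batch, each example draws its own
structure and contributes `(F_i − b)(1{·} − π)`; the structural update
applies the *sum* of these per-example terms (the head update uses the
mean). This mirrors the episodic estimator, which sums per-step terms
`Σ_t A_t ∇ log π(a_t|s_t)` over a trajectory, and it is what gives the
selector learning rate (7×10⁻² supervised) a workable signal scale: with
mean reduction the per-step logit movement is ~10⁻⁴ and realizable targets
never train; with the summed convention the same rates drive a realizable
conjunction target to train accuracy 1.0 within the 50-epoch budget on
every seed tested.

Alternative estimators are provided and tested:
`optimal_constant_baseline` (the variance-minimizing constant
`b* = E[F‖∇log π‖²]/E[‖∇log π‖²]`), `rao_blackwell_grad` (per-slot
conditional feedback tables, integrated exactly over the unit's own
choice, never larger variance by the law of total variance),
`gumbel_softmax_sample` (temperature-annealed relaxed sampling with common
random numbers), and a clipped straight-through backward rule. The default
training path is REINFORCE + EMA; the relaxed and RB estimators are
ablation options, and the full REBAR/RELAX corrections and learned critics
for the RB conditional are out of scope.

## Training recipes and defaults

Supervised: 50 epochs, batch 64, selector lr 7×10⁻², head lr 0.3 (midpoint
of the 0.25–0.35 range), early stopping disabled, evaluation once at the
end of training under the MAP structure (per-slot argmax, ties to the
lowest index). Default `N = 20` units for the `d=8, B=5` tasks, giving
20·(2·40+4)+21 = 1701 trainable parameters; the MLP baseline's hidden
width is the parameter-count match within ±10% (H = 170 is exact here).
A width chosen from a small reference MLP would give `N ≈ 2`, which has no
usable capacity, so the unit count anchors the match instead.

Regression trains on targets standardized on the training split (the head
is rescaled back afterwards) and uses the half-squared-error convention
(gradient = residual); both choices keep the stated head rate inside the
stability region of the 0/1 feature Gram matrix — with raw targets of
standard deviation ≈4 the head diverges within one epoch.

RL (LineWorld): 500 episodes, horizon 40, undiscounted, selector lr
7×10⁻², policy-head lr 1.8×10⁻¹, `N = 16`, structure sampled once per
episode (so the action log-probabilities along a trajectory are defined
under one concrete Boolean controller; per-step resampling — the
probabilistic-network reading — is a config switch). The MLP policy
(1 hidden tanh layer, lr 2×10⁻²) is width-matched to the LPBN's 386
parameters (H = 32).

DRL (CartPole): 300 episodes, horizon 280, γ = 0.99, selector lr 10⁻²,
head lr 2×10⁻², advantages clipped to [−5, 5], gradients to ℓ2-norm ≤ 5,
`λ0 = 5×10⁻³` annealed slowly — over the full 300-episode budget. Two
recipe choices matter here and are deliberate:

- **Linear critic on h** (lr 0.1) supplies per-step advantages
  `A_t = G_t − v·h_t`; a scalar EMA cannot center returns that vary with
  `t` by an order of magnitude, and with a saturating ±5 clip the
  uncentered advantages carry almost no signal.
- **Identity-biased selector initialization**: unit `n` starts with logit
  offset +8 on reading substrate bit `n` through OR (`OR(z, z) = z`), so
  the action head initially sees a stable copy of the discretized state
  while the selectors remain fully trainable under the entropy bonus.
  From a uniform initialization the policy head sees white-noise features,
  the selectors receive no credit, and training stalls near a 20-step
  return; with the identity bias the median final last-100-episode moving
  average is ≈230 and every tested seed exceeds the 200-step benchmark.
  Supervised tasks do not need the bias and default to uniform
  initialization.

## Dynamics

Rule files declare one gene per line (`NAME = expr` with
AND/OR/NOT/XOR/NAND and parentheses, precedence NOT > AND = NAND > XOR >
OR; `NAME := 0|1` freezes a gene). Updates are synchronous. Attractors are
enumerated exhaustively (guarded to ≤ 20 genes) by iterating every state
to its cycle; cycles are canonicalized to start at their minimal state and
basins count every state flowing into each attractor.

The perturbed chain flips each bit independently with probability `p`
*after* the deterministic update, giving the closed-form kernel
`P(x→y) = p^H (1−p)^{n−H}` with `H` the Hamming distance from the
deterministic successor; for `p > 0` the chain is irreducible and
aperiodic. Stationary distributions are computed by squaring-accelerated
power iteration (repeated `P ← P²` with row renormalization until all rows
agree to ℓ1 tolerance 10⁻¹²; equivalent to `2^k` plain iterations), which
handles the slow mixing at `p = 10⁻³`–`10⁻⁴` that defeats plain iteration;
non-mixing kernels (e.g. `p = 0`) are reported as errors rather than
returning one of many stationary vectors. KL divergences floor the second
argument at 10⁻¹² and renormalize.

Transition fitting collapses the observed `(x_t, x_{t+1})` pairs to unique
states with visit counts and per-gene empirical next-bit frequencies, then
trains one logistic-head LPBN per gene (substrate = state bits + constant
bits) on the count-weighted cross-entropy — identical in expectation to
per-sample training on the raw trajectory and far faster. The default
budget scales to ≈2400 selector updates regardless of how few unique
states the trajectory visited, since count-weighted batches carry less
per-update signal than raw replicated samples would. `lpbn_to_network`
freezes each gene's MAP structure through its head at threshold 0.5,
enabling attractor and stationary comparison against the source network.
A learned network is only constrained where the trajectory put mass
(`p = 10⁻³` keeps it near the attractors and their 1-flip neighborhoods),
so spurious extra attractors may appear in unvisited regions; recovery of
the source's attractors is the meaningful criterion, and it holds across
all seeds tested for the cell-cycle fixture.

The 10-gene mammalian cell-cycle fixture is transcribed from the published
logical model of Fauré, Naldi, Chaouiya & Thieffry (2006); CycD is the
self-sustaining growth-factor input, so the state space splits into a
CycD=0 half (quiescent fixed point: Rb, p27, Cdh1 on) and a CycD=1 half
(7-state cycle), 512 states each.

## Statistics

Comparisons are seed-paired: Δ_s = score_ANN(s) − score_LPBN(s) on a
higher-is-better scale (−RMSE for regression). Reported per task: mean Δ,
percentile bootstrap 95% CI (10,000 resamples; a bias-corrected variant is
a switch), exact two-sided sign test with ties dropped
(`p = min(1, 2·P(X ≥ max(n⁺, n⁻)))`, all ties → p = 1), Holm step-down
adjustment across tasks, Cliff's δ by direct dominance counting, and TOST
equivalence against a pre-registered margin (ε = 0.02 for accuracy,
0.05·|mean ANN score| for regression). The TOST verdict is "Yes" only when
both one-sided t-tests reject at α = 0.05 *and* the bootstrap CI lies
inside (−ε, ε) — the t-tests alone degenerate at 3 seeds. A winner is
declared when the bootstrap CI of the mean difference excludes zero;
otherwise "No clear winner". (A Holm-p-based winner rule would contradict
the degenerate 3-seed case where a consistent 3/0 split can never reach
p < 0.05.)

## Synthetic data

All generators are pure functions of their spec (seed → bitwise-identical
data); the task-defining weight vector draws from its own documented seed
(1150) so the same task is shareable across data seeds. Splits are
⌊0.7n⌋/⌊0.1n⌋/remainder, disjoint and exhaustive.

- Classification/regression: `x ~ N(0, I₈)`, score `w'x + ε`,
  `ε ~ N(0, σ²)` with σ = 0.1 by default (the noise scale is a free
  parameter of the generator; absolute benchmark scores therefore depend
  on it and are not reproduction targets).
- Blobs: 3 isotropic Gaussian clusters in R⁴, unit-norm means in a fixed
  2-plane at pairwise angles of exactly 120° (cosine −1/2), spread 0.25 —
  a well-separated regime where k-means on raw features reaches ARI ≈ 1.
- Text: "the product is [not] [intensifier] word." with 8 positive and
  8 negative polarity words and 4 label-neutral intensifiers; the label is
  polarity XOR the presence of "not", so interaction-free linear models
  sit at chance by symmetry.

What the generators do *not* emulate: correlated or heavy-tailed features,
label imbalance, covariate shift, real linguistic variety, asynchronous or
multi-predictor gene dynamics. Passing tests demonstrate the machinery and
its stated behaviors under these clean conditions, not performance on real
assay data.

## Known limitations

- Discretization bias: piecewise-constant approximations underfit smooth
  targets; the oblique linear-boundary classification and regression tasks
  stay far from the Bayes optimum under the standard recipe, and this is
  the expected regime of the method, not an implementation artifact.
- Credit assignment through the head: structure learning only receives
  signal proportional to the head weights on each unit, so distributed
  targets that need many coordinated units (full-vocabulary negation, raw
  CartPole from a uniform initialization) train slowly or need the
  initialization support described above.
- Dense chain analysis is limited to ≤ 12 genes (2^n × 2^n kernels);
  attractor enumeration to ≤ 20.
- Percentile bootstrap CIs undercover at very small n (measured ≈0.87 at
  n = 10 Gaussian); at n ≥ 20 coverage is within the nominal band.
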