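# Methods

This note documents the models, statistics and numerical choices behind
`tempograph`, and what the synthetic-data experiments do and do not
establish.

## Task structure and sequences

A session has eight phases of 121 stimulus presentations (PRE, E1–E6,
POST) separated by breaks B1–B7. Exposure sequences are simple random walks
on the experiment graph (uniform start, uniform neighbour steps), so every
transition is an edge and the stationary visit frequency of a node is
proportional to its degree (2:1 inner:outer on the pyramid). PRE/POST
sequences are constrained shuffles with **exactly 60 edge ("direct") and 60
non-edge ("indirect") transitions** and no immediate repeats; construction
draws the transition category with probability proportional to its
remaining budget and the partner node among the least-presented pairs,
rejecting attempts whose per-pair spread exceeds 2. Exposure phases carry
exactly 60 mirrored / 61 normal image flags. The first trial of each phase
has no preceding transition and is dropped, leaving 120 analysed trials per
phase. The per-pair presentation *averages* sometimes quoted for this
design (7 per direct, 9 per indirect transition) are arithmetically
inconsistent with the exact totals over 9 edges and 6 non-edges; the totals
are treated as binding.

## Distance templates

For adjacency matrix `A` (symmetric, binary, hollow):

- **geodesic** — all-pairs shortest-path edge counts (every non-adjacent
  pyramid pair is at distance 2);
- **euclidean** — geodesic, except non-adjacent inner–outer pairs at
  distance 2 (the hypotenuses 1–5, 4–3, 6–2 of unit right triangles) get
  √2. No planar layout realises these lengths exactly; the rule is applied
  combinatorially;
- **successor** — `ST = −e^A = −Σ Aⁿ/n!`: path counts of all lengths with
  factorial discounting, negated so larger = farther. Its diagonal is *not*
  constant (closed-walk counts grow with degree), so all statistics use
  off-diagonal entries only;
- **discounted successor** — `−(I − γA)⁻¹ = −Σ γⁿAⁿ`, valid for
  γ < 1/ρ(A) (ρ ≈ 3.24 on the pyramid, so γ < 0.309); γ is a config
  parameter (default 0.15) since no canonical value exists.

2-D illustrations use metric Sammon-stress MDS: the matrix is shifted
positive by |min| + 0.1, then L-BFGS minimises the Sammon stress from (by
default) 100 random seeded initialisations, keeping the best. This makes
the embedding reproducible where only the stress criterion is prescribed.

## Synthetic sessions

Each neuron is Poisson. Baseline rate (default 2 Hz) applies everywhere —
trials, inter-trial intervals and breaks. During a trial, a boxcar kernel
from 0.1 to 1.0 s after onset adds `preferred_gain × m`, where the
multiplier `m` depends on the presented stimulus relative to the neuron's
preferred node and the phase: the selectivity-decay schedule for the
preferred stimulus, the direct-gain schedule for graph neighbours, a
constant (default 0) for indirect stimuli. With `remap_profile="successor"`
the spread is graded by e^A closeness instead of the adjacency dichotomy.
Timing follows the task description: self-paced stimulus duration modelled
lognormal with 0.9 s median, 0.5 s feedback, ITI uniform on 1–3 s; break
duration is a parameter (default 60 s).

Defaults are chosen for single-session statistical power where the source
design gives no effect sizes: preferred gain 8 Hz; decay schedule falling
to 0.55 by E5–E6 and persisting at POST; direct gain rising to 0.6 of the
preferred gain by E5. One regime deserves a caution: when the planted
spread approaches the concurrent preferred gain, the representations of
adjacent nodes merge and the population *geometry* degenerates even though
single-neuron relational detection still succeeds. The successor-geometry
scenarios therefore use a milder ratio (spread 0.35 vs. decay floor 0.7),
consistent with decoded posteriors in which the presented stimulus stays
dominant throughout.

`simulate_template_population` plants an exact geometry: the
positive-shifted template is made Euclidean-embeddable by the smallest
additive constant (bisection on the double-centred Gram matrix's minimum
eigenvalue — rank order is unchanged), embedded by classical MDS, and each
neuron adopts one embedding dimension as its tuning axis, so the expected
population distance matrix is rank-faithful to the template.

Replay injection adds seed-neuron spikes inside named breaks, each followed
by one direct- and one indirect-neuron spike at the requested latencies
(±1 ms jitter, clipped inside (0, 30) ms).

What the generator does **not** emulate: bursting and refractoriness,
rate drift and unit instability, correlated noise across neurons,
theta/ripple structure in breaks, and behavioural-performance coupling.
Passing tests therefore demonstrate the *analysis code's* sensitivity and
calibration under Poisson assumptions, not properties of any real
recording.

## Preprocessing

Spikes are counted in half-open 0.1 s bins on a −1…+2 s window around each
onset, smoothed with a ±0.25 s moving sum (edge windows truncated — no
padding beyond the window), baseline-corrected by the −0.5…0 s mean, and
optionally z-scored per neuron over all bins and trials of the session
(session scope keeps phases on a common scale; zero-variance neurons are
flagged silent and excluded downstream). Analysis windows are named
presets: selection 0.1–1.2 s; decoding 0.1–1.0 s (summed counts);
distances 0.1–1.0 s with ±0.15 s smoothing. Baseline correction precedes
z-scoring in provenance order.

## Single-neuron statistics

The preferred stimulus is the PRE argmax of mean response-window activity
(ties → lowest node id, flagged). Selectivity requires, during PRE,
(1) response window > baseline on preferred trials and (2) preferred >
remaining stimuli combined; relational neurons additionally show direct >
indirect during E5+E6 and direct E5+E6 > E1+E2 (PRE/POST never enter the
selection, keeping PRE-vs-POST contrasts unbiased); diminishing
selectivity is preferred E1+E2 > E5+E6. All one-sided rank tests at
α = 0.05. Where a signed-rank test needs pairs from unequal trial counts,
each trial of the smaller sample is paired with the mean of a consecutive
temporal chunk of the larger (`np.array_split`); an unpaired rank-sum
variant is available (`method="rank_sum"`).

Because the preferred stimulus is chosen by argmax on the same PRE data the
criteria test, raw selective fractions are inflated under the null (flat
Poisson units come out "selective" at ~20–25%, not α²) — which is why
region-level inference is a label-permutation test: stimulus labels
(selectivity) or exposure-phase labels (relational/diminishing) are
permuted per neuron and the classification re-run. The empirical P value
counts permutations detecting **at least as many** neurons as observed;
counting only strictly more is anticonservative for small discrete counts
(an observed count of 0 would otherwise earn a small p from rare non-zero
permutations). Detected-count ties are common at desk scale, so the
tie-inclusive rule is the default and is what the calibration suite
verifies (super-uniform null p).

## Population statistics

**Decoder.** Poisson naive Bayes with uniform prior on summed 0.1–1.0 s
counts; per-class rates are trial means floored at ε = 0.01 to avoid zero
likelihoods. PRE is decoded leave-one-trial-out; later phases by the
PRE-trained model. Posterior entries are labelled actual / direct /
indirect relative to the presented stimulus and pooled; phase contrasts
use one-sided two-sample KS tests with directions fixed a priori (actual:
decrease; direct: increase; indirect: increase by default, both reported).
Pairwise node comparisons pool trials by seed role and label posterior
entries by relation to the seed (direct-inner, indirect-outer, …),
reporting KS z = D·√(mn/(m+n)) with the smaller one-sided p,
Benjamini–Hochberg corrected.

**Distance matrices.** Euclidean distances between per-node population
mean-response vectors (active neurons only), z-scored over off-diagonal
entries per phase group. The default estimator subtracts the sampling
variance of each node mean from the squared differences (an unbiased
squared-distance estimator): under a random-walk schedule the outer nodes
receive about half the trials of inner nodes, and the naive estimator's
noise inflation of outer-node distances masquerades as successor-like
geometry — the calibration suite fails without the correction.
`unbiased=False` restores the plain formula. Bias-corrected squared
distances can dip below zero; a signed square root keeps the ordering
monotone. Template fits are Spearman correlations over the 15 off-diagonal
pairs, Fisher-transformed (|ρ| clipped at 1 − 10⁻⁶), reported as changes
from PRE. Null distributions come from node relabelings applied jointly to
every phase's matrix (10,000 by default; p = 0 is reported as a bound
below 1/n_perm). Template contrasts permute the same way on the difference
of PRE-subtracted fits, with ties counted as exceedances so the degenerate
equal-template contrast is non-significant. Region contrasts balance
neuron counts by subsampling the larger region (squared distances are
additive over neurons, so each draw is a sum, not a recomputation) and
permute region labels; ablation curves report template-fit quartiles as a
function of the removed fraction, compared between regions on third
quartiles with a label-permutation p.

**Replay.** Candidate triplets are selective same-hemisphere neurons whose
preferred nodes form a seed–direct–indirect path. Only break-period spikes
are scanned; for each seed spike both partners' first spikes within
(0, 30] ms are required (the window is half-open — a zero-lag coincidence
carries no order information), and each seed spike is evaluated
independently when windows overlap. Candidates need ≥ 5 repetitions — the
smallest n whose exact one-sided all-one-sign signed-rank p (1/32) clears
α = 0.05. Verdicts use an exact sign-flip enumeration over (possibly tied,
averaged) ranks via dynamic programming on doubled ranks; this matches the
classic exact tables for untied data and handles the ties that arise when
overlapping seed windows share partner spikes. Epoch-level proportions
(B1 vs. B2–B7) are tested against a null that swaps each repetition's
direct/indirect labels with probability 1/2 (1,000 permutations; zero
exceedances reported as p < 0.001). No multiple-comparison adjustment is
applied here, matching the design being emulated.

## Reproducibility and problem sizes

All randomness flows from one root seed through named substreams
(`SeedSequence(seed, spawn_key)`), so stages re-run in isolation
bit-identically. Library defaults keep the published permutation counts
(1,000 / 10,000); the test and acceptance suites run reduced
configurations chosen as the package's own desk-scale working points —
sessions of 20–70 neurons, 10–12 null sessions for calibration, 40–2,000
permutations per test, 100 seeds for template-selection rates — which keep
the full suite under two minutes while leaving every assertion's margin
wide (sensitivities near 100% against a 70% requirement, selection rates
98–100% against 90%).

## Known limitations

- The pyramid's non-adjacent pairs are all at geodesic distance 2, so
  geodesic and Euclidean templates differ on only three pairs; Spearman
  fits against templates with tied entries have a ceiling below 1 for any
  continuous empirical matrix.
- Node-permutation tests on a 6-node graph draw from only 720 distinct
  relabelings; attainable p values are correspondingly coarse.
- Single-session geometry (≤ ~70 neurons) is underpowered for the
  PRE-subtracted fit change; pooling neurons across sessions, as the
  emulated design does, is the intended operating regime.
- The region contrast and ablation analyses assume the per-neuron distance
  contributions are exchangeable across regions under the null; planted
  differences in tuning *sharpness* that also change overall rate scale
  can confound them.
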