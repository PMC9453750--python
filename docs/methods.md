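# Methods

## The task

The Iowa Gambling Task (IGT) presents four decks of cards, A–D. Every draw
pays a fixed reward — 100 units for decks A and B, 50 for C and D — and
sometimes incurs a loss according to a deterministic cyclic schedule indexed
by how many cards have been drawn from that specific deck (physical-deck
semantics: each deck's counter advances independently). Over each 10-draw
cycle, decks A and B lose 250 net (bad decks) while C and D gain 250 (good
decks); A and C lose often in small amounts, B and D rarely but heavily. The
default `traditional` scheme pins the canonical Bechara loss tables
(A: 150/300/200/250/350 at five positions; B: one 1250; C: five 50s;
D: one 250); a `fixed_C` variant holds deck C's loss constant at 25 per draw.
Only this relative structure — net-payoff signs and loss-frequency ordering —
matters for the analyses here, and both are enforced as registry invariants.
The loss positions are fixed rather than randomized so off-policy probes are
exactly reproducible. Subjects start with a virtual endowment of 2,000.

## The choice model

Behavior is modeled trial-by-trial by a gated recurrent unit (GRU) layer with
`N_u` hidden cells feeding a bias-free softmax head over the four decks. The
input at step t is the previous trial's one-hot choice plus its reward and
loss (both divided by 100 — unscaled currency up to 1250 saturates the
sigmoid/tanh gates); the first step receives an all-zeros start token, and
every trial is a scored prediction target. The recurrence is

    z_t  = σ(W_z x_t + U_z h_{t−1} + b_z)
    r_t  = σ(W_r x_t + U_r h_{t−1} + b_r)
    h'_t = tanh(W x_t + b_hW + r_t ⊙ (U h_{t−1} + b_hU))
    h_t  = z_t ⊙ h_{t−1} + (1 − z_t) ⊙ h'_t

with h_0 = 0. Two deliberate conventions: the update gate z multiplies the
*old* state (an exact z ↔ 1−z relabeling of the more common orientation, kept
so the equations above are literally what the code computes — tests must not
assume a library-default GRU), and the candidate-state bias `b_hU` sits
inside the reset product (the "reset applies to the recurrent term" reading;
the alternative placement, outside the product, is a one-line change and was
not pursued). The objective is the categorical cross-entropy summed over
subjects and trials; a floor of 1e−12 inside the log guards impossible
events without measurable bias.

Forward, backward (full backpropagation through time) and Adam are written
directly over numpy arrays. The backward pass is exact — it is checked
against central finite differences to relative error ≤ 1e−4 in the test
suite, and the recurrence against an element-wise scalar oracle to 1e−8.
Initialization is uniform ±1/√N_u for weights and zero for biases, from an
explicit seed. The optimizer minimizes the per-sequence-mean loss internally
(loss histories report the summed convention); this normalization is what
makes one-step federated averaging algebraically equal to a pooled gradient
step (below). Within a minibatch, the seeded shuffle decides membership only
and rows are processed in sorted order, so full-batch training is invariant
to the shuffle seed. Defaults: N_u = 10, learning rate 0.02, 250 epochs,
centralized batch size 50.

## Collaborative paradigms

Four ways ten laboratories can pool their learning, all consuming every
training sample exactly 250 times (the equal-exposure budget; audited by
instrumented per-sample counters):

- **CL** (centralized): pool all subjects, one 250-epoch fit, minibatch 50.
- **IL** (incremental): each lab trains 250 epochs on its own data
  (full-lab batch) and hands the parameters to the next lab; one pass.
- **CIL** (cyclic incremental): 5 cycles of 50 epochs per lab.
- **FL** (federated): 5 rounds; in each, every client trains 50 local epochs
  from the global model and the server averages parameters element-wise with
  weights n_k/Σn (FedAvg). All ten clients participate every round
  (cross-silo); synchronization is deterministic by default (`sync_prob=1`),
  with the stochastic-adoption reading exposed as an option.

Lab orderings for IL/CIL: ascending or descending by training-set size (ties
broken by lab id) or a seeded permutation. Adam state is reset at every
hand-off and round — only parameters travel in these protocols — so a
5×50-epoch cyclic run on one lab is *not* bit-equal to one 250-epoch run,
while the true degeneracies (single cycle ≡ IL; single lab ≡ CL; single
client ≡ CL) are exact and tested. Size-weighted averaging makes a one-local-
gradient-step round equal the pooled full-batch gradient step, a linearity
identity the tests verify to 1e−8.

## Evaluation

Prediction accuracy is next-choice argmax accuracy pooled over all scored
trials of a test set (trial-weighted, consistent with the summed loss; a
per-subject view is also emitted). Ties break to the lowest deck index; with
zero-initialized biases the start-token trial is an exact four-way tie, so
symmetry properties are stated on probabilities, not argmax. Splits are
subject-level, train size floor(0.8·n) — the only rule consistent with the
canonical per-lab training sizes (12, 129, …, 122) summing to 491 — seeded
and recorded in run metadata. Hyperparameter tuning is subject-level k-fold
cross-validation over a (N_u × epochs) grid, with per-trial-averaged
validation loss so unequal folds are comparable; each fold is trained once to
the largest epoch candidate and all epoch candidates are read off that run.

## Synthetic cohort

The generator emulates the canonical many-labs pool: 10 labs of sizes
15, 162, 19, 40, 70, 25, 153, 35, 57, 41 (617 subjects), native trial counts
mixing 95/100/150 (the smallest lab runs 95; the two last labs 150), all
truncated to 95 for modeling. Subjects are delta-rule expectancy agents:
E_d ← E_d + a(u − E_d) for the chosen deck, u = (1−w)·reward − w·loss in raw
currency, with softmax choice over θ·E_d plus a perseverance bonus π for
repeating the previous deck. Labs differ in the hyperprior means of
(a, w, θ, π) — population heterogeneity, not label skew, is the non-IID
mechanism — with within-lab spreads common to all labs. Because utility is in
raw currency, θ is O(0.01–0.035) per unit. The canonical means are spread so
that between-lab differences in good-deck preference exceed within-lab
standard errors, giving genuinely non-IID clients.

This agent family reproduces the three signatures the analyses measure:
gradual good-deck learning, switching after losses, and tolerance of deck B's
rare large losses. One caveat found while validating: the switch-after-loss >
switch-after-no-loss ordering requires residual exploration. A near-greedy
agent (large θ) on the deterministic schedule locks into a stable least-loss
cycle and the ordering reverses; the canonical hyperpriors sit well inside
the exploratory regime. What the generator does not emulate: demographic
covariates, payoff-variant diversity across labs beyond the registered
variants, and any within-subject nonstationarity beyond the delta rule — so
passing tests show the pipeline recovers the structure this population has,
not that it matches any particular human dataset.

## Behavioral statistics

On-policy simulation lets a trained model play the task: actions are
*sampled* from the predictive distribution (argmax would collapse all agents
onto near-identical trajectories, erasing subject-like dispersion); the agent
count defaults to the training-population size. Off-policy probes force one
deck for 30 trials, feed the scheme's payoffs, and record the model's
probability of repeating that deck — deterministic by construction.

Readouts: per-subject deck proportions; block learning scores
(#good − #bad per block; 95 trials → 9 blocks of 10 plus one of 5; other
lengths fall back to floor(T/10) full blocks plus remainder, with a warning);
and switch probability conditioned on whether the previous trial lost
(any positive loss counts; magnitude is ignored). A subject who never lands
in a condition reports NaN there and is excluded from that cell's mean.
Group contrasts are mean differences with t-based inference (Welch unpaired,
paired otherwise). The blocks × group comparison uses a mixed-design ANOVA
via pingouin with Greenhouse–Geisser correction (the conservative ε choice);
with a 2-level within factor ε ≡ 1. The between-groups F is independently
cross-checked against the squared pooled-variance t on subject means.

## Problem sizes and determinism

Tests exercise reduced configurations chosen to keep every property
observable: schedule/exposure audits on 10 labs × 2 subjects × 10 trials;
the behavior-recovery check on a quarter-scale canonical pool (≈154
subjects) with the full 250-epoch budget; the overfitting demonstration on a
12-subject lab watched over 250 epochs (validation loss bottoms out around
epoch 60–70 there and rises afterwards while training loss keeps falling).
The acceptance script runs the full 617-subject pool. Every stochastic
operation takes an explicit seed; a single run seed fans out to per-stage
seeds through `numpy.random.SeedSequence`, so reruns are byte-identical and
individual stages are independently reproducible.

## Known limitations

- The agent family is one convenient member of the expectancy-valence
  class; its parameters are not fitted to any human data.
- Accuracy levels on synthetic pools depend on the generator's θ/π regime
  and are not comparable to accuracies on human datasets.
- The loss-schedule tables are the canonical fixed-position ones; per-study
  variants of the source pool (beyond `fixed_C`) must be supplied by the
  user via the scheme registry.
- Single-CPU numpy training is efficient at these model sizes (N_u = 10)
  but would not scale to substantially larger hidden layers.
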