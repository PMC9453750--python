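# fediowa

Collaborative training of recurrent choice models on Iowa Gambling Task (IGT)
data, for computational cognitive modelers who want to pool trial-by-trial
decision data across laboratories without sharing it.

Cognitive experiments are small — tens of subjects per site — while neural
models of behavior are data-hungry. When ten labs each hold IGT records
(per-trial deck choice, reward, loss), there are four ways to learn one model
from all of them:

- **CL** — centralized: pool the raw data, train once (the privacy-free
  benchmark);
- **IL** — incremental: labs train in sequence, handing parameters to the
  next site;
- **CIL** — cyclic incremental: the same, repeated over shorter cycles;
- **FL** — federated: parallel local training with size-weighted parameter
  averaging (FedAvg) at a central server each round.

All four consume every training sample exactly 250 times, so their
accuracies are comparable. The model is a GRU layer (N_u = 10 hidden cells)
plus a softmax head over the four decks: input x_t ∈ R^{N_c+2} is the
previous one-hot choice with its scaled reward and loss, and training
minimizes the categorical cross-entropy −Σ_s Σ_t y_st · log ŷ_st with Adam
(learning rate 0.02). The recurrence and its backpropagation are implemented
explicitly over numpy arrays and verified against a scalar oracle and finite
differences.

A synthetic-cohort module generates a 10-lab pool with the canonical sizes
(15, 162, …, 41; 617 subjects, 95/100/150-trial mixes) from delta-rule
expectancy agents whose parameters differ by lab — non-IID clients with
learnable strategies — so the whole pipeline runs with no downloads. Local
copies of the real many-labs pool (wide CSV tables of choices/wins/losses
plus a subject→lab index) load through the same reader. Trained models are
evaluated by per-lab next-choice accuracy and by simulation: on-policy
(models play the task autonomously) and off-policy (one deck is forced and
the stay probability is probed), summarized as deck proportions, block
learning scores, switch-after-loss probabilities, and mixed-design ANOVA.

See `docs/methods.md` for the full model and design notes.

## Worked example

```python
import numpy as np
from fediowa import (
    canonical_profiles, generate_pool, truncate_pool, split_lab,
    TrainPlan, train, accuracy, build_scheme,
    simulate_on_policy, switch_probability,
)

# quarter-scale canonical pool: 10 non-IID labs, 154 subjects
pool = truncate_pool(generate_pool(canonical_profiles(0.25), seed=1), 95)
splits = [split_lab(ds, 0.8, seed=i) for i, ds in enumerate(pool)]
train_sets = [tr for tr, _ in splits]
test_sets = [te for _, te in splits]

cl = train(train_sets, TrainPlan(paradigm="CL", seed=3))
accs = [accuracy(cl.params, te) for te in test_sets]
print(f"held-out accuracy per lab: {np.round(accs, 2)}")
print(f"average: {np.mean(accs):.3f}  (chance 0.25)")

agents = simulate_on_policy(cl.params, build_scheme("traditional"),
                            n_agents=200, T=95, seed=7)
sw = switch_probability(agents)
print(f"P(switch | loss) = {np.nanmean(sw[:, 0]):.3f}, "
      f"P(switch | no loss) = {np.nanmean(sw[:, 1]):.3f}")
```

Output:

```
held-out accuracy per lab: [0.21 0.48 0.28 0.42 0.32 0.26 0.57 0.37 0.42 0.3 ]
average: 0.363  (chance 0.25)
P(switch | loss) = 0.605, P(switch | no loss) = 0.481
```

The pooled model predicts held-out next choices well above the 25% chance
level (labs with more training subjects, like labs 2 and 7, are predicted
best), and its on-policy agents reproduce the training population's
loss-avoidance signature: they switch decks more often after a loss.

The same pipeline is scriptable end to end:

```sh
fediowa run-all --seed 0 --size-scale 0.25 --out runs/demo
fediowa report --run-dir runs/demo
```

which trains all eight collaborative models (CL, FL, and IL/CIL in three lab
orders), writes the accuracy matrix and behavior CSVs, and renders the
figure analogs from those CSVs.

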