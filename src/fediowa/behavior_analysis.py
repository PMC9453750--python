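"""On-/off-policy simulation of trained models and behavioral statistics.

The behavioral readouts mirror the standard IGT analyses: per-subject deck
proportions, block learning scores (good-deck minus bad-deck choices per block
of trials; decks C/D are good, A/B bad), and switch probability conditioned on
whether the previous trial incurred a loss.  Group contrasts use t-based mean
differences and a mixed-design (blocks x group) ANOVA with Greenhouse-Geisser
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ChoiceSequence, N_CHOICES
from .gru_choice_model import ModelParams, _sigmoid, _softmax
from .igt_task import PayoffScheme

GOOD_DECKS = (3, 4)  # C, D
BAD_DECKS = (1, 2)   # A, B


@dataclass
class BehaviorSummary:
    group: str
    deck_proportions: np.ndarray        # (n_subjects, 4)
    block_scores: np.ndarray            # (n_subjects, n_blocks)
    switch_probs: np.ndarray            # (n_subjects, 2): after-loss, after-no-loss


def _batched_step(params: ModelParams, x: np.ndarray, h: np.ndarray) -> np.ndarray:
    z = _sigmoid(x @ params.W_z.T + h @ params.U_z.T + params.b_z)
    r = _sigmoid(x @ params.W_r.T + h @ params.U_r.T + params.b_r)
    hbar = np.tanh(x @ params.W.T + params.b_hW + r * (h @ params.U.T + params.b_hU))
    return z * h + (1 - z) * hbar


def simulate_on_policy(
    params: ModelParams,
    scheme: PayoffScheme,
    n_agents: int,
    T: int = 95,
    seed: int = 0,
    scale: float = 100.0,
) -> list[ChoiceSequence]:
    """Let ``n_agents`` model agents play the task autonomously.

    At every trial each agent's next deck is sampled from the model's
    predictive distribution given its own history; payoffs come from the
    scheme with independent per-deck draw counters per agent.
    """
    rng = np.random.default_rng(seed)
    h = np.zeros((n_agents, params.N_u))
    x = np.zeros((n_agents, params.N_c + 2))
    draws = np.zeros((n_agents, N_CHOICES), dtype=int)
    loss_tables = np.array(scheme.loss_schedule)  # (4, 10)
    rewards_per_deck = np.array(scheme.reward_per_deck)

    choices = np.empty((n_agents, T), dtype=np.int64)
    rewards = np.empty((n_agents, T))
    losses = np.empty((n_agents, T))
    agents = np.arange(n_agents)
    for t in range(T):
        h = _batched_step(params, x, h)
        p = _softmax(h @ params.V)
        # vectorized categorical sampling
        u = rng.random((n_agents, 1))
        d = (p.cumsum(axis=1) < u).sum(axis=1)
        d = np.minimum(d, N_CHOICES - 1)
        r = rewards_per_deck[d]
        l = loss_tables[d, draws[agents, d] % 10]
        draws[agents, d] += 1
        choices[:, t] = d + 1
        rewards[:, t] = r
        losses[:, t] = l
        x = np.zeros((n_agents, params.N_c + 2))
        x[agents, d] = 1.0
        x[:, N_CHOICES] = r / scale
        x[:, N_CHOICES + 1] = l / scale
    return [
        ChoiceSequence(f"agent_{i+1}", 0, choices[i], rewards[i], losses[i])
        for i in range(n_agents)
    ]


def deck_proportions(
    sequences: Sequence[ChoiceSequence],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-subject deck-choice proportions plus group mean and standard error."""
    if len(sequences) == 0:
        raise ValueError("no sequences")
    props = np.stack(
        [np.bincount(s.choices - 1, minlength=N_CHOICES) / s.T for s in sequences]
    )
    mean = props.mean(axis=0)
    se = props.std(axis=0, ddof=1) / np.sqrt(len(sequences)) if len(sequences) > 1 else np.zeros(N_CHOICES)
    return props, mean, se


def _block_edges(T: int) -> list[tuple[int, int]]:
    if T == 95:
        edges = [(i * 10, i * 10 + 10) for i in range(9)] + [(90, 95)]
    else:
        warnings.warn(f"T={T} != 95; using floor(T/10) full blocks plus remainder")
        n_full = T // 10
        edges = [(i * 10, i * 10 + 10) for i in range(n_full)]
        if T % 10:
            edges.append((n_full * 10, T))
    return edges


def block_learning_scores(sequences: Sequence[ChoiceSequence]) -> np.ndarray:
    """Per-subject per-block (good - bad) choice counts.

    For the canonical 95-trial sequences: 9 blocks of 10 trials plus a final
    block of 5.
    """
    edges = _block_edges(sequences[0].T)
    scores = np.empty((len(sequences), len(edges)))
    for i, s in enumerate(sequences):
        good = np.isin(s.choices, GOOD_DECKS)
        for b, (lo, hi) in enumerate(edges):
            seg = good[lo:hi]
            scores[i, b] = seg.sum() - (len(seg) - seg.sum())
    return scores


def switch_probability(sequences: Sequence[ChoiceSequence]) -> np.ndarray:
    """Per-subject (P(switch | loss), P(switch | no loss)); NaN when a subject
    never lands in a condition."""
    out = np.full((len(sequences), 2), np.nan)
    for i, s in enumerate(sequences):
        switched = s.choices[1:] != s.choices[:-1]
        lossy = s.losses[:-1] > 0
        if lossy.any():
            out[i, 0] = switched[lossy].mean()
        if (~lossy).any():
            out[i, 1] = switched[~lossy].mean()
    return out


@dataclass
class GroupDiff:
    eta: float  # mean(a) - mean(b)
    se: float
    p: float


def group_mean_diff(
    values_a: np.ndarray, values_b: np.ndarray, paired: bool = False
) -> GroupDiff:
    """Two-sided mean difference with t-based inference (Welch if unpaired)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    eta = float(a.mean() - b.mean())
    if len(a) < 2 or len(b) < 2:
        return GroupDiff(eta, float("nan"), float("nan"))
    if paired:
        d = a - b
        se = float(d.std(ddof=1) / np.sqrt(len(d)))
        _, p = stats.ttest_rel(a, b)
    else:
        se = float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)))
        _, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupDiff(eta, se, float(p))


@dataclass
class MixedAnovaResult:
    F_interaction: float
    df_interaction: tuple[float, float]  # Greenhouse-Geisser corrected
    p_interaction: float
    F_block: float
    df_block: tuple[float, float]
    p_block: float
    F_group: float
    df_group: tuple[float, float]
    p_group: float
    epsilon: float


def mixed_anova(block_scores_a: np.ndarray, block_scores_b: np.ndarray) -> MixedAnovaResult:
    """Mixed-design ANOVA: within-factor block, between-factor group.

    Greenhouse-Geisser correction is applied to the within and interaction
    terms (computed through pingouin).
    """
    import pingouin as pg

    a = np.asarray(block_scores_a, dtype=float)
    b = np.asarray(block_scores_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("inputs must be subjects x blocks with equal block counts")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    n_blocks = a.shape[1]

    rows = []
    for g, scores in (("a", a), ("b", b)):
        for i, subj in enumerate(scores):
            for blk in range(n_blocks):
                rows.append(
                    {"subject": f"{g}{i}", "group": g, "block": blk + 1, "score": subj[blk]}
                )
    df = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(
            data=df, dv="score", within="block", subject="subject", between="group",
            correction=True,
        ).set_index("Source")

    aov.columns = [c.replace("-", "_") for c in aov.columns]
    blk, grp, inter = aov.loc["block"], aov.loc["group"], aov.loc["Interaction"]
    eps = 1.0 if n_blocks == 2 else float(blk["eps"])
    eps = min(max(eps, 1.0 / (n_blocks - 1)), 1.0)

    def corrected(row):
        df1, df2 = float(row["DF1"]), float(row["DF2"])
        p = row.get("p_GG_corr", np.nan)
        if not np.isfinite(p):
            # GG-corrected p from the F with epsilon-scaled dfs
            p = float(stats.f.sf(row["F"], df1 * eps, df2 * eps))
        return (df1 * eps, df2 * eps), float(p)

    df_i, p_i = corrected(inter)
    df_b, p_b = corrected(blk)
    return MixedAnovaResult(
        F_interaction=float(inter["F"]),
        df_interaction=df_i,
        p_interaction=p_i,
        F_block=float(blk["F"]),
        df_block=df_b,
        p_block=p_b,
        F_group=float(grp["F"]),
        df_group=(float(grp["DF1"]), float(grp["DF2"])),
        p_group=float(grp["p_unc"]),
        epsilon=eps,
    )


def simulate_off_policy(
    params: ModelParams,
    forced_deck: int,
    T: int = 30,
    scheme: PayoffScheme | None = None,
    scale: float = 100.0,
) -> pd.DataFrame:
    """Force one deck for ``T`` trials and probe the model's stay probability.

    Returns a tidy frame with, per trial, the model's predicted probability of
    repeating the forced deck and a marker for trials on which the scheme
    delivered a loss.  Fully deterministic.
    """
    from .igt_task import build_scheme, payoff

    if not 1 <= forced_deck <= N_CHOICES:
        raise ValueError(f"forced_deck must be 1..{N_CHOICES}")
    scheme = scheme or build_scheme("traditional")
    h = np.zeros(params.N_u)
    x = np.zeros(params.N_c + 2)
    rows = []
    for t in range(T):
        h = _batched_step(params, x[None, :], h[None, :])[0]
        p = _softmax(h @ params.V)
        r, l = payoff(scheme, forced_deck, t)
        rows.append(
            {
                "trial": t + 1,
                "p_stay": float(p[forced_deck - 1]),
                "loss": l,
                "loss_trial": l > 0,
            }
        )
        x = np.zeros(params.N_c + 2)
        x[forced_deck - 1] = 1.0
        x[N_CHOICES] = r / scale
        x[N_CHOICES + 1] = l / scale
    return pd.DataFrame(rows)


def summarize(sequences: Sequence[ChoiceSequence], group: str) -> BehaviorSummary:
    props, _, _ = deck_proportions(sequences)
    return BehaviorSummary(
        group=group,
        deck_proportions=props,
        block_scores=block_learning_scores(sequences),
        switch_probs=switch_probability(sequences),
    )
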