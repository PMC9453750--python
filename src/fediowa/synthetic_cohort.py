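"""Synthetic 10-lab IGT cohort with lab-level strategy heterogeneity.

Subjects are delta-rule expectancy agents: after choosing deck d and receiving
reward r and loss l, the deck's expectancy updates as

    E_d <- E_d + a * (u - E_d),      u = (1 - w) * r - w * l   (raw currency),

and the next choice is softmax over theta * E_d plus a perseverance bonus pi
for repeating the previous deck.  Labs differ in the hyperprior means of
(a, w, theta, pi), which makes the generated clients non-IID in strategy —
the structure the collaborative-training comparison assumes — while every lab
still shows the three qualitative signatures of human play: gradual good-deck
learning, switching after losses, and tolerance of deck B's rare large losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .data_model import (
    CANONICAL_LAB_SIZES,
    ChoiceSequence,
    LabDataset,
    N_CHOICES,
    ValidationError,
)
from .igt_task import PayoffScheme, build_scheme, payoff


@dataclass(frozen=True)
class AgentParams:
    """Knobs of one synthetic subject."""

    learn_rate: float   # a in [0,1]: expectancy update speed
    loss_weight: float  # w in [0,1]: loss vs reward salience in utility
    consistency: float  # theta >= 0: softmax inverse temperature (per currency unit)
    perseverance: float  # pi: additive logit bonus for repeating the last deck

    def __post_init__(self) -> None:
        if not 0 <= self.learn_rate <= 1:
            raise ValidationError(f"learn_rate must be in [0,1], got {self.learn_rate}")
        if not 0 <= self.loss_weight <= 1:
            raise ValidationError(f"loss_weight must be in [0,1], got {self.loss_weight}")
        if self.consistency < 0:
            raise ValidationError(f"consistency must be >= 0, got {self.consistency}")


@dataclass
class LabProfile:
    lab_id: int
    n_subjects: int
    native_T: int = 100
    payoff_variant: str = "traditional"
    # per-parameter (mean, spread) hyperpriors; draws are clipped to bounds
    hyperpriors: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValidationError(f"lab {self.lab_id}: n_subjects must be > 0")


# Canonical lab hyperprior means, one row per lab.  The spread across labs is
# the non-IID mechanism; within-lab spreads are common to all labs.
_LAB_MEANS = {
    # lab: (a, w, theta, pi)
    1: (0.10, 0.25, 0.010, 0.20),
    2: (0.30, 0.45, 0.030, 0.60),
    3: (0.15, 0.30, 0.015, 0.30),
    4: (0.25, 0.50, 0.025, 0.50),
    5: (0.20, 0.40, 0.020, 0.40),
    6: (0.12, 0.28, 0.012, 0.25),
    7: (0.35, 0.55, 0.035, 0.70),
    8: (0.18, 0.35, 0.018, 0.35),
    9: (0.28, 0.48, 0.028, 0.55),
    10: (0.22, 0.42, 0.022, 0.45),
}
_SPREADS = {"learn_rate": 0.05, "loss_weight": 0.08, "consistency": 0.006, "perseverance": 0.15}
# trial counts mirroring the canonical pool's 95/100/150 mix
_LAB_T = {1: 95, 2: 100, 3: 100, 4: 100, 5: 100, 6: 100, 7: 100, 8: 100, 9: 150, 10: 150}


def canonical_profiles(size_scale: float = 1.0) -> list[LabProfile]:
    """The 10 canonical lab profiles (sizes 15..41, total 617).

    ``size_scale`` shrinks every lab proportionally (minimum 2 subjects) for
    reduced-scale runs.
    """
    profiles = []
    for lab, n in zip(range(1, 11), CANONICAL_LAB_SIZES):
        a, w, th, pi = _LAB_MEANS[lab]
        profiles.append(
            LabProfile(
                lab_id=lab,
                n_subjects=max(2, round(n * size_scale)),
                native_T=_LAB_T[lab],
                hyperpriors={
                    "learn_rate": (a, _SPREADS["learn_rate"]),
                    "loss_weight": (w, _SPREADS["loss_weight"]),
                    "consistency": (th, _SPREADS["consistency"]),
                    "perseverance": (pi, _SPREADS["perseverance"]),
                },
            )
        )
    return profiles


def draw_agent_params(profile: LabProfile, rng: np.random.Generator) -> AgentParams:
    def draw(name: str, lo: float, hi: float) -> float:
        mean, spread = profile.hyperpriors[name]
        return float(np.clip(rng.normal(mean, spread), lo, hi))

    return AgentParams(
        learn_rate=draw("learn_rate", 0.0, 1.0),
        loss_weight=draw("loss_weight", 0.0, 1.0),
        consistency=draw("consistency", 0.0, np.inf),
        perseverance=float(
            rng.normal(*profile.hyperpriors["perseverance"])
        ),
    )


def simulate_subject(
    params: AgentParams,
    scheme: PayoffScheme,
    T: int,
    seed: int,
    subject_id: str = "agent",
    lab_id: int = 0,
) -> ChoiceSequence:
    """Play ``T`` trials with a delta-rule expectancy agent (seeded)."""
    rng = np.random.default_rng(seed)
    E = np.zeros(N_CHOICES)
    draws = np.zeros(N_CHOICES, dtype=int)
    prev = -1
    choices = np.empty(T, dtype=np.int64)
    rewards = np.empty(T)
    losses = np.empty(T)
    for t in range(T):
        logits = params.consistency * E
        if prev >= 0:
            logits = logits.copy()
            logits[prev] += params.perseverance
        p = np.exp(logits - logits.max())
        p /= p.sum()
        d = int(rng.choice(N_CHOICES, p=p))
        r, l = payoff(scheme, d + 1, draws[d])
        draws[d] += 1
        u = (1 - params.loss_weight) * r - params.loss_weight * l
        E[d] += params.learn_rate * (u - E[d])
        prev = d
        choices[t], rewards[t], losses[t] = d + 1, r, l
    return ChoiceSequence(subject_id, lab_id, choices, rewards, losses)


def generate_pool(
    profiles: Sequence[LabProfile] | None = None, seed: int = 0
) -> list[LabDataset]:
    """Generate one synthetic many-labs pool.

    Agent parameters are drawn per subject from the lab's hyperpriors; every
    stochastic step derives from ``seed`` alone.
    """
    if profiles is None:
        profiles = canonical_profiles()
    lab_seeds = np.random.SeedSequence(seed).spawn(len(profiles))
    pool = []
    for profile, ss in zip(profiles, lab_seeds):
        scheme = build_scheme(profile.payoff_variant)
        rng = np.random.default_rng(ss)
        subj_seeds = ss.spawn(profile.n_subjects)
        records = []
        for i in range(profile.n_subjects):
            params = draw_agent_params(profile, rng)
            records.append(
                simulate_subject(
                    params,
                    scheme,
                    profile.native_T,
                    seed=int(subj_seeds[i].generate_state(1)[0] % 2**31),
                    subject_id=f"lab{profile.lab_id}_s{i+1}",
                    lab_id=profile.lab_id,
                )
            )
        pool.append(
            LabDataset(
                lab_id=profile.lab_id,
                records=records,
                native_T=profile.native_T,
                payoff_variant=profile.payoff_variant,
            )
        )
    return pool


def profiles_to_yaml(profiles: Sequence[LabProfile], path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            [
                {
                    "lab_id": p.lab_id,
                    "n_subjects": p.n_subjects,
                    "native_T": p.native_T,
                    "payoff_variant": p.payoff_variant,
                    "hyperpriors": {k: list(v) for k, v in p.hyperpriors.items()},
                }
                for p in profiles
            ]
        )
    )


def profiles_from_yaml(path: str | Path) -> list[LabProfile]:
    raw = yaml.safe_load(Path(path).read_text())
    return [
        LabProfile(
            lab_id=d["lab_id"],
            n_subjects=d["n_subjects"],
            native_T=d.get("native_T", 100),
            payoff_variant=d.get("payoff_variant", "traditional"),
            hyperpriors={k: tuple(v) for k, v in d["hyperpriors"].items()},
        )
        for d in raw
    ]
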