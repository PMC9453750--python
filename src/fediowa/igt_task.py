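"""The Iowa Gambling Task environment: payoff schemes and episode execution.

Four decks A-D.  Every draw pays a fixed reward (100 for A/B, 50 for C/D in
the traditional variant) and sometimes incurs a loss; losses follow a
deterministic cyclic 10-position schedule per deck, indexed by how many cards
have been drawn from that specific deck.  Decks A and B lose money in the long
run (net -250 per 10 draws), C and D gain (+250); A and C lose often in small
amounts, B and D rarely but heavily.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import yaml

from .data_model import ChoiceSequence, N_CHOICES, ValidationError

DECK_NAMES = ("A", "B", "C", "D")


@dataclass(frozen=True)
class PayoffScheme:
    reward_per_deck: tuple[float, float, float, float]
    loss_schedule: tuple[tuple[float, ...], ...]  # per deck, cyclic over 10 positions
    variant_label: str = "traditional"
    initial_endowment: float = 2000.0

    def net_ten_draw_payoff(self, deck: int) -> float:
        """Expected net payoff of 10 consecutive draws from deck 1..4."""
        d = deck - 1
        return 10 * self.reward_per_deck[d] - sum(self.loss_schedule[d])

    def loss_events_per_cycle(self, deck: int) -> int:
        return int(np.count_nonzero(self.loss_schedule[deck - 1]))


class SchemeRegistryError(KeyError):
    pass


# Canonical traditional schedules: deck A loses 5 times per 10 draws (1250
# total), B once (1250), C five times 50 (250 total), D once (250).
_TRADITIONAL_LOSSES = (
    (0, 0, 150, 0, 300, 0, 200, 0, 250, 350),  # A
    (0, 0, 0, 0, 0, 0, 0, 0, 1250, 0),         # B
    (0, 0, 50, 0, 50, 0, 50, 50, 50, 0),       # C
    (0, 0, 0, 0, 0, 0, 0, 0, 0, 250),          # D
)

# Variant with deck C's loss held constant across draws (25 every draw,
# preserving the 250-per-10 total).
_FIXED_C_LOSSES = (
    _TRADITIONAL_LOSSES[0],
    _TRADITIONAL_LOSSES[1],
    tuple([25.0] * 10),
    _TRADITIONAL_LOSSES[3],
)

_REGISTRY: dict[str, Callable[[], PayoffScheme]] = {}


def register_scheme(label: str, factory: Callable[[], PayoffScheme]) -> None:
    _REGISTRY[label] = factory


register_scheme(
    "traditional",
    lambda: PayoffScheme((100.0, 100.0, 50.0, 50.0), _TRADITIONAL_LOSSES, "traditional"),
)
register_scheme(
    "fixed_C",
    lambda: PayoffScheme((100.0, 100.0, 50.0, 50.0), _FIXED_C_LOSSES, "fixed_C"),
)


def build_scheme(variant_label: str = "traditional") -> PayoffScheme:
    """Look up a payoff scheme by variant label."""
    try:
        scheme = _REGISTRY[variant_label]()
    except KeyError:
        raise SchemeRegistryError(
            f"unknown payoff variant {variant_label!r}; known: {sorted(_REGISTRY)}"
        ) from None
    _check_invariants(scheme)
    return scheme


def _check_invariants(s: PayoffScheme) -> None:
    for deck in (1, 2):
        if s.net_ten_draw_payoff(deck) >= 0:
            raise ValidationError(f"deck {DECK_NAMES[deck-1]} must be net-negative")
    for deck in (3, 4):
        if s.net_ten_draw_payoff(deck) <= 0:
            raise ValidationError(f"deck {DECK_NAMES[deck-1]} must be net-positive")
    if not (
        s.loss_events_per_cycle(1) > s.loss_events_per_cycle(2)
        and s.loss_events_per_cycle(3) > s.loss_events_per_cycle(4)
    ):
        raise ValidationError("A/C must lose more frequently than B/D")


def payoff(scheme: PayoffScheme, deck: int, draw_index: int) -> tuple[float, float]:
    """Deterministic (reward, loss) for the ``draw_index``-th draw (0-based,
    counting prior draws from that specific deck)."""
    if not 1 <= deck <= N_CHOICES:
        raise ValidationError(f"deck must be 1..{N_CHOICES}, got {deck}")
    d = deck - 1
    return scheme.reward_per_deck[d], scheme.loss_schedule[d][draw_index % 10]


def run_episode(
    policy: Callable[[list[tuple[int, float, float]]], int],
    scheme: PayoffScheme,
    T: int,
    seed: int = 0,
    subject_id: str = "episode",
    lab_id: int = 0,
) -> ChoiceSequence:
    """Play ``T`` trials of the task under ``policy``.

    ``policy(history)`` receives the list of past (choice, reward, loss)
    triples and returns the next deck in 1..4; stochastic policies should
    close over their own seeded generator.  Per-deck draw counters advance
    independently, like physical decks.
    """
    if T < 1:
        raise ValidationError(f"T must be >= 1, got {T}")
    draws = [0] * N_CHOICES
    history: list[tuple[int, float, float]] = []
    choices, rewards, losses = [], [], []
    for _ in range(T):
        deck = int(policy(history))
        if not 1 <= deck <= N_CHOICES:
            raise ValidationError(f"policy returned invalid deck {deck}")
        r, l = payoff(scheme, deck, draws[deck - 1])
        draws[deck - 1] += 1
        history.append((deck, r, l))
        choices.append(deck)
        rewards.append(r)
        losses.append(l)
    return ChoiceSequence(subject_id, lab_id, np.array(choices), np.array(rewards), np.array(losses))


def wallet_trace(scheme: PayoffScheme, record: ChoiceSequence) -> np.ndarray:
    """Running money total after each trial, starting from the endowment."""
    return scheme.initial_endowment + np.cumsum(record.rewards - record.losses)


def scheme_to_yaml(scheme: PayoffScheme, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {
                "variant_label": scheme.variant_label,
                "initial_endowment": scheme.initial_endowment,
                "reward_per_deck": list(scheme.reward_per_deck),
                "loss_schedule": [list(row) for row in scheme.loss_schedule],
            }
        )
    )


def scheme_from_yaml(path: str | Path) -> PayoffScheme:
    d = yaml.safe_load(Path(path).read_text())
    return PayoffScheme(
        tuple(d["reward_per_deck"]),
        tuple(tuple(row) for row in d["loss_schedule"]),
        d.get("variant_label", "custom"),
        d.get("initial_endowment", 2000.0),
    )
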