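"""Four collaboration paradigms over the GRU choice model.

CL  — centralized: pool every lab's training subjects, one fit.
IL  — incremental: labs train sequentially, 250 epochs each, parameters
      handed to the next lab; order matters.
CIL — cyclic incremental: 5 cycles of 50 epochs per lab.
FL  — federated: 5 rounds of 50 local epochs in parallel, then size-weighted
      (FedAvg) parameter averaging at a central server.

All four consume every training sample exactly ``total_epoch_budget`` (250)
times — the equal-exposure budget that makes the paradigms comparable — which
the returned exposure counters certify.  Distributed paradigms use each lab's
full training set as the batch; CL uses minibatches of 50.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data_model import LabDataset, ValidationError, encode_lab
from .gru_choice_model import (
    FitResult,
    ModelParams,
    PARAM_NAMES,
    TrainSchedule,
    dataset_loss,
    fit,
    init_params,
)
from .data_model import stack_encoded

PARADIGMS = ("CL", "IL", "CIL", "FL")
ORDERINGS = ("ascending", "descending", "random")


@dataclass
class TrainPlan:
    paradigm: str = "CL"
    total_epoch_budget: int = 250
    epochs_per_visit: int | None = None  # IL: 250; CIL/FL: 50; derived if None
    cycles: int = 5        # CIL
    rounds: int = 5        # FL
    ordering: str = "ascending"
    batch_size: int | None = 50  # CL minibatch; distributed paradigms use full lab
    learn_rate: float = 0.02
    N_u: int = 10
    scale: float = 100.0
    seed: int = 0
    sync_prob: float = 1.0  # FL: probability a client adopts the global model
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ValidationError(f"paradigm must be one of {PARADIGMS}")
        if self.ordering not in ORDERINGS:
            raise ValidationError(f"ordering must be one of {ORDERINGS}")
        if self.epochs_per_visit is None:
            if self.paradigm in ("CL", "IL"):
                self.epochs_per_visit = self.total_epoch_budget
            elif self.paradigm == "CIL":
                self.epochs_per_visit = self.total_epoch_budget // self.cycles
            else:
                self.epochs_per_visit = self.total_epoch_budget // self.rounds
        if self.paradigm == "CIL" and self.cycles * self.epochs_per_visit != self.total_epoch_budget:
            raise ValidationError("CIL: cycles * epochs_per_visit must equal the budget")
        if self.paradigm == "FL" and self.rounds * self.epochs_per_visit != self.total_epoch_budget:
            raise ValidationError("FL: rounds * epochs_per_visit must equal the budget")


@dataclass
class ClientUpdate:
    lab_id: int
    params: ModelParams
    n_train: int

    def __post_init__(self) -> None:
        if self.n_train <= 0:
            raise ValidationError("n_train must be > 0")


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


def _merge_exposures(into: dict[str, int], update: dict[str, int]) -> None:
    for k, v in update.items():
        into[k] = into.get(k, 0) + v


def order_labs(
    train_sets: Sequence[LabDataset], strategy: str = "ascending", seed: int = 0
) -> list[LabDataset]:
    """Order labs by training-set size (ties by lab id) or by seeded shuffle."""
    if len(train_sets) == 0:
        raise ValidationError("no labs to order")
    if strategy == "ascending":
        return sorted(train_sets, key=lambda d: (len(d), d.lab_id))
    if strategy == "descending":
        return sorted(train_sets, key=lambda d: (-len(d), d.lab_id))
    if strategy == "random":
        rng = np.random.default_rng(seed)
        return [train_sets[i] for i in rng.permutation(len(train_sets))]
    raise ValidationError(f"unknown ordering strategy {strategy!r}")


def _lab_encoded(ds: LabDataset, scale: float):
    enc = encode_lab(ds, scale)
    ids = [r.subject_id for r in ds.records]
    return enc, ids


def average_params(updates: Sequence[ClientUpdate]) -> ModelParams:
    """Size-weighted (FedAvg) element-wise average over every array in Theta."""
    if len(updates) == 0:
        raise ValidationError("no client updates to aggregate")
    total = sum(u.n_train for u in updates)
    out = updates[0].params.copy()
    for name in PARAM_NAMES:
        acc = np.zeros_like(getattr(out, name))
        for u in updates:
            acc += (u.n_train / total) * getattr(u.params, name)
        getattr(out, name)[...] = acc
    return out


def train_centralized(train_sets: Sequence[LabDataset], plan: TrainPlan) -> FitResult:
    """Pool all labs' subjects and run a single fit."""
    assert plan.paradigm == "CL"
    encoded, ids = [], []
    for ds in train_sets:
        e, i = _lab_encoded(ds, plan.scale)
        encoded.extend(e)
        ids.extend(i)
    if not encoded:
        raise ValidationError("empty pooled training set")
    init_seed, fit_seed = _spawn_seeds(plan.seed, 2)
    params = init_params(plan.N_u, seed=init_seed)
    return fit(
        params,
        encoded,
        TrainSchedule(
            epochs=plan.total_epoch_budget,
            batch_size=plan.batch_size,
            learn_rate=plan.learn_rate,
            seed=fit_seed,
            optimizer=plan.optimizer,
        ),
        subject_ids=ids,
    )


def train_incremental(train_sets: Sequence[LabDataset], plan: TrainPlan) -> FitResult:
    """Sequential site-by-site training with parameter hand-off (one pass)."""
    assert plan.paradigm == "IL"
    ordered = order_labs(train_sets, plan.ordering, plan.seed)
    init_seed, *lab_seeds = _spawn_seeds(plan.seed, 1 + len(ordered))
    params = init_params(plan.N_u, seed=init_seed)
    hist: list[float] = []
    exposures: dict[str, int] = {}
    for ds, s in zip(ordered, lab_seeds):
        enc, ids = _lab_encoded(ds, plan.scale)
        res = fit(
            params,
            enc,
            TrainSchedule(
                epochs=plan.epochs_per_visit,
                batch_size=None,  # full lab training set
                learn_rate=plan.learn_rate,
                seed=s,
                optimizer=plan.optimizer,
            ),
            subject_ids=ids,
        )
        params = res.params
        hist.extend(res.train_loss_history)
        _merge_exposures(exposures, res.exposures)
    return FitResult(params, hist, None, len(hist), plan.seed, exposures)


def train_cyclic(train_sets: Sequence[LabDataset], plan: TrainPlan) -> FitResult:
    """Incremental training repeated over ``cycles`` shorter passes."""
    assert plan.paradigm == "CIL"
    ordered = order_labs(train_sets, plan.ordering, plan.seed)
    seeds = _spawn_seeds(plan.seed, 1 + plan.cycles * len(ordered))
    params = init_params(plan.N_u, seed=seeds[0])
    hist: list[float] = []
    exposures: dict[str, int] = {}
    si = 1
    for _cycle in range(plan.cycles):
        for ds in ordered:
            enc, ids = _lab_encoded(ds, plan.scale)
            res = fit(
                params,
                enc,
                TrainSchedule(
                    epochs=plan.epochs_per_visit,
                    batch_size=None,
                    learn_rate=plan.learn_rate,
                    seed=seeds[si],
                    optimizer=plan.optimizer,
                ),
                subject_ids=ids,
            )
            si += 1
            params = res.params
            hist.extend(res.train_loss_history)
            _merge_exposures(exposures, res.exposures)
    return FitResult(params, hist, None, len(hist), plan.seed, exposures)


def federated_round(
    global_params: ModelParams,
    train_sets: Sequence[LabDataset],
    epochs_per_visit: int = 50,
    learn_rate: float = 0.02,
    seed: int = 0,
    scale: float = 100.0,
    optimizer: str = "adam",
) -> tuple[ModelParams, list[ClientUpdate], dict[str, int]]:
    """One federated round: parallel local fits from the global model, then
    size-weighted aggregation.  Client Adam state is fresh each round (only
    parameters travel)."""
    if len(train_sets) == 0:
        raise ValidationError("federated round needs at least one client")
    seeds = _spawn_seeds(seed, len(train_sets))
    updates: list[ClientUpdate] = []
    exposures: dict[str, int] = {}
    for ds, s in zip(train_sets, seeds):
        enc, ids = _lab_encoded(ds, scale)
        res = fit(
            global_params,
            enc,
            TrainSchedule(
                epochs=epochs_per_visit,
                batch_size=None,
                learn_rate=learn_rate,
                seed=s,
                optimizer=optimizer,
            ),
            subject_ids=ids,
        )
        updates.append(ClientUpdate(ds.lab_id, res.params, len(ds)))
        _merge_exposures(exposures, res.exposures)
    return average_params(updates), updates, exposures


def train_federated(train_sets: Sequence[LabDataset], plan: TrainPlan) -> FitResult:
    """``rounds`` federated rounds of ``epochs_per_visit`` local epochs."""
    assert plan.paradigm == "FL"
    init_seed, sync_seed, *round_seeds = _spawn_seeds(plan.seed, 2 + plan.rounds)
    global_params = init_params(plan.N_u, seed=init_seed)
    client_params: list[ModelParams] = [global_params.copy() for _ in train_sets]
    sync_rng = np.random.default_rng(sync_seed)

    Xs, Ys = [], []
    for ds in train_sets:
        enc, _ = _lab_encoded(ds, plan.scale)
        X, Y = stack_encoded(enc)
        Xs.append(X)
        Ys.append(Y)
    pooled_X, pooled_Y = np.concatenate(Xs), np.concatenate(Ys)

    hist: list[float] = []
    exposures: dict[str, int] = {}
    for r in range(plan.rounds):
        seeds = _spawn_seeds(round_seeds[r], len(train_sets))
        updates = []
        for ds, start, s in zip(train_sets, client_params, seeds):
            enc, ids = _lab_encoded(ds, plan.scale)
            res = fit(
                start,
                enc,
                TrainSchedule(
                    epochs=plan.epochs_per_visit,
                    batch_size=None,
                    learn_rate=plan.learn_rate,
                    seed=s,
                    optimizer=plan.optimizer,
                ),
                subject_ids=ids,
            )
            updates.append(ClientUpdate(ds.lab_id, res.params, len(ds)))
            _merge_exposures(exposures, res.exposures)
        global_params = average_params(updates)
        client_params = [
            global_params.copy() if sync_rng.random() < plan.sync_prob else u.params
            for u in updates
        ]
        hist.append(dataset_loss(global_params, pooled_X, pooled_Y))
    return FitResult(global_params, hist, None, plan.rounds, plan.seed, exposures)


def train(train_sets: Sequence[LabDataset], plan: TrainPlan) -> FitResult:
    """Dispatch to the paradigm named in the plan."""
    return {
        "CL": train_centralized,
        "IL": train_incremental,
        "CIL": train_cyclic,
        "FL": train_federated,
    }[plan.paradigm](train_sets, plan)
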