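"""Prediction-accuracy evaluation and cross-validated hyperparameter tuning.

Accuracy is next-choice accuracy: the model's argmax deck at each trial versus
the deck the subject actually chose, pooled over all scored trials of all
subjects in a test set (chance level 25%).  The accuracy matrix crosses models
(rows) with the 10 lab test sets (columns) plus their mean (AVG).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import LabDataset, ValidationError, encode_lab, stack_encoded
from .gru_choice_model import (
    ModelParams,
    TrainSchedule,
    fit,
    init_params,
    predict_probs_batch,
)


def accuracy(params: ModelParams, test_set: LabDataset, scale: float = 100.0) -> float:
    """Trial-pooled next-choice accuracy on one lab's test set.

    Argmax ties break toward the lowest deck index.
    """
    if len(test_set) == 0:
        raise ValidationError(f"lab {test_set.lab_id}: empty test set")
    X, Y = stack_encoded(encode_lab(test_set, scale))
    P = predict_probs_batch(params, X)
    hits = (P.argmax(axis=2) == Y.argmax(axis=2)).sum()
    return float(hits / Y[..., 0].size)


def accuracy_per_subject(
    params: ModelParams, test_set: LabDataset, scale: float = 100.0
) -> np.ndarray:
    """Per-subject accuracies (secondary, subject-averaged view)."""
    X, Y = stack_encoded(encode_lab(test_set, scale))
    P = predict_probs_batch(params, X)
    return (P.argmax(axis=2) == Y.argmax(axis=2)).mean(axis=1)


@dataclass
class AccuracyMatrix:
    table: pd.DataFrame  # rows: model labels; columns: lab1..labN, AVG

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="model")

    @classmethod
    def from_csv(cls, path: str | Path) -> "AccuracyMatrix":
        return cls(pd.read_csv(path, index_col="model"))


def accuracy_matrix(
    models: Mapping[str, ModelParams],
    test_sets: Sequence[LabDataset],
    scale: float = 100.0,
) -> AccuracyMatrix:
    """Cross every model with every lab test set; AVG is the row mean."""
    cols = [f"lab{ds.lab_id}" for ds in test_sets]
    rows = {}
    for label, params in models.items():
        cells = [accuracy(params, ds, scale) for ds in test_sets]
        rows[label] = cells + [float(np.mean(cells))]
    return AccuracyMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=cols + ["AVG"]))


@dataclass
class CrossvalResult:
    best_N_u: int
    best_epochs: int
    best_loss: float  # mean per-trial validation loss at the optimum
    fold_losses: pd.DataFrame  # columns: N_u, fold, epoch, train_loss, val_loss (per-trial)


def crossval_tune(
    lab_train_set: LabDataset,
    grid: Mapping[str, Sequence[int]],
    k: int = 10,
    seed: int = 0,
    learn_rate: float = 0.02,
    scale: float = 100.0,
    batch_size: int | None = None,
) -> CrossvalResult:
    """Subject-level k-fold CV over a (hidden cells x epochs) grid.

    For each hidden-unit candidate each fold is trained once to the largest
    epoch candidate, recording per-epoch losses, so every epoch candidate is
    read off the same training runs.  Validation loss is per-trial-averaged so
    folds of unequal size are comparable.
    """
    n = len(lab_train_set)
    if n == 0:
        raise ValidationError("cannot cross-validate an empty lab")
    if n < k:
        warnings.warn(f"lab has {n} subjects < k={k}; reducing k to {n}")
        k = n
    nu_cands = list(grid.get("N_u", [10]))
    epoch_cands = sorted(grid.get("epochs", [250]))
    max_epochs = epoch_cands[-1]

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    encoded = encode_lab(lab_train_set, scale)
    T = encoded[0].inputs.shape[0]

    records = []
    for N_u in nu_cands:
        fold_seeds = np.random.SeedSequence([seed, N_u]).spawn(k)
        for f, val_idx in enumerate(folds):
            train_idx = np.setdiff1d(perm, val_idx)
            tr = [encoded[i] for i in train_idx]
            va = [encoded[i] for i in val_idx]
            s1, s2 = (int(s.generate_state(1)[0] % 2**31) for s in fold_seeds[f].spawn(2))
            res = fit(
                init_params(N_u, seed=s1),
                tr,
                TrainSchedule(
                    epochs=max_epochs, batch_size=batch_size, learn_rate=learn_rate, seed=s2
                ),
                val_batch=va,
            )
            for e in range(max_epochs):
                records.append(
                    {
                        "N_u": N_u,
                        "fold": f,
                        "epoch": e + 1,
                        "train_loss": res.train_loss_history[e] / (len(tr) * T),
                        "val_loss": res.val_loss_history[e] / (len(va) * T),
                    }
                )
    df = pd.DataFrame.from_records(records)
    mean_val = (
        df[df["epoch"].isin(epoch_cands)]
        .groupby(["N_u", "epoch"])["val_loss"]
        .mean()
        .reset_index()
    )
    best = mean_val.loc[mean_val["val_loss"].idxmin()]
    return CrossvalResult(
        best_N_u=int(best["N_u"]),
        best_epochs=int(best["epoch"]),
        best_loss=float(best["val_loss"]),
        fold_losses=df,
    )
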