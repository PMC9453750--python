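"""Domain types and I/O for many-labs Iowa Gambling Task choice data.

The canonical pool groups 617 subjects into 10 laboratories; each subject is a
trial-by-trial sequence of deck choices with the reward and loss received on
every trial.  Decks are labelled A-D externally (1-4 in files); internally we
keep the 1-4 convention in ``ChoiceSequence`` and convert to 0-based indices
only at encoding time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Number of deck options in the task.
N_CHOICES = 4

#: Published per-lab subject counts of the canonical 10-study pool.
CANONICAL_LAB_SIZES = (15, 162, 19, 40, 70, 25, 153, 35, 57, 41)

#: Trial counts present in the canonical pool.
CANONICAL_TRIAL_COUNTS = (95, 100, 150)


class FormatError(ValueError):
    """Structural mismatch between the wide input tables."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass
class ChoiceSequence:
    """One subject's aligned per-trial (choice, reward, loss) vectors.

    ``losses`` stores magnitudes (nonnegative); the sign convention is that a
    loss is applied negatively to the subject's wallet.
    """

    subject_id: str
    lab_id: int
    choices: np.ndarray
    rewards: np.ndarray
    losses: np.ndarray

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=np.int64)
        self.rewards = np.asarray(self.rewards, dtype=np.float64)
        self.losses = np.asarray(self.losses, dtype=np.float64)
        if not (len(self.choices) == len(self.rewards) == len(self.losses)):
            raise ValidationError(
                f"subject {self.subject_id}: choices/rewards/losses lengths differ "
                f"({len(self.choices)}/{len(self.rewards)}/{len(self.losses)})"
            )
        if self.choices.size and (self.choices.min() < 1 or self.choices.max() > N_CHOICES):
            raise ValidationError(
                f"subject {self.subject_id}: choice outside 1..{N_CHOICES}"
            )
        if (self.rewards < 0).any():
            raise ValidationError(f"subject {self.subject_id}: negative reward")
        if (self.losses < 0).any():
            raise ValidationError(f"subject {self.subject_id}: negative loss magnitude")

    @property
    def T(self) -> int:
        return len(self.choices)

    def truncated(self, T_min: int) -> "ChoiceSequence":
        if self.T < T_min:
            raise ValidationError(
                f"subject {self.subject_id}: T={self.T} shorter than {T_min}"
            )
        return ChoiceSequence(
            self.subject_id,
            self.lab_id,
            self.choices[:T_min].copy(),
            self.rewards[:T_min].copy(),
            self.losses[:T_min].copy(),
        )


@dataclass
class LabDataset:
    """All subjects of one laboratory."""

    lab_id: int
    records: list[ChoiceSequence]
    native_T: int | None = None
    payoff_variant: str = "traditional"

    def __post_init__(self) -> None:
        for r in self.records:
            if r.lab_id != self.lab_id:
                raise ValidationError(
                    f"record {r.subject_id} has lab {r.lab_id}, dataset is lab {self.lab_id}"
                )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class EncodedSequence:
    """Model-ready representation of one subject.

    ``inputs`` has shape (T, N_c + 2): one-hot of the previous choice, then
    previous reward and previous loss (both divided by the scale).  The first
    row is the all-zeros start token.  ``targets`` has shape (T, N_c), one-hot
    of the current trial's choice; every trial is a scored target.
    """

    inputs: np.ndarray
    targets: np.ndarray

    @property
    def n_predicted(self) -> int:
        return self.targets.shape[0]


# ---------------------------------------------------------------------------
# readers / writers


def _read_wide(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, header=None)
    # tolerate a header row of non-numeric labels
    try:
        return df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError):
        return pd.read_csv(path).to_numpy(dtype=np.float64)


def read_manylabs_csv(
    choice_path: str | Path,
    win_path: str | Path,
    loss_path: str | Path,
    index_path: str | Path,
) -> list[LabDataset]:
    """Parse the many-labs wide-CSV layout into per-lab datasets.

    The three wide tables hold one row per subject and one column per trial
    (choices 1-4, win amounts, loss amounts in either sign dialect); the index
    CSV maps row order to ``subject`` and ``lab`` labels.  Loss cells are
    stored as magnitudes regardless of the file's sign convention.
    """
    choices = _read_wide(choice_path)
    wins = _read_wide(win_path)
    losses = _read_wide(loss_path)
    if not (choices.shape == wins.shape == losses.shape):
        raise FormatError(
            f"wide tables disagree in shape: choices {choices.shape}, "
            f"wins {wins.shape}, losses {losses.shape}"
        )
    index = pd.read_csv(index_path)
    if not {"subject", "lab"}.issubset(index.columns):
        raise FormatError("index CSV must have 'subject' and 'lab' columns")
    if len(index) != choices.shape[0]:
        raise FormatError(
            f"index has {len(index)} rows but tables have {choices.shape[0]}"
        )

    by_lab: dict[int, list[ChoiceSequence]] = {}
    for i, row in enumerate(index.itertuples(index=False)):
        c = choices[i]
        if not np.all((c >= 1) & (c <= N_CHOICES) & (c == np.round(c))):
            raise ValidationError(f"row {i}: choice value outside 1..{N_CHOICES}")
        rec = ChoiceSequence(
            subject_id=str(row.subject),
            lab_id=int(row.lab),
            choices=c.astype(np.int64),
            rewards=np.abs(wins[i]),
            losses=np.abs(losses[i]),
        )
        by_lab.setdefault(rec.lab_id, []).append(rec)
    return [
        LabDataset(lab_id=lab, records=recs, native_T=recs[0].T)
        for lab, recs in sorted(by_lab.items())
    ]


def write_tidy_csv(pool: Sequence[LabDataset], path: str | Path) -> None:
    """Write the pool as tidy CSV: subject, lab, trial, choice, reward, loss."""
    frames = []
    for ds in pool:
        for rec in ds.records:
            frames.append(
                pd.DataFrame(
                    {
                        "subject": rec.subject_id,
                        "lab": rec.lab_id,
                        "trial": np.arange(1, rec.T + 1),
                        "choice": rec.choices,
                        "reward": rec.rewards,
                        "loss": rec.losses,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tidy_csv(path: str | Path) -> list[LabDataset]:
    """Inverse of :func:`write_tidy_csv`."""
    df = pd.read_csv(path)
    by_lab: dict[int, list[ChoiceSequence]] = {}
    for (lab, subj), g in df.groupby(["lab", "subject"], sort=True):
        g = g.sort_values("trial")
        rec = ChoiceSequence(
            subject_id=str(subj),
            lab_id=int(lab),
            choices=g["choice"].to_numpy(),
            rewards=g["reward"].to_numpy(),
            losses=g["loss"].to_numpy(),
        )
        by_lab.setdefault(int(lab), []).append(rec)
    return [
        LabDataset(lab_id=lab, records=recs, native_T=recs[0].T)
        for lab, recs in sorted(by_lab.items())
    ]


def write_pool_metadata(pool: Sequence[LabDataset], path: str | Path, **extra) -> None:
    meta = {
        "n_labs": len(pool),
        "lab_sizes": {ds.lab_id: len(ds) for ds in pool},
        "total_subjects": sum(len(ds) for ds in pool),
        "native_T": {ds.lab_id: ds.native_T for ds in pool},
        **extra,
    }
    Path(path).write_text(json.dumps(meta, indent=2, default=str))


# ---------------------------------------------------------------------------
# transforms


def truncate_pool(pool: Sequence[LabDataset], T_min: int = 95) -> list[LabDataset]:
    """Truncate every record to its first ``T_min`` trials.

    All sequences must be at least ``T_min`` long; the pool's mixed trial
    counts {95, 100, 150} are aligned to the shortest.
    """
    if T_min < 1:
        raise ValidationError(f"T_min must be >= 1, got {T_min}")
    return [
        LabDataset(
            lab_id=ds.lab_id,
            records=[r.truncated(T_min) for r in ds.records],
            native_T=T_min,
            payoff_variant=ds.payoff_variant,
        )
        for ds in pool
    ]


def split_lab(
    dataset: LabDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[LabDataset, LabDataset]:
    """Subject-level train/test split of one lab.

    Training size is ``floor(train_fraction * n)``; subjects never appear in
    both parts, and the permutation is deterministic under the seed.
    """
    n = len(dataset)
    if n == 0:
        raise ValidationError(f"lab {dataset.lab_id}: cannot split empty dataset")
    if not 0 < train_fraction < 1:
        raise ValidationError(f"train_fraction must be in (0,1), got {train_fraction}")
    n_train = math.floor(train_fraction * n)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx, test_idx = sorted(perm[:n_train]), sorted(perm[n_train:])
    make = lambda idx: LabDataset(
        lab_id=dataset.lab_id,
        records=[dataset.records[i] for i in idx],
        native_T=dataset.native_T,
        payoff_variant=dataset.payoff_variant,
    )
    return make(train_idx), make(test_idx)


def split_pool(
    pool: Sequence[LabDataset], train_fraction: float = 0.8, seed: int = 0
) -> tuple[list[LabDataset], list[LabDataset]]:
    """Apply :func:`split_lab` per lab with per-lab derived seeds."""
    seeds = np.random.SeedSequence(seed).spawn(len(pool))
    trains, tests = [], []
    for ds, ss in zip(pool, seeds):
        tr, te = split_lab(ds, train_fraction, seed=int(ss.generate_state(1)[0] % 2**31))
        trains.append(tr)
        tests.append(te)
    return trains, tests


def encode_sequence(record: ChoiceSequence, scale: float = 100.0) -> EncodedSequence:
    """Encode one subject for the sequence model.

    The input at step t carries trial t-1's one-hot choice plus its reward and
    loss divided by ``scale``; step 1 is the all-zeros start token.  The target
    at step t is trial t's choice, one-hot.
    """
    T = record.T
    x = np.zeros((T, N_CHOICES + 2), dtype=np.float64)
    y = np.zeros((T, N_CHOICES), dtype=np.float64)
    idx = record.choices - 1
    y[np.arange(T), idx] = 1.0
    if T > 1:
        x[np.arange(1, T), idx[:-1]] = 1.0
        x[1:, N_CHOICES] = record.rewards[:-1] / scale
        x[1:, N_CHOICES + 1] = record.losses[:-1] / scale
    return EncodedSequence(inputs=x, targets=y)


def decode_choices(encoded: EncodedSequence) -> np.ndarray:
    """Recover the 1-based choice sequence from the targets."""
    return np.argmax(encoded.targets, axis=1) + 1


def encode_lab(dataset: LabDataset, scale: float = 100.0) -> list[EncodedSequence]:
    return [encode_sequence(r, scale) for r in dataset.records]


def stack_encoded(encoded: Sequence[EncodedSequence]) -> tuple[np.ndarray, np.ndarray]:
    """Stack equal-length encoded sequences into (S, T, N_c+2) and (S, T, N_c)."""
    Ts = {e.inputs.shape[0] for e in encoded}
    if len(Ts) > 1:
        raise ValidationError(f"cannot stack sequences of differing lengths {sorted(Ts)}")
    return (
        np.stack([e.inputs for e in encoded]),
        np.stack([e.targets for e in encoded]),
    )
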