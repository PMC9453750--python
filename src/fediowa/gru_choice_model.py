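"""Trial-by-trial GRU choice model: gated recurrent layer + softmax head.

The recurrence, for input x_t (one-hot previous choice plus scaled previous
reward and loss) and hidden state h_{t-1}:

    z_t  = sigmoid(W_z x_t + U_z h_{t-1} + b_z)            (update gate)
    r_t  = sigmoid(W_r x_t + U_r h_{t-1} + b_r)            (reset gate)
    h'_t = tanh(W x_t + b_hW + r_t * (U h_{t-1} + b_hU))   (candidate state)
    h_t  = z_t * h_{t-1} + (1 - z_t) * h'_t

Note the gate orientation: the update gate z multiplies the OLD state — an
exact relabeling z <-> (1-z) of the more common convention, kept deliberately.
The softmax head has no bias: logits_t = h_t V, and the training objective is
the categorical cross-entropy summed over subjects and trials,

    Loss = - sum_s sum_t y_st . log(yhat_st).

Forward, backward (full backpropagation through time) and Adam are implemented
directly over numpy arrays so that every gradient is checkable against finite
differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_model import EncodedSequence, N_CHOICES, ValidationError, stack_encoded

PARAM_NAMES = ("V", "W_z", "W_r", "W", "U_z", "U_r", "U", "b_z", "b_r", "b_hW", "b_hU")

#: floor applied inside the log of the cross-entropy
PROB_FLOOR = 1e-12


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class ModelParams:
    """The full parameter set Theta of the model."""

    W_z: np.ndarray
    W_r: np.ndarray
    W: np.ndarray
    U_z: np.ndarray
    U_r: np.ndarray
    U: np.ndarray
    b_z: np.ndarray
    b_r: np.ndarray
    b_hW: np.ndarray
    b_hU: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        N_u, n_in = self.W_z.shape
        if n_in < 3:
            raise ValidationError("input dimension must be at least N_c + 2 with N_c >= 1")
        for name in ("W_r", "W"):
            if getattr(self, name).shape != (N_u, n_in):
                raise ValidationError(f"{name} must have shape {(N_u, n_in)}")
        for name in ("U_z", "U_r", "U"):
            if getattr(self, name).shape != (N_u, N_u):
                raise ValidationError(f"{name} must have shape {(N_u, N_u)}")
        for name in ("b_z", "b_r", "b_hW", "b_hU"):
            if getattr(self, name).shape != (N_u,):
                raise ValidationError(f"{name} must have shape {(N_u,)}")
        if self.V.shape != (N_u, n_in - 2):
            raise ValidationError(f"V must have shape {(N_u, n_in - 2)}")

    @property
    def N_u(self) -> int:
        return self.W_z.shape[0]

    @property
    def N_c(self) -> int:
        return self.V.shape[1]

    def copy(self) -> "ModelParams":
        return ModelParams(**{n: getattr(self, n).copy() for n in PARAM_NAMES})

    def arrays(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in PARAM_NAMES}

    def save(self, path: str | Path) -> None:
        """Flat named-array archive plus a JSON shape manifest."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.arrays())
        manifest = {n: list(getattr(self, n).shape) for n in PARAM_NAMES}
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        with np.load(Path(path).with_suffix(".npz")) as z:
            return cls(**{n: z[n] for n in PARAM_NAMES})


@dataclass
class FitResult:
    params: ModelParams
    train_loss_history: list[float]
    val_loss_history: list[float] | None
    epochs_run: int
    seed: int
    exposures: dict[str, int] = field(default_factory=dict)


@dataclass
class TrainSchedule:
    epochs: int = 250
    batch_size: int | None = 50  # None = full batch
    learn_rate: float = 0.02
    seed: int = 0
    optimizer: str = "adam"  # "adam" | "sgd"


def init_params(N_u: int = 10, N_c: int = N_CHOICES, seed: int = 0) -> ModelParams:
    """Uniform(-1/sqrt(N_u), 1/sqrt(N_u)) weights, zero biases; seeded."""
    if N_u < 1:
        raise ValidationError(f"N_u must be >= 1, got {N_u}")
    rng = np.random.default_rng(seed)
    s = 1.0 / np.sqrt(N_u)
    n_in = N_c + 2
    u = lambda *shape: rng.uniform(-s, s, shape)
    return ModelParams(
        W_z=u(N_u, n_in), W_r=u(N_u, n_in), W=u(N_u, n_in),
        U_z=u(N_u, N_u), U_r=u(N_u, N_u), U=u(N_u, N_u),
        b_z=np.zeros(N_u), b_r=np.zeros(N_u), b_hW=np.zeros(N_u), b_hU=np.zeros(N_u),
        V=u(N_u, N_c),
    )


def zero_params(N_u: int = 10, N_c: int = N_CHOICES) -> ModelParams:
    n_in = N_c + 2
    z = np.zeros
    return ModelParams(
        W_z=z((N_u, n_in)), W_r=z((N_u, n_in)), W=z((N_u, n_in)),
        U_z=z((N_u, N_u)), U_r=z((N_u, N_u)), U=z((N_u, N_u)),
        b_z=z(N_u), b_r=z(N_u), b_hW=z(N_u), b_hU=z(N_u),
        V=z((N_u, N_c)),
    )


# ---------------------------------------------------------------------------
# forward


def gru_step(params: ModelParams, x_t: np.ndarray, h_prev: np.ndarray) -> np.ndarray:
    """One recurrence step for a single vector input."""
    x_t = np.asarray(x_t, dtype=np.float64)
    h_prev = np.asarray(h_prev, dtype=np.float64)
    if x_t.shape != (params.N_c + 2,):
        raise ValidationError(f"x_t must have shape {(params.N_c + 2,)}, got {x_t.shape}")
    if h_prev.shape != (params.N_u,):
        raise ValidationError(f"h_prev must have shape {(params.N_u,)}, got {h_prev.shape}")
    z = _sigmoid(params.W_z @ x_t + params.U_z @ h_prev + params.b_z)
    r = _sigmoid(params.W_r @ x_t + params.U_r @ h_prev + params.b_r)
    hbar = np.tanh(params.W @ x_t + params.b_hW + r * (params.U @ h_prev + params.b_hU))
    return z * h_prev + (1 - z) * hbar


def _forward(params: ModelParams, X: np.ndarray, keep_cache: bool):
    """Batched forward over X of shape (S, T, N_c+2); h_0 = 0."""
    S, T, _ = X.shape
    N_u = params.N_u
    h = np.zeros((S, N_u))
    H = np.empty((S, T, N_u))
    cache = [] if keep_cache else None
    for t in range(T):
        x = X[:, t, :]
        z = _sigmoid(x @ params.W_z.T + h @ params.U_z.T + params.b_z)
        r = _sigmoid(x @ params.W_r.T + h @ params.U_r.T + params.b_r)
        k = h @ params.U.T + params.b_hU
        hbar = np.tanh(x @ params.W.T + params.b_hW + r * k)
        h_new = z * h + (1 - z) * hbar
        if keep_cache:
            cache.append((h, z, r, k, hbar))
        h = h_new
        H[:, t, :] = h
    return H, cache


def _softmax(logits: np.ndarray) -> np.ndarray:
    m = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(m)
    return e / e.sum(axis=-1, keepdims=True)


def predict_probs(params: ModelParams, encoded: EncodedSequence) -> np.ndarray:
    """Per-trial predictive distribution over the four decks, shape (T, N_c)."""
    H, _ = _forward(params, encoded.inputs[None, :, :], keep_cache=False)
    return _softmax(H[0] @ params.V)


def predict_probs_batch(params: ModelParams, X: np.ndarray) -> np.ndarray:
    H, _ = _forward(params, X, keep_cache=False)
    return _softmax(H @ params.V)


def nll_loss(prob_sequences: np.ndarray, target_sequences: np.ndarray) -> float:
    """Cross-entropy summed over all subjects and trials (natural log)."""
    P = np.asarray(prob_sequences, dtype=np.float64)
    Y = np.asarray(target_sequences, dtype=np.float64)
    if P.shape != Y.shape:
        raise ValidationError(f"shape mismatch {P.shape} vs {Y.shape}")
    return float(-(Y * np.log(np.maximum(P, PROB_FLOOR))).sum())


def dataset_loss(params: ModelParams, X: np.ndarray, Y: np.ndarray) -> float:
    return nll_loss(predict_probs_batch(params, X), Y)


# ---------------------------------------------------------------------------
# backward


def loss_and_grads(
    params: ModelParams, X: np.ndarray, Y: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Summed cross-entropy and its exact gradient w.r.t. every array in Theta.

    Backpropagation through time over the batch (S, T, .); the returned loss
    and gradients use the summed convention — callers that optimize a mean
    divide by the batch size.
    """
    S, T, _ = X.shape
    H, cache = _forward(params, X, keep_cache=True)
    P = _softmax(H @ params.V)
    loss = nll_loss(P, Y)

    g = {n: np.zeros_like(getattr(params, n)) for n in PARAM_NAMES}
    dlogits = P - Y  # (S, T, N_c)
    g["V"] = np.einsum("stu,stc->uc", H, dlogits)
    dH = dlogits @ params.V.T  # (S, T, N_u)

    carry = np.zeros((S, params.N_u))
    for t in range(T - 1, -1, -1):
        h_prev, z, r, k, hbar = cache[t]
        x = X[:, t, :]
        dh = dH[:, t, :] + carry
        dz = dh * (h_prev - hbar)
        dhbar = dh * (1 - z)
        dh_prev = dh * z
        da = dhbar * (1 - hbar * hbar)
        g["W"] += da.T @ x
        g["b_hW"] += da.sum(axis=0)
        dr = da * k
        dk = da * r
        g["U"] += dk.T @ h_prev
        g["b_hU"] += dk.sum(axis=0)
        dh_prev += dk @ params.U
        ds_r = dr * r * (1 - r)
        g["W_r"] += ds_r.T @ x
        g["U_r"] += ds_r.T @ h_prev
        g["b_r"] += ds_r.sum(axis=0)
        dh_prev += ds_r @ params.U_r
        ds_z = dz * z * (1 - z)
        g["W_z"] += ds_z.T @ x
        g["U_z"] += ds_z.T @ h_prev
        g["b_z"] += ds_z.sum(axis=0)
        dh_prev += ds_z @ params.U_z
        carry = dh_prev
    return loss, g


# ---------------------------------------------------------------------------
# optimization


class _Adam:
    def __init__(self, params: ModelParams, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {n: np.zeros_like(getattr(params, n)) for n in PARAM_NAMES}
        self.v = {n: np.zeros_like(getattr(params, n)) for n in PARAM_NAMES}

    def step(self, params: ModelParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        c1 = 1 - self.b1**self.t
        c2 = 1 - self.b2**self.t
        for n in PARAM_NAMES:
            gn = grads[n]
            self.m[n] = self.b1 * self.m[n] + (1 - self.b1) * gn
            self.v[n] = self.b2 * self.v[n] + (1 - self.b2) * gn * gn
            getattr(params, n)[...] -= (
                self.lr * (self.m[n] / c1) / (np.sqrt(self.v[n] / c2) + self.eps)
            )


class _SGD:
    def __init__(self, params: ModelParams, lr: float):
        self.lr = lr

    def step(self, params: ModelParams, grads: dict[str, np.ndarray]) -> None:
        for n in PARAM_NAMES:
            getattr(params, n)[...] -= self.lr * grads[n]


def fit(
    params: ModelParams,
    encoded_batch: Sequence[EncodedSequence],
    schedule: TrainSchedule | None = None,
    val_batch: Sequence[EncodedSequence] | None = None,
    subject_ids: Sequence[str] | None = None,
) -> FitResult:
    """Minibatch training on the summed cross-entropy.

    Shuffling is re-seeded per call from ``schedule.seed``; the per-batch
    gradient is normalized by the number of sequences in the batch (the
    reported loss history keeps the summed convention).  ``subject_ids`` feeds
    the per-sample exposure audit used by the collaborative paradigms.
    """
    if len(encoded_batch) == 0:
        raise ValidationError("cannot fit on an empty batch")
    schedule = schedule or TrainSchedule()
    X, Y = stack_encoded(encoded_batch)
    S = X.shape[0]
    if val_batch is not None:
        Xv, Yv = stack_encoded(val_batch)
    bs = schedule.batch_size or S
    bs = min(bs, S)
    params = params.copy()
    opt_cls = {"adam": _Adam, "sgd": _SGD}[schedule.optimizer]
    opt = opt_cls(params, schedule.learn_rate)
    rng = np.random.default_rng(schedule.seed)
    if subject_ids is None:
        subject_ids = [f"s{i}" for i in range(S)]
    exposures = {sid: 0 for sid in subject_ids}

    train_hist: list[float] = []
    val_hist: list[float] = []
    for epoch in range(schedule.epochs):
        order = rng.permutation(S)
        epoch_loss = 0.0
        for start in range(0, S, bs):
            # shuffle decides batch membership; sorting fixes the row order so
            # full-batch training is invariant to the shuffle seed
            idx = np.sort(order[start : start + bs])
            loss, grads = loss_and_grads(params, X[idx], Y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch offset {start}"
                )
            epoch_loss += loss
            inv = 1.0 / len(idx)
            opt.step(params, {n: g * inv for n, g in grads.items()})
            for i in idx:
                exposures[subject_ids[i]] += 1
        train_hist.append(epoch_loss)
        if val_batch is not None:
            val_hist.append(dataset_loss(params, Xv, Yv))
    return FitResult(
        params=params,
        train_loss_history=train_hist,
        val_loss_history=val_hist if val_batch is not None else None,
        epochs_run=schedule.epochs,
        seed=schedule.seed,
        exposures=exposures,
    )
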