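"""Seeded training loop: Adam on the censored discrete-time likelihood,
structured modality dropout, and validation-based checkpoint selection.

Modality dropout is the training-time counterpart of test-time missingness:
independently per sample and per epoch, the RNA / text modality is marked
unavailable with probability p_rna / p_txt (the anchor image modality is
never droppable), so the gate learns to redistribute weight instead of
relying on always-complete data.
"""

from __future__ import annotations

import copy
import dataclasses

import numpy as np
import pandas as pd

from ._autodiff import Tensor, clip
from .data import Batch
from .fusion import ModelConfig, Params, forward, survival_curve
from .objectives import HAZARD_EPS, c_index, risk_score

_GLOBAL_SEED: int | None = None


def set_global_seed(seed: int) -> np.random.Generator:
    """Seed every stochastic component from one integer.

    Seeds NumPy's legacy global state (for any library call that consults
    it) and returns a fresh ``Generator``; dedicated streams for init,
    shuffling, modality dropout and missing-pattern sampling are spawned
    from the same seed via ``SeedSequence``.
    """
    global _GLOBAL_SEED
    _GLOBAL_SEED = int(seed)
    np.random.seed(int(seed) % (2**32))
    return np.random.default_rng(seed)


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """n independent child generators deterministically derived from seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclasses.dataclass
class TrainConfig:
    """Optimisation settings (defaults sized for desk-scale cohorts)."""

    epochs: int = 50
    batch_size: int = 32
    lr: float = 1e-3
    weight_decay: float = 1e-3  # decoupled L2 on weight matrices (not norms/biases)
    optimizer: str = "adam"
    p_rna: float = 0.3  # structured modality dropout rates
    p_txt: float = 0.3
    patience: int = 10  # early stopping on validation mean C-index
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_rna < 1.0 and 0.0 <= self.p_txt < 1.0):
            raise ValueError("modality dropout probabilities must lie in [0, 1)")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is implemented")


def modality_dropout(
    batch: Batch, p_rna: float, p_txt: float, rng: np.random.Generator
) -> Batch:
    """Randomly mark RNA/text unavailable per sample; image is untouched.

    Returns a new batch with mask and feature rows zeroed consistently; the
    input batch is never mutated.
    """
    if not (0.0 <= p_rna < 1.0 and 0.0 <= p_txt < 1.0):
        raise ValueError("dropout probabilities must lie in [0, 1)")
    n = len(batch)
    keep_rna = rng.random(n) >= p_rna
    keep_txt = rng.random(n) >= p_txt
    mask = batch.mask.copy()
    mask[:, 1] &= keep_rna
    mask[:, 2] &= keep_txt
    x_rna = batch.x_rna * mask[:, 1:2]
    x_txt = batch.x_txt * mask[:, 2:3]
    return Batch(
        patient_ids=list(batch.patient_ids),
        x_img=batch.x_img,
        x_rna=x_rna,
        x_txt=x_txt,
        mask=mask,
        cancer_index=batch.cancer_index,
        tau=batch.tau,
        event=batch.event,
    )


def nll_loss_tensor(hazards: Tensor, tau: np.ndarray, event: np.ndarray,
                    eps: float = HAZARD_EPS) -> Tensor:
    """Differentiable mean censored NLL (same convention as objectives.nll_loss)."""
    n, T = hazards.shape
    tau = np.asarray(tau, dtype=int)
    event = np.asarray(event, dtype=float)
    if np.any(tau < 1) or np.any(tau > T):
        raise ValueError(f"time bin out of range 1..{T}")
    bins = np.arange(1, T + 1)
    m_prev = (bins[None, :] < tau[:, None]).astype(float)  # k < τ
    m_le = (bins[None, :] <= tau[:, None]).astype(float)  # k <= τ
    m_tau = (bins[None, :] == tau[:, None]).astype(float)  # k == τ
    h = clip(hazards, eps, 1.0 - eps)
    log_h = h.log()
    log_1mh = (1.0 - h).log()
    ev_term = (Tensor(m_prev) * log_1mh).sum(axis=1) + (Tensor(m_tau) * log_h).sum(axis=1)
    cen_term = (Tensor(m_le) * log_1mh).sum(axis=1)
    per_sample = Tensor(event) * ev_term + Tensor(1.0 - event) * cen_term
    return -per_sample.mean()


class Adam:
    """Adam over named parameter tensors (updates .data in place)."""

    def __init__(self, params: Params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.tensors.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.tensors.items()}

    @staticmethod
    def _decayable(name: str) -> bool:
        # weight matrices only; layer-norm scales/offsets and biases are exempt
        return name.startswith(("W_", "head")) or "_W" in name or name.endswith(
            ("Wq", "Wk", "Wv", "Wo", "W1", "W2")
        )

    def step(self) -> None:
        self.t += 1
        for name, tensor in self.params.tensors.items():
            if tensor.grad is None:
                continue
            g = tensor.grad
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            m_hat = self.m[name] / (1 - self.b1**self.t)
            v_hat = self.v[name] / (1 - self.b2**self.t)
            update = m_hat / (np.sqrt(v_hat) + self.eps)
            if self.weight_decay > 0.0 and self._decayable(name) and tensor.ndim > 1:
                update = update + self.weight_decay * tensor.data
            tensor.data -= self.lr * update


def _val_mean_cindex(
    params: Params,
    config: ModelConfig,
    batch: Batch,
    times: np.ndarray,
    events: np.ndarray,
    cancer_labels: np.ndarray,
) -> float:
    hazards = forward(batch, params, config, training=False)["hazards"].data
    risks = risk_score(hazards, kind=config.risk)
    values = []
    for cancer in np.unique(cancer_labels):
        sel = cancer_labels == cancer
        try:
            values.append(c_index(risks[sel], times[sel], events[sel]))
        except ValueError:  # no comparable pair for this cancer in val
            continue
    return float(np.mean(values)) if values else float("nan")


def train(
    params: Params,
    model_config: ModelConfig,
    train_batch: Batch,
    val_batch: Batch,
    val_times: np.ndarray,
    val_events: np.ndarray,
    val_cancer_labels: np.ndarray,
    config: TrainConfig,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Minimise the censored NLL; return the best-validation parameters.

    The checkpoint with the highest validation mean C-index (unweighted
    across cancer types) is kept; training stops early after ``patience``
    epochs without improvement.  Bit-reproducible given ``config.seed``.
    """
    if set(train_batch.patient_ids) & set(val_batch.patient_ids):
        raise ValueError("train and validation patient ids overlap")
    rng_shuffle, rng_dropout, rng_proj = spawn_rngs(config.seed, 3)
    optimizer = Adam(params, lr=config.lr, weight_decay=config.weight_decay)
    n = len(train_batch)
    best_score = -np.inf
    best_arrays = params.arrays()
    best_epoch = -1
    rows = []
    for epoch in range(config.epochs):
        epoch_batch = modality_dropout(
            train_batch, config.p_rna, config.p_txt, rng_dropout
        )
        order = rng_shuffle.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            mini = epoch_batch.take(order[start : start + config.batch_size])
            params.zero_grad()
            out = forward(mini, params, model_config, training=True, rng=rng_proj)
            loss = nll_loss_tensor(out["hazards"], mini.tau, mini.event)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "try a lower learning rate (e.g. lr/10) or smaller batches"
                )
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        val_score = _val_mean_cindex(
            params, model_config, val_batch, val_times, val_events, val_cancer_labels
        )
        rows.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_cindex": val_score}
        )
        if np.isfinite(val_score) and val_score > best_score:
            best_score = val_score
            best_arrays = params.arrays()
            best_epoch = epoch
        elif epoch - best_epoch >= config.patience:
            break
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = best_epoch
    history.attrs["best_val_cindex"] = best_score
    history.attrs["seed"] = config.seed
    return best_arrays, history
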