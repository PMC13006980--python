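"""Forward model: availability-masked gated fusion with per-cancer hazard heads.

The architecture, end to end:

1. each modality is projected into a shared d = 32 embedding space
   (``Dropout(ReLU(x Wᵀ + b))``, dropout active in training only);
2. rows of unavailable modalities are zero-substituted;
3. a bias-free gate maps the concatenated (img, rna, txt) embeddings to
   three logits; unavailable modalities receive an additive −1e9 logit
   penalty, and a row-wise softmax yields convex fusion weights — the
   anchor (image) modality is never maskable;
4. the weighted sum of modality embeddings passes through a shared
   pre-norm transformer encoder (global average pool over tokens);
5. per-cancer hazard heads emit T per-bin sigmoid hazards, from which the
   survival curve Ŝ(t) = Π_{k≤t}(1 − ĥ_k) follows.

All compute runs on the package autodiff tape so the same code path serves
training (gradients) and evaluation (plain arrays).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, clip, concat, layer_norm, relu, sigmoid, softmax
from .data import Batch, MODALITY_DIMS

GATE_PENALTY = -1.0e9


@dataclasses.dataclass
class ModelConfig:
    """Dimensions and architectural switches of the fusion model."""

    d: int = 32  # shared embedding dimension
    T: int = 4  # discrete time bins
    C: int = 10  # number of cancer-type heads
    d_img: int = MODALITY_DIMS["img"]
    d_rna: int = MODALITY_DIMS["rna"]
    d_txt: int = MODALITY_DIMS["txt"]
    dropout: float = 0.25
    encoder_layers: int = 2
    encoder_heads: int = 4
    encoder_ffn: int = 64
    penalty: float = GATE_PENALTY
    fusion: str = "gated"  # "gated" | "early" (unmasked concat foil)
    encoder_tokens: str = "fused"  # "fused" (one token) | "modality" (three)
    risk: str = "neg_cum_surv"  # "neg_cum_surv" | "cum_hazard"
    schema_version: str = "gatedsurv-checkpoint-1"

    def __post_init__(self) -> None:
        if self.d < 1 or self.T < 2 or self.C < 1:
            raise ValueError("require d >= 1, T >= 2, C >= 1")
        if self.penalty > -1.0e6:
            raise ValueError("gate penalty must be <= -1e6")
        if self.d % self.encoder_heads != 0:
            raise ValueError("embedding dim must divide into encoder heads")
        if self.fusion not in ("gated", "early"):
            raise ValueError("fusion must be 'gated' or 'early'")
        if self.encoder_tokens not in ("fused", "modality"):
            raise ValueError("encoder_tokens must be 'fused' or 'modality'")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls(**json.loads(text))


def _uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def init_params(config: ModelConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Seeded uniform fan-in initialisation of every parameter group.

    The input projections start at a tenth of the fan-in scale: with
    thousand-dimensional inputs a full-scale random projection dominates
    the 32-d embedding with frozen random features that the gradient then
    has to fight, whereas a damped start lets the fitted signal directions
    define the embedding.
    """
    d = config.d
    p: dict[str, np.ndarray] = {}
    for m, dim in (("img", config.d_img), ("rna", config.d_rna), ("txt", config.d_txt)):
        p[f"W_{m}"] = _uniform(rng, (d, dim), dim) * 0.1
        p[f"b_{m}"] = _uniform(rng, (d,), dim)
    p["W_gate"] = _uniform(rng, (3, 3 * d), 3 * d) * 0.1  # bias-free gate, damped
    if config.fusion == "early":
        p["W_fuse"] = _uniform(rng, (d, 3 * d), 3 * d)
        p["b_fuse"] = _uniform(rng, (d,), 3 * d)
    for layer in range(config.encoder_layers):
        pre = f"enc{layer}_"
        for name in ("Wq", "Wk", "Wv", "Wo"):
            p[pre + name] = _uniform(rng, (d, d), d)
        for name in ("bq", "bk", "bv", "bo"):
            p[pre + name] = _uniform(rng, (d,), d)
        p[pre + "ln1_g"] = np.ones(d)
        p[pre + "ln1_b"] = np.zeros(d)
        p[pre + "ln2_g"] = np.ones(d)
        p[pre + "ln2_b"] = np.zeros(d)
        p[pre + "W1"] = _uniform(rng, (config.encoder_ffn, d), d)
        p[pre + "b1"] = _uniform(rng, (config.encoder_ffn,), d)
        p[pre + "W2"] = _uniform(rng, (d, config.encoder_ffn), config.encoder_ffn)
        p[pre + "b2"] = _uniform(rng, (d,), config.encoder_ffn)
    for c in range(config.C):
        p[f"head{c}_W"] = _uniform(rng, (config.T, d), d)
        p[f"head{c}_b"] = _uniform(rng, (config.T,), d)
    return p


class Params:
    """Named parameter groups wrapped as autodiff leaves."""

    def __init__(self, arrays: dict[str, np.ndarray]):
        self.tensors = {k: Tensor(v, requires_grad=True) for k, v in arrays.items()}
        for name, t in self.tensors.items():
            if not np.all(np.isfinite(t.data)):
                raise ValueError(f"non-finite parameter group {name}")

    def __getitem__(self, name: str) -> Tensor:
        return self.tensors[name]

    def __contains__(self, name: str) -> bool:
        return name in self.tensors

    def arrays(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.tensors.items()}

    def zero_grad(self) -> None:
        for t in self.tensors.values():
            t.zero_grad()


# -- checkpoint IO ------------------------------------------------------------


def save_checkpoint(path: str | Path, arrays: dict[str, np.ndarray], config: ModelConfig,
                    meta: dict | None = None) -> None:
    """Single-file JSON checkpoint: config, metadata and parameter groups."""
    payload = {
        "schema": config.schema_version,
        "config": dataclasses.asdict(config),
        "meta": meta or {},
        "params": {k: v.tolist() for k, v in arrays.items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], ModelConfig, dict]:
    payload = json.loads(Path(path).read_text())
    config = ModelConfig(**payload["config"])
    if payload["schema"] != config.schema_version:
        raise ValueError(f"unknown checkpoint schema {payload['schema']!r}")
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in payload["params"].items()}
    return arrays, config, payload["meta"]


# -- forward components -------------------------------------------------------


def project_modality(
    x: Tensor | np.ndarray,
    params: Params,
    modality: str,
    config: ModelConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Dropout(ReLU(x Wᵀ + b)) into the shared d-dim space."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    expected = {"img": config.d_img, "rna": config.d_rna, "txt": config.d_txt}[modality]
    if x.shape[-1] != expected:
        raise ValueError(
            f"{modality} input width {x.shape[-1]} != configured {expected}"
        )
    w, b = params[f"W_{modality}"], params[f"b_{modality}"]
    z = relu(x @ w.transpose(1, 0) + b)
    if training and config.dropout > 0.0:
        if rng is None:
            raise ValueError("training-mode projection needs an rng for dropout")
        keep = (rng.random(z.shape) >= config.dropout) / (1.0 - config.dropout)
        z = z * Tensor(keep)
    return z


def zero_substitute(z: Tensor, mask_col: np.ndarray) -> Tensor:
    """Zero the embedding rows of samples whose modality is unavailable."""
    return z * Tensor(mask_col.astype(np.float64)[:, None])


def gate_logits(z_img: Tensor, z_rna: Tensor, z_txt: Tensor, params: Params) -> Tensor:
    """Bias-free gate over the concatenated (img, rna, txt) embeddings."""
    if not (z_img.shape == z_rna.shape == z_txt.shape):
        raise ValueError("modality embeddings must share shape B x d")
    z_cat = concat([z_img, z_rna, z_txt], axis=1)
    return z_cat @ params["W_gate"].transpose(1, 0)


def mask_logits(
    logits: Tensor | np.ndarray, mask: np.ndarray, penalty: float = GATE_PENALTY
) -> Tensor:
    """Additive logit penalty (1 − M) · penalty for unavailable modalities."""
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("availability mask must be binary")
    if not np.all(mask[:, 0] == 1):
        raise ValueError("pathological image modality must be available")
    logits = logits if isinstance(logits, Tensor) else Tensor(logits)
    return logits + Tensor((1.0 - mask.astype(np.float64)) * penalty)


def gate_weights(masked_logits: Tensor | np.ndarray) -> Tensor:
    """Row-wise softmax of the masked logits: convex fusion weights."""
    masked_logits = (
        masked_logits if isinstance(masked_logits, Tensor) else Tensor(masked_logits)
    )
    return softmax(masked_logits, axis=-1)


def fuse(g: Tensor, z_img: Tensor, z_rna: Tensor, z_txt: Tensor) -> Tensor:
    """Weighted sum Σ_m G[:, m] ⊙ Z_m of the modality embeddings."""
    row_sums = g.data.sum(axis=-1)
    if np.any(np.abs(row_sums - 1.0) > 1e-6):
        raise ValueError("gate weight rows must sum to 1 (upstream contract)")
    return _column(g, 0) * z_img + _column(g, 1) * z_rna + _column(g, 2) * z_txt


def _column(g: Tensor, j: int) -> Tensor:
    """Column j of a B×3 tensor as B×1, via a constant selector matmul."""
    sel = np.zeros((3, 1))
    sel[j, 0] = 1.0
    return g @ Tensor(sel)


def _encoder_layer(x: Tensor, params: Params, layer: int, config: ModelConfig) -> Tensor:
    """One pre-norm transformer block on a (B, S, d) token tensor."""
    pre = f"enc{layer}_"
    b, s, d = x.shape
    h = config.encoder_heads
    dh = d // h

    def heads(t: Tensor) -> Tensor:  # (B,S,d) -> (B,h,S,dh)
        return t.reshape(b, s, h, dh).transpose(0, 2, 1, 3)

    xn = layer_norm(x, params[pre + "ln1_g"], params[pre + "ln1_b"])
    q = heads(xn @ params[pre + "Wq"].transpose(1, 0) + params[pre + "bq"])
    k = heads(xn @ params[pre + "Wk"].transpose(1, 0) + params[pre + "bk"])
    v = heads(xn @ params[pre + "Wv"].transpose(1, 0) + params[pre + "bv"])
    scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
    attn = softmax(scores, axis=-1)
    ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, s, d)
    x = x + ctx @ params[pre + "Wo"].transpose(1, 0) + params[pre + "bo"]
    xn2 = layer_norm(x, params[pre + "ln2_g"], params[pre + "ln2_b"])
    ff = relu(xn2 @ params[pre + "W1"].transpose(1, 0) + params[pre + "b1"])
    return x + ff @ params[pre + "W2"].transpose(1, 0) + params[pre + "b2"]


def shared_encode(tokens: Tensor, params: Params, config: ModelConfig) -> Tensor:
    """Shared transformer encoder + global average pool over tokens.

    ``tokens`` is (B, S, d); with the default single fused token (S = 1) the
    pool simply returns that token's encoding.
    """
    x = tokens
    for layer in range(config.encoder_layers):
        x = _encoder_layer(x, params, layer, config)
    return x.mean(axis=1)


def cancer_hazards(
    h: Tensor, cancer_index: np.ndarray, params: Params, config: ModelConfig
) -> Tensor:
    """Per-row dispatch to the cancer-type-specific sigmoid hazard head."""
    cancer_index = np.asarray(cancer_index)
    if cancer_index.min() < 0 or cancer_index.max() >= config.C:
        raise ValueError(
            f"cancer index out of range [0, {config.C}): {sorted(set(cancer_index))}"
        )
    total: Tensor | None = None
    for c in np.unique(cancer_index):
        sel = Tensor((cancer_index == c).astype(np.float64)[:, None])
        logits = h @ params[f"head{int(c)}_W"].transpose(1, 0) + params[f"head{int(c)}_b"]
        contrib = sel * logits
        total = contrib if total is None else total + contrib
    return sigmoid(total)


def survival_curve(hazards: np.ndarray) -> np.ndarray:
    """Ŝ(t) = Π_{k≤t}(1 − ĥ_k) along the last axis; Ŝ(0) := 1 implicitly."""
    hazards = np.asarray(hazards, dtype=np.float64)
    if np.any(hazards < 0.0) or np.any(hazards > 1.0):
        raise ValueError("hazards must lie in [0, 1]")
    return np.cumprod(1.0 - hazards, axis=-1)


@dataclasses.dataclass
class HazardPrediction:
    """Per-patient hazards, derived survival curve and scalar risk."""

    patient_ids: list[str]
    hazards: np.ndarray  # B x T in (0, 1)
    survival: np.ndarray  # B x T, non-increasing
    risk: np.ndarray  # B
    gate: np.ndarray  # B x 3 fusion weights (img, rna, txt)


def forward(
    batch: Batch,
    params: Params,
    config: ModelConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> dict[str, Tensor]:
    """Full forward pass; returns named intermediate tensors for inspection."""
    z_img = project_modality(batch.x_img, params, "img", config, training, rng)
    z_rna = project_modality(batch.x_rna, params, "rna", config, training, rng)
    z_txt = project_modality(batch.x_txt, params, "txt", config, training, rng)
    z_rna = zero_substitute(z_rna, batch.mask[:, 1])
    z_txt = zero_substitute(z_txt, batch.mask[:, 2])

    if config.fusion == "gated":
        logits = gate_logits(z_img, z_rna, z_txt, params)
        g = gate_weights(mask_logits(logits, batch.mask, config.penalty))
        z_fused = fuse(g, z_img, z_rna, z_txt)
    else:  # unmasked early-fusion foil: plain concat, zeros stand in
        z_cat = concat([z_img, z_rna, z_txt], axis=1)
        z_fused = z_cat @ params["W_fuse"].transpose(1, 0) + params["b_fuse"]
        g = Tensor(np.full((len(batch), 3), np.nan))

    b = z_fused.shape[0]
    if config.encoder_tokens == "fused":
        tokens = z_fused.reshape(b, 1, config.d)
    else:
        tokens = concat(
            [z.reshape(b, 1, config.d) for z in (z_img, z_rna, z_txt)], axis=1
        )
    h = shared_encode(tokens, params, config)
    hazards = cancer_hazards(h, batch.cancer_index, params, config)
    return {
        "z_img": z_img,
        "z_rna": z_rna,
        "z_txt": z_txt,
        "gate": g,
        "z_fused": z_fused,
        "encoded": h,
        "hazards": hazards,
    }


def predict(
    batch: Batch, params: Params, config: ModelConfig
) -> HazardPrediction:
    """Deterministic eval-mode prediction with derived curves and risks."""
    from .objectives import risk_score  # local import avoids a cycle

    out = forward(batch, params, config, training=False)
    hazards = out["hazards"].data
    survival = survival_curve(hazards)
    return HazardPrediction(
        patient_ids=list(batch.patient_ids),
        hazards=hazards,
        survival=survival,
        risk=risk_score(hazards, kind=config.risk),
        gate=out["gate"].data.copy(),
    )
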