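"""Patient-level feature preprocessing.

Raw inputs are per-patient arrays: histopathology patch features
(N_i × 2048 embeddings, optionally with the grayscale patches they came
from), RNA gene embeddings (G × 256) and clinical-text token embeddings
(L × 768).  This module reduces them to the fixed-size pooled vectors the
fusion model consumes:

* tissue/background separation by Shannon entropy of the 8-bit intensity
  histogram (background patches, entropy < 5 bits, are discarded);
* K-means aggregation of patch embeddings into k = 128 cluster centres,
  mean-pooled to a single 2048-d image vector;
* mean pooling over tokens (text, max length 200) and genes (RNA).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .data import MODALITY_DIMS

ENTROPY_THRESHOLD_BITS = 5.0
DEFAULT_K = 128
MAX_TEXT_TOKENS = 200


@dataclasses.dataclass
class PatchSet:
    """Patches of one slide: intensity arrays and/or their feature matrix."""

    patches: list[np.ndarray] | None = None
    patch_features: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.patches is None and self.patch_features is None:
            raise ValueError("PatchSet needs patches and/or patch_features")
        if self.patch_features is not None:
            self.patch_features = np.asarray(self.patch_features, dtype=np.float64)
            if self.patch_features.ndim != 2 or self.patch_features.shape[1] != MODALITY_DIMS["img"]:
                raise ValueError(
                    f"patch_features must be N x {MODALITY_DIMS['img']}, "
                    f"got {self.patch_features.shape}"
                )
        if (
            self.patches is not None
            and self.patch_features is not None
            and len(self.patches) != self.patch_features.shape[0]
        ):
            raise ValueError("patches and patch_features disagree on N")

    def __len__(self) -> int:
        if self.patches is not None:
            return len(self.patches)
        return self.patch_features.shape[0]


def patch_entropy(patch: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin intensity histogram of a patch.

    Intensities must be integers in [0, 255]; the result lies in [0, 8].
    """
    patch = np.asarray(patch)
    if patch.size == 0:
        raise ValueError("empty patch")
    if not np.issubdtype(patch.dtype, np.integer):
        if not np.all(patch == np.floor(patch)):
            raise ValueError(
                "patch intensities must be integers in [0, 255]; "
                "quantize (e.g. np.round) before computing entropy"
            )
        patch = patch.astype(np.int64)
    if patch.min() < 0 or patch.max() > 255:
        raise ValueError("patch intensities must lie in [0, 255]")
    counts = np.bincount(patch.ravel(), minlength=256)
    p = counts[counts > 0] / patch.size
    return float(-(p * np.log2(p)).sum())


def filter_patches(
    patch_set: PatchSet, threshold: float = ENTROPY_THRESHOLD_BITS
) -> PatchSet:
    """Drop background patches (entropy < threshold), preserving order."""
    if patch_set.patches is None:
        raise ValueError("entropy filtering needs intensity patches")
    keep = [i for i, p in enumerate(patch_set.patches) if patch_entropy(p) >= threshold]
    if not keep:
        raise ValueError(
            "all patches discarded by the entropy filter; "
            "patient has no foreground tissue"
        )
    features = (
        None if patch_set.patch_features is None else patch_set.patch_features[keep]
    )
    return PatchSet(
        patches=[patch_set.patches[i] for i in keep], patch_features=features
    )


def _canonical_row_order(x: np.ndarray) -> np.ndarray:
    """Lexicographic row order, so clustering ignores input row permutation."""
    return np.lexsort(x.T[::-1])


def kmeans_aggregate(
    patch_features: np.ndarray, k: int = DEFAULT_K, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate N×2048 patch embeddings into cluster centres + pooled vector.

    Runs seeded K-means with k' = min(k, N) clusters (max 300 iterations,
    tol 1e-4) on a canonicalised row order, and returns ``(centers, pooled)``
    where ``pooled`` is the unweighted mean of the k' centres — the single
    patient-level image vector.
    """
    x = np.asarray(patch_features, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("patch_features must be a non-empty N x D matrix")
    if k < 1:
        raise ValueError("k must be >= 1")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite patch features")
    x = x[_canonical_row_order(x)]
    k_eff = min(k, x.shape[0])
    if k_eff == x.shape[0]:
        centers = x.copy()  # each point its own cluster
    else:
        km = KMeans(
            n_clusters=k_eff,
            n_init=1,
            max_iter=300,
            tol=1e-4,
            random_state=seed,
        ).fit(x)
        centers = km.cluster_centers_
    return centers, centers.mean(axis=0)


def mean_pool(matrix: np.ndarray) -> np.ndarray:
    """Arithmetic mean over the first axis of an L×D matrix (L >= 1).

    An empty matrix is an error: a missing modality must be flagged absent,
    never pooled into zeros.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[0] == 0:
        raise ValueError("mean_pool needs a non-empty L x D matrix")
    return matrix.mean(axis=0)


def pool_text(tokens: np.ndarray, max_len: int = MAX_TEXT_TOKENS) -> np.ndarray:
    """Mean-pool token embeddings, truncating sequences longer than max_len.

    Shorter sequences are pooled over their true length — padding never
    enters the mean.
    """
    tokens = np.asarray(tokens, dtype=np.float64)
    return mean_pool(tokens[:max_len])


def pool_patient(
    patch_features: np.ndarray,
    rna: np.ndarray | None = None,
    txt: np.ndarray | None = None,
    k: int = DEFAULT_K,
    seed: int = 0,
) -> dict[str, np.ndarray | None]:
    """Full preprocessing for one patient: pooled img/rna/txt vectors."""
    _, img = kmeans_aggregate(patch_features, k=k, seed=seed)
    return {
        "img": img,
        "rna": None if rna is None else mean_pool(rna),
        "txt": None if txt is None else pool_text(txt),
    }


def pooled_table(
    patient_ids: Sequence[str], pooled: Sequence[dict[str, np.ndarray | None]]
):
    """Assemble pooled per-patient vectors into the standard feature table."""
    import pandas as pd

    rows = []
    for pid, feats in zip(patient_ids, pooled):
        row: dict[str, object] = {"patient_id": pid}
        row.update({f"img_{j}": v for j, v in enumerate(feats["img"])})
        row["has_rna"] = feats["rna"] is not None
        row["has_txt"] = feats["txt"] is not None
        if feats["rna"] is not None:
            row.update({f"rna_{j}": v for j, v in enumerate(feats["rna"])})
        if feats["txt"] is not None:
            row.update({f"txt_{j}": v for j, v in enumerate(feats["txt"])})
        rows.append(row)
    return pd.DataFrame(rows)
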