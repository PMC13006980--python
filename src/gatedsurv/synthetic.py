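"""Synthetic multimodal survival cohorts with plantable prognostic signal.

The generator emulates the statistical structure the model assumes, at the
true feature dimensions (2048 / 256 / 768 pooled widths):

* per patient, one latent prognostic factor per modality, built from a
  shared tumour-state latent g plus modality-specific components:
  f_m = w·g + sqrt(1 − w²)·e_m with w = 0.7 by default, so modality
  signals are strongly but not perfectly redundant (pairwise factor
  correlation w² ≈ 0.5) — the regime in which histology, transcriptome
  and report text all reflect the same underlying grade/stage;
* observed pooled features = embedding mean + site mean shift +
  loading · factor + noise, where the loading direction u_m is a fixed
  unit vector per modality, the embedding mean is a fixed non-zero offset
  (pooled transformer embeddings are not centred), and the site shift
  moves feature means only (never the latent risk), so institution-grouped
  splits probe covariate-shift robustness;
* true log hazard ratio r_i = Σ_m β_m^{c_i} · f_m,i with per-cancer signal
  coefficients β;
* survival time ~ Exponential(λ0 · exp(r_i)); independent censoring time
  ~ Exponential(λ_c) with λ_c solved numerically so the expected censoring
  fraction hits the configured target.

Ground-truth risks are returned in a separate table so no pipeline stage
can consume them by accident; they exist for oracle scoring only.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data import Cohort, MODALITY_DIMS, PatientRecord

MODALITY_KEYS = ("img", "rna", "txt")


@dataclasses.dataclass
class SimConfig:
    """Cohort-level simulation settings.

    ``betas`` maps each cancer type to its (β_img, β_rna, β_txt) signal
    coefficients; a single triple is broadcast to all cancers.
    """

    n_patients: int = 600
    cancer_types: Sequence[str] = ("CA", "CB", "CC")
    institutions_per_cancer: int = 6
    betas: dict[str, tuple[float, float, float]] | tuple[float, float, float] = (
        0.7,
        0.9,
        0.5,
    )
    baseline_hazard: float = 1.0 / 365.0  # events per day
    censoring_target: float = 0.35
    loading_scale: float = 2.0  # signal magnitude along the loading direction
    # pooled features are means of ~n_patches raw rows carrying row_noise_sd
    # noise, so patient-level noise is row_noise_sd / sqrt(128) ~ 0.1
    noise_sd: float = 0.1
    site_shift_sd: float = 0.25  # per-site mean-shift magnitude
    shared_latent_weight: float = 0.7  # cross-modal redundancy w (corr w²)
    embedding_mean: float = 0.5  # per-coordinate mean of the embedding offset
    embedding_mean_sd: float = 0.25
    n_patches: tuple[int, int] = (128, 128)  # N_i range for raw patch arrays
    n_tokens: int = 200  # L_max for raw text arrays
    n_genes: int = 2048  # G for raw RNA arrays
    row_noise_sd: float = 1.0  # within-patient patch/token/gene noise

    def __post_init__(self) -> None:
        if not 0.0 <= self.censoring_target < 1.0:
            raise ValueError("censoring target must lie in [0, 1)")
        if not 0.0 <= self.shared_latent_weight < 1.0:
            raise ValueError("shared latent weight must lie in [0, 1)")
        if self.n_patients < 1 or not self.cancer_types:
            raise ValueError("need at least one patient and one cancer type")
        if isinstance(self.betas, (tuple, list)):
            self.betas = {c: tuple(self.betas) for c in self.cancer_types}
        missing = set(self.cancer_types) - set(self.betas)
        if missing:
            raise ValueError(f"betas missing for cancer types {sorted(missing)}")

    def beta_matrix(self) -> np.ndarray:
        return np.array([self.betas[c] for c in self.cancer_types], dtype=float)


def _censoring_rate_for(lam_c: float, patient_rates: np.ndarray) -> float:
    # P(censor before event) for independent exponentials
    return float(np.mean(lam_c / (lam_c + patient_rates)))


def _solve_censoring_rate(patient_rates: np.ndarray, target: float) -> float:
    """λ_c such that the expected censoring fraction equals target."""
    if target == 0.0:
        return 0.0
    lo, hi = 1e-12, 1e12
    f = lambda lam: _censoring_rate_for(lam, patient_rates) - target
    if f(hi) < 0:
        achievable = _censoring_rate_for(hi, patient_rates)
        raise ValueError(
            f"censoring target {target} unattainable; achievable range "
            f"is [0, {achievable:.4f}) for this cohort"
        )
    return brentq(f, lo, hi, xtol=1e-15, rtol=1e-12)


def generate_cohort(config: SimConfig, seed: int) -> tuple[Cohort, pd.DataFrame]:
    """Simulate a cohort; returns (records, ground-truth table).

    The truth table carries the latent factors, the true risk and the
    uncensored event/censoring times — for oracle scoring only.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    cancers = list(config.cancer_types)
    n = config.n_patients
    dims = {m: MODALITY_DIMS[m] for m in MODALITY_KEYS}

    # fixed cohort-level structure: loadings, embedding offsets, site shifts
    loadings = {
        m: _unit(rng.standard_normal(dims[m])) * config.loading_scale
        for m in MODALITY_KEYS
    }
    offsets = {
        m: rng.normal(config.embedding_mean, config.embedding_mean_sd, dims[m])
        for m in MODALITY_KEYS
    }
    sites = {
        c: [f"{c}-site{j}" for j in range(config.institutions_per_cancer)]
        for c in cancers
    }
    site_shift = {
        (c, s): {
            m: rng.standard_normal(dims[m]) * config.site_shift_sd
            for m in MODALITY_KEYS
        }
        for c in cancers
        for s in sites[c]
    }

    cancer_of = np.array([cancers[i % len(cancers)] for i in range(n)], dtype=object)
    site_of = np.array(
        [rng.choice(sites[c]) for c in cancer_of], dtype=object
    )
    w = config.shared_latent_weight
    shared = rng.standard_normal(n)
    specific = rng.standard_normal((n, 3))
    factors = w * shared[:, None] + np.sqrt(1.0 - w**2) * specific
    beta = np.array([config.betas[c] for c in cancer_of])
    true_risk = (beta * factors).sum(axis=1)

    patient_rates = config.baseline_hazard * np.exp(true_risk)
    event_times = rng.exponential(1.0 / patient_rates)
    lam_c = _solve_censoring_rate(patient_rates, config.censoring_target)
    if lam_c > 0:
        censor_times = rng.exponential(1.0 / lam_c, size=n)
    else:
        censor_times = np.full(n, np.inf)
    observed = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)

    records = []
    for i in range(n):
        feats = {}
        for j, m in enumerate(MODALITY_KEYS):
            center = (
                offsets[m]
                + site_shift[(cancer_of[i], site_of[i])][m]
                + factors[i, j] * loadings[m]
            )
            feats[m] = center + rng.standard_normal(dims[m]) * config.noise_sd
        records.append(
            PatientRecord(
                patient_id=f"P{i:05d}",
                cancer_type=str(cancer_of[i]),
                institution=str(site_of[i]),
                time=float(observed[i]),
                event=int(event[i]),
                img=feats["img"],
                rna=feats["rna"],
                txt=feats["txt"],
            )
        )
    truth = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "cancer_type": cancer_of,
            "institution": site_of,
            "f_shared": shared,
            "f_img": factors[:, 0],
            "f_rna": factors[:, 1],
            "f_txt": factors[:, 2],
            "true_risk": true_risk,
            "event_time": event_times,
            "censor_time": censor_times,
            "time_days": observed,
            "event": event,
        }
    )
    truth.attrs["seed"] = int(seed)
    truth.attrs["censoring_rate_target"] = config.censoring_target
    return Cohort(records), truth


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def materialize_raw(
    record: PatientRecord, config: SimConfig, seed: int
) -> dict[str, np.ndarray]:
    """Per-patient raw arrays (patches / genes / tokens) on demand.

    Rows are the patient's pooled vector plus mean-centred within-patient
    noise, so mean pooling the raw arrays reproduces the pooled features
    exactly.  Deterministic per (seed, patient).
    """
    index = int(record.patient_id.lstrip("P"))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), index, 0xA77]))
    lo, hi = config.n_patches
    counts = {
        "img": int(rng.integers(lo, hi + 1)),
        "rna": config.n_genes,
        "txt": config.n_tokens,
    }
    out = {}
    for m, key in (("img", "patches"), ("rna", "rna"), ("txt", "txt")):
        pooled = getattr(record, "img" if m == "img" else m)
        if pooled is None:
            continue
        eta = rng.standard_normal((counts[m], pooled.size)) * config.row_noise_sd
        out[key] = pooled + (eta - eta.mean(axis=0))
    return out


def synthetic_patches(
    rng: np.random.Generator,
    n_foreground: int,
    n_background: int,
    size: int = 224,
) -> list[np.ndarray]:
    """Grayscale test patches for the entropy filter: i.i.d. uniform noise
    (high entropy, tissue-like) followed by constant patches (background)."""
    fore = [
        rng.integers(0, 256, size=(size, size)).astype(np.int64)
        for _ in range(n_foreground)
    ]
    back = [
        np.full((size, size), int(rng.integers(0, 256)), dtype=np.int64)
        for _ in range(n_background)
    ]
    return fore + back


def censoring_rate(cohort: Cohort) -> float:
    """Observed censoring fraction 1 − mean(event)."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    return 1.0 - float(np.mean([r.event for r in cohort]))


def oracle_cindex_ceiling(
    truth: pd.DataFrame, per_cancer: bool = True
) -> dict[str, float]:
    """C-index of the true latent risks against the simulated outcomes.

    This is the ceiling any fitted model can approach on the same data;
    keyed by cancer type plus an ``overall`` unweighted mean.
    """
    from .objectives import c_index

    out: dict[str, float] = {}
    if per_cancer:
        for cancer, grp in truth.groupby("cancer_type"):
            out[str(cancer)] = c_index(
                grp["true_risk"], grp["time_days"], grp["event"]
            )
        out["overall"] = float(np.mean([v for k, v in out.items()]))
    else:
        out["overall"] = c_index(
            truth["true_risk"], truth["time_days"], truth["event"]
        )
    return out
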