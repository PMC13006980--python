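"""Survival-time discretisation, the censored discrete-time likelihood,
risk scoring and the concordance index.

Conventions (δ = 1 means the event was observed):

* an event in bin τ contributes  −[log Ŝ(τ−1) + log ĥ_τ]  (survive the
  earlier bins, fail in bin τ), with Ŝ(0) := 1;
* a censoring in bin τ contributes  −log Ŝ(τ)  (known to survive through τ);
* hazards are clamped to [eps, 1 − eps], eps = 1e-7, before logs.

The concordance index counts pairs (i, j) with t_i < t_j and δ_i = 1 as
comparable; a pair is concordant when risk_i > risk_j, and exact risk ties
receive half credit.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .fusion import survival_curve

HAZARD_EPS = 1e-7

_POOLED = "__pooled__"


@dataclasses.dataclass
class Discretizer:
    """Per-cancer survival-time cut points (T − 1 thresholds in days).

    Cut points are fitted on the training split only, as the T-quantiles of
    *uncensored* event times; cancers with fewer than T uncensored events
    fall back to pooled cut points.  Bin assignment maps time t to the
    half-open interval [cut_{k−1}, cut_k), the last bin unbounded above.
    """

    T: int
    cuts: dict[str, np.ndarray]  # cancer type (or pooled key) -> T-1 cuts
    max_time: dict[str, float]  # per-cancer max observed time (censor rule)

    def _cuts_for(self, cancer_type: str) -> np.ndarray:
        if cancer_type in self.cuts:
            return self.cuts[cancer_type]
        return self.cuts[_POOLED]

    def assign_bin(self, time: float, cancer_type: str) -> int:
        """1-based bin index in {1..T}."""
        cuts = self._cuts_for(cancer_type)
        return int(np.searchsorted(cuts, time, side="right")) + 1

    def assign(
        self, times: Sequence[float], cancer_types: Sequence[str]
    ) -> np.ndarray:
        return np.array(
            [self.assign_bin(t, c) for t, c in zip(times, cancer_types)],
            dtype=np.int64,
        )

    def label(self, time: float, event: int, cancer_type: str) -> tuple[int, int]:
        """(τ, δ) with the beyond-maximum rule: times past the largest
        observed training time for the cancer type are right-censored in the
        last bin (τ = T, δ = 0)."""
        cap = self.max_time.get(cancer_type)
        if cap is not None and time > cap:
            return self.T, 0
        return self.assign_bin(time, cancer_type), int(event)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "T": self.T,
            "cuts": {k: list(map(float, v)) for k, v in self.cuts.items()},
            "max_time": self.max_time,
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Discretizer":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        payload = json.loads(text)
        return cls(
            T=payload["T"],
            cuts={k: np.asarray(v, dtype=float) for k, v in payload["cuts"].items()},
            max_time={k: float(v) for k, v in payload["max_time"].items()},
        )


def _quantile_cuts(event_times: np.ndarray, T: int) -> np.ndarray:
    cuts = np.quantile(event_times, np.arange(1, T) / T)
    if np.any(np.diff(cuts) <= 0):
        raise ValueError(
            "degenerate cut points (tied event-time quantiles); "
            "cannot form strictly increasing bins"
        )
    return cuts


def fit_discretizer(
    times: Sequence[float],
    events: Sequence[int],
    cancer_types: Sequence[str],
    T: int = 4,
    per_cancer: bool = True,
) -> Discretizer:
    """Fit per-cancer quantile cut points on training labels."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    cancer_types = np.asarray(cancer_types, dtype=object)
    uncensored = events == 1
    if not uncensored.any():
        raise ValueError("no uncensored events anywhere; cannot fit bins")
    cuts = {_POOLED: _quantile_cuts(times[uncensored], T)}
    max_time = {}
    for cancer in np.unique(cancer_types):
        sel = cancer_types == cancer
        max_time[str(cancer)] = float(times[sel].max())
        cancer_events = times[sel & uncensored]
        if per_cancer and cancer_events.size >= T:
            cuts[str(cancer)] = _quantile_cuts(cancer_events, T)
    return Discretizer(T=T, cuts=cuts, max_time=max_time)


def nll_loss(
    hazards: np.ndarray,
    tau: np.ndarray,
    event: np.ndarray,
    eps: float = HAZARD_EPS,
) -> float:
    """Mean censored discrete-time negative log-likelihood (always >= 0)."""
    hazards = np.clip(np.asarray(hazards, dtype=float), eps, 1.0 - eps)
    tau = np.asarray(tau, dtype=int)
    event = np.asarray(event, dtype=int)
    n, T = hazards.shape
    if np.any(tau < 1) or np.any(tau > T):
        raise ValueError(f"time bin out of range 1..{T}")
    log_1mh = np.log(1.0 - hazards)
    log_surv = np.cumsum(log_1mh, axis=1)  # log Ŝ(t), t = 1..T
    idx = np.arange(n)
    log_s_prev = np.where(tau > 1, log_surv[idx, np.maximum(tau - 2, 0)], 0.0)
    log_h_tau = np.log(hazards)[idx, tau - 1]
    log_s_tau = log_surv[idx, tau - 1]
    terms = np.where(event == 1, -(log_s_prev + log_h_tau), -log_s_tau)
    return float(terms.mean())


def risk_score(hazards: np.ndarray, kind: str = "neg_cum_surv") -> np.ndarray:
    """Scalar risk from a hazard curve; higher risk = worse prognosis.

    Default is −Σ_t Ŝ(t) (negative area under the discrete survival curve);
    the cumulative hazard Σ_t ĥ_t is available as an alternative.
    """
    survival = survival_curve(hazards)
    if kind == "neg_cum_surv":
        return -survival.sum(axis=-1)
    if kind == "cum_hazard":
        return np.asarray(hazards, dtype=float).sum(axis=-1)
    raise ValueError(f"unknown risk kind {kind!r}")


def c_index(
    risks: Sequence[float], times: Sequence[float], events: Sequence[int]
) -> float:
    """Concordance index over comparable pairs (vectorised O(n²) count)."""
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    comparable = (times[:, None] < times[None, :]) & (events[:, None] == 1)
    n_pairs = comparable.sum()
    if n_pairs == 0:
        raise ValueError("no comparable pairs (check censoring pattern)")
    greater = risks[:, None] > risks[None, :]
    tied = risks[:, None] == risks[None, :]
    score = (comparable & greater).sum() + 0.5 * (comparable & tied).sum()
    return float(score / n_pairs)


def cohort_c_index(
    risks: Mapping[str, float],
    times: Mapping[str, float],
    events: Mapping[str, int],
) -> float:
    """c_index over aligned patient-id mappings (convenience wrapper)."""
    ids = list(risks)
    return c_index(
        [risks[i] for i in ids], [times[i] for i in ids], [events[i] for i in ids]
    )
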