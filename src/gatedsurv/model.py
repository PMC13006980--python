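"""Model and results objects for cancer-type-aware multimodal survival.

:class:`MultimodalSurvivalModel` is built from a cohort of patient records
(pooled modality features + survival labels); ``fit()`` runs the seeded
training loop and returns a :class:`SurvivalFit` carrying the fitted
parameters, training history, per-cancer test concordance and prediction /
plotting methods — the same model-object / results-object division used by
the mainstream statistical modelling packages.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import Batch, Cohort, build_batch
from .evaluation import (
    DEFAULT_SEEDS,
    ExperimentResult,
    SplitSpec,
    evaluate_risks,
    make_split,
    missing_modality_protocol,
)
from .fusion import (
    HazardPrediction,
    ModelConfig,
    Params,
    init_params,
    load_checkpoint,
    predict as _predict,
    save_checkpoint,
)
from .objectives import Discretizer, fit_discretizer
from .training import TrainConfig, train


class MultimodalSurvivalModel:
    """Discrete-time survival model over gated multimodal fusion.

    Parameters
    ----------
    cohort : Cohort
        Patient records with pooled features and survival labels.
    config : ModelConfig, optional
        Architecture settings; the number of hazard heads defaults to the
        number of cancer types in the cohort.
    standardize : bool
        Z-score features per modality using training-split statistics
        (recommended; absent modalities remain exact zeros).
    """

    def __init__(
        self,
        cohort: Cohort,
        config: ModelConfig | None = None,
        standardize: bool = True,
    ):
        self.cohort = cohort
        self.cancer_types = cohort.cancer_types
        if config is None:
            config = ModelConfig(C=len(self.cancer_types))
        if config.C < len(self.cancer_types):
            raise ValueError(
                f"config.C={config.C} < {len(self.cancer_types)} cancer types"
            )
        self.config = config
        self.standardize = standardize

    @classmethod
    def from_csv(cls, data_dir: str | Path, **kwargs) -> "MultimodalSurvivalModel":
        return cls(Cohort.from_csv(data_dir), **kwargs)

    # -- internals ------------------------------------------------------------

    def _fit_standardizer(self, records) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Scale-only standardisation (unit variance, no centring).

        Centring is deliberately avoided: the missing-modality contract
        substitutes the zero tensor, and centring would silently turn that
        into mean-imputation, changing the semantics of absence for any
        fusion scheme that sees the raw zeros.
        """
        stats = {}
        for m in ("img", "rna", "txt"):
            rows = [getattr(r, m) for r in records if getattr(r, m) is not None]
            if rows:
                x = np.stack(rows)
                sd = x.std(axis=0)
                stats[m] = (np.zeros(x.shape[1]), np.where(sd > 0, sd, 1.0))
        return stats

    def _make_batch(
        self,
        records,
        discretizer: Discretizer,
        standardizer: dict | None,
    ) -> Batch:
        labelled = [discretizer.label(r.time, r.event, r.cancer_type) for r in records]
        tau = [lab[0] for lab in labelled]
        if standardizer:
            std_records = []
            for r in records:
                r = r.copy()
                for m in ("img", "rna", "txt"):
                    value = getattr(r, m)
                    if value is not None and m in standardizer:
                        mu, sd = standardizer[m]
                        setattr(r, m, (value - mu) / sd)
                std_records.append(r)
            records = std_records
        batch = build_batch(records, self.cancer_types, tau)
        batch.event = np.array([lab[1] for lab in labelled], dtype=np.int64)
        return batch

    # -- fitting --------------------------------------------------------------

    def fit(
        self,
        split: SplitSpec | None = None,
        train_config: TrainConfig | None = None,
        seed: int = 0,
    ) -> "SurvivalFit":
        """Train with validation-based checkpoint selection.

        If no split is given, a stratified 4:2:4 patient-level split is
        drawn from ``seed``.  The discretizer (per-cancer event-time
        quantile bins) and feature standardiser are fitted on the training
        split only.
        """
        if train_config is None:
            train_config = TrainConfig(seed=seed)
        if split is None:
            split = make_split(self.cohort, (4, 2, 4), "patient", seed)
        train_records = self.cohort.subset(split.train).records
        val_records = self.cohort.subset(split.val).records
        discretizer = fit_discretizer(
            [r.time for r in train_records],
            [r.event for r in train_records],
            [r.cancer_type for r in train_records],
            T=self.config.T,
        )
        standardizer = self._fit_standardizer(train_records) if self.standardize else None
        train_batch = self._make_batch(train_records, discretizer, standardizer)
        val_batch = self._make_batch(val_records, discretizer, standardizer)
        rng_init = np.random.default_rng(np.random.SeedSequence([seed, 0x1417]))
        params = Params(init_params(self.config, rng_init))
        arrays, history = train(
            params,
            self.config,
            train_batch,
            val_batch,
            np.array([r.time for r in val_records]),
            np.array([r.event for r in val_records]),
            np.array([r.cancer_type for r in val_records], dtype=object),
            train_config,
        )
        return SurvivalFit(
            model=self,
            params=arrays,
            history=history,
            discretizer=discretizer,
            standardizer=standardizer,
            split=split,
            seed=seed,
            train_config=train_config,
        )


@dataclasses.dataclass
class SurvivalFit:
    """Fitted parameters plus everything needed to predict and evaluate."""

    model: MultimodalSurvivalModel
    params: dict[str, np.ndarray]
    history: pd.DataFrame
    discretizer: Discretizer
    standardizer: dict | None
    split: SplitSpec
    seed: int
    train_config: TrainConfig

    # -- prediction -----------------------------------------------------------

    def predict(self, cohort: Cohort | None = None) -> HazardPrediction:
        """Eval-mode hazards, survival curves, risks and gate weights."""
        cohort = cohort if cohort is not None else self.model.cohort
        batch = self.model._make_batch(
            cohort.records, self.discretizer, self.standardizer
        )
        return _predict(batch, Params(self.params), self.model.config)

    def predict_frame(self, cohort: Cohort | None = None) -> pd.DataFrame:
        """Prediction table: hazards, survival, risk and fusion weights."""
        cohort = cohort if cohort is not None else self.model.cohort
        pred = self.predict(cohort)
        T = self.model.config.T
        frame = {"patient_id": pred.patient_ids,
                 "cancer_type": [r.cancer_type for r in cohort]}
        for t in range(T):
            frame[f"hazard_{t + 1}"] = pred.hazards[:, t]
        for t in range(T):
            frame[f"surv_{t + 1}"] = pred.survival[:, t]
        frame["risk"] = pred.risk
        for j, m in enumerate(("w_img", "w_rna", "w_txt")):
            frame[m] = pred.gate[:, j]
        return pd.DataFrame(frame)

    # -- evaluation -----------------------------------------------------------

    def c_index_table(self, cohort: Cohort | None = None) -> pd.DataFrame:
        """Per-cancer concordance of predicted risks (test split default)."""
        if cohort is None:
            cohort = self.model.cohort.subset(self.split.test)
        pred = self.predict(cohort)
        return evaluate_risks(pred.risk, cohort)

    def summary(self) -> str:
        table = self.c_index_table()
        lines = [
            "Multimodal discrete-time survival fit",
            "=" * 45,
            f"cancer types: {len(self.model.cancer_types)}"
            f"  time bins: {self.model.config.T}"
            f"  fusion: {self.model.config.fusion}",
            f"split: {self.split.mode} {':'.join(map(str, self.split.ratios))}"
            f"  seed: {self.seed}",
            f"epochs run: {len(self.history)}"
            f"  best val C-index: {self.history.attrs['best_val_cindex']:.3f}"
            f" (epoch {self.history.attrs['best_epoch']})",
            "",
            "test C-index by cancer type",
            "-" * 45,
        ]
        for row in table.itertuples(index=False):
            lines.append(f"  {row.cancer_type:<12} n={row.n:<5d} C-index {row.c_index:.3f}")
        lines.append("-" * 45)
        lines.append(f"  mean (unweighted)      C-index {table['c_index'].mean():.3f}")
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = {
            "seed": self.seed,
            "cancer_types": self.model.cancer_types,
            "discretizer": json.loads(self.discretizer.to_json()),
            "split": json.loads(self.split.to_json()),
            "standardizer": None
            if self.standardizer is None
            else {m: [mu.tolist(), sd.tolist()] for m, (mu, sd) in self.standardizer.items()},
        }
        save_checkpoint(path, self.params, self.model.config, meta)

    @classmethod
    def load(cls, path: str | Path, cohort: Cohort) -> "SurvivalFit":
        arrays, config, meta = load_checkpoint(path)
        model = MultimodalSurvivalModel(cohort, config=config)
        model.cancer_types = meta["cancer_types"]
        standardizer = meta["standardizer"]
        if standardizer is not None:
            standardizer = {
                m: (np.asarray(mu), np.asarray(sd)) for m, (mu, sd) in standardizer.items()
            }
        return cls(
            model=model,
            params=arrays,
            history=pd.DataFrame(),
            discretizer=Discretizer.from_json(json.dumps(meta["discretizer"])),
            standardizer=standardizer,
            split=SplitSpec.from_json(json.dumps(meta["split"])),
            seed=meta["seed"],
            train_config=TrainConfig(seed=meta["seed"]),
        )

    # -- plotting -------------------------------------------------------------

    def plot_survival(self, cohort: Cohort | None = None, ax=None):
        """Step plot of predicted discrete survival curves."""
        import matplotlib.pyplot as plt

        pred = self.predict(cohort)
        if ax is None:
            _, ax = plt.subplots()
        T = self.model.config.T
        bins = np.arange(0, T + 1)
        for i, pid in enumerate(pred.patient_ids):
            curve = np.concatenate([[1.0], pred.survival[i]])
            ax.step(bins, curve, where="post", alpha=0.6, label=pid)
        ax.set_xlabel("time bin")
        ax.set_ylabel("predicted survival probability")
        ax.set_ylim(0, 1.02)
        if len(pred.patient_ids) <= 10:
            ax.legend(fontsize="small")
        return ax


def multi_seed_experiment(
    cohort_for_seed: Callable[[int], Cohort] | Cohort,
    seeds: Sequence[int] = DEFAULT_SEEDS,
    config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    ratios: tuple[int, int, int] = (4, 2, 4),
    split_mode: str = "patient",
    missing: tuple[str, float] | None = None,
) -> ExperimentResult:
    """Full train + evaluate per seed; aggregate per-cancer C-indices.

    ``cohort_for_seed`` is either a fixed cohort (resplit per seed) or a
    callable generating one per seed.  ``missing = (modality, fraction)``
    applies the evaluation-time missing-modality protocol to the test split.
    Any seed failure aborts with a partial-results manifest attached.
    """
    rows = []
    try:
        for seed in seeds:
            cohort = (
                cohort_for_seed(seed) if callable(cohort_for_seed) else cohort_for_seed
            )
            model = MultimodalSurvivalModel(cohort, config=config)
            tc = (
                dataclasses.replace(train_config, seed=seed)
                if train_config is not None
                else TrainConfig(seed=seed)
            )
            split = make_split(cohort, ratios, split_mode, seed)
            fit = model.fit(split=split, train_config=tc, seed=seed)
            test = cohort.subset(split.test)
            if missing is not None:
                test = missing_modality_protocol(test, missing[0], missing[1], seed)
            table = fit.c_index_table(test)
            for row in table.itertuples(index=False):
                rows.append(
                    {"seed": seed, "cancer_type": row.cancer_type, "c_index": row.c_index}
                )
    except Exception as exc:
        raise RuntimeError(
            f"multi-seed experiment aborted at seed {seed}; "
            f"partial results: {rows!r}"
        ) from exc
    return ExperimentResult(
        per_seed=pd.DataFrame(rows),
        provenance={
            "seeds": list(seeds),
            "ratios": list(ratios),
            "split_mode": split_mode,
            "missing": None if missing is None else list(missing),
        },
    )
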