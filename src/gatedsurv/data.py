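"""Patient records, cohorts and training batches.

A :class:`PatientRecord` carries one patient's pooled modality features
(histopathology always present; RNA and clinical-text embeddings optional),
the cancer type, the contributing institution (tissue source site) and the
survival label.  A :class:`Cohort` is an ordered collection of records with
tabular import/export, and :func:`build_batch` stacks records into the dense
arrays + availability mask the model consumes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

#: modality order used everywhere: image, RNA, text (fixed concat order)
MODALITIES = ("img", "rna", "txt")
#: pooled feature widths per modality
MODALITY_DIMS = {"img": 2048, "rna": 256, "txt": 768}


@dataclasses.dataclass
class PatientRecord:
    """One patient's pooled features, availability flags and survival label."""

    patient_id: str
    cancer_type: str
    institution: str
    time: float  # follow-up in days
    event: int  # 1 = event observed, 0 = right-censored
    img: np.ndarray
    rna: np.ndarray | None = None
    txt: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"{self.patient_id}: survival time must be positive")
        if self.event not in (0, 1):
            raise ValueError(f"{self.patient_id}: event indicator must be 0 or 1")
        self.img = np.asarray(self.img, dtype=np.float64)
        if self.img.shape != (MODALITY_DIMS["img"],):
            raise ValueError(
                f"{self.patient_id}: img features must have shape "
                f"({MODALITY_DIMS['img']},), got {self.img.shape}"
            )
        for name in ("rna", "txt"):
            value = getattr(self, name)
            if value is not None:
                value = np.asarray(value, dtype=np.float64)
                if value.shape != (MODALITY_DIMS[name],):
                    raise ValueError(
                        f"{self.patient_id}: {name} features must have shape "
                        f"({MODALITY_DIMS[name]},), got {value.shape}"
                    )
                setattr(self, name, value)
        if not np.all(np.isfinite(self.img)):
            raise ValueError(f"{self.patient_id}: non-finite img features")

    @property
    def availability(self) -> np.ndarray:
        """Binary availability over (img, rna, txt); img is always 1."""
        return np.array(
            [1, int(self.rna is not None), int(self.txt is not None)], dtype=np.int64
        )

    def copy(self) -> "PatientRecord":
        return dataclasses.replace(
            self,
            img=self.img.copy(),
            rna=None if self.rna is None else self.rna.copy(),
            txt=None if self.txt is None else self.txt.copy(),
        )


class Cohort:
    """Ordered collection of patient records with tabular import/export."""

    def __init__(self, records: Iterable[PatientRecord]):
        self.records: list[PatientRecord] = list(records)
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient ids in cohort")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, key):
        if isinstance(key, (list, np.ndarray)):
            return Cohort([self.records[i] for i in key])
        return self.records[key]

    @property
    def cancer_types(self) -> list[str]:
        return sorted({r.cancer_type for r in self.records})

    @property
    def institutions(self) -> list[str]:
        return sorted({r.institution for r in self.records})

    def subset(self, patient_ids: Sequence[str]) -> "Cohort":
        wanted = set(patient_ids)
        return Cohort([r for r in self.records if r.patient_id in wanted])

    def copy(self) -> "Cohort":
        return Cohort([r.copy() for r in self.records])

    # -- tabular IO -----------------------------------------------------------

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in self.records],
                "cancer_type": [r.cancer_type for r in self.records],
                "institution": [r.institution for r in self.records],
                "time_days": [r.time for r in self.records],
                "event": [r.event for r in self.records],
            }
        )

    def features_frame(self) -> pd.DataFrame:
        """Pooled-feature table: img_* always, rna_*/txt_* where available."""
        rows = []
        for r in self.records:
            row: dict[str, object] = {"patient_id": r.patient_id}
            row.update({f"img_{j}": v for j, v in enumerate(r.img)})
            row["has_rna"] = r.rna is not None
            row["has_txt"] = r.txt is not None
            if r.rna is not None:
                row.update({f"rna_{j}": v for j, v in enumerate(r.rna)})
            if r.txt is not None:
                row.update({f"txt_{j}": v for j, v in enumerate(r.txt)})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.labels_frame().to_csv(out_dir / "labels.csv", index=False)
        self.features_frame().to_csv(out_dir / "features.csv", index=False)

    @classmethod
    def from_csv(cls, in_dir: str | Path) -> "Cohort":
        in_dir = Path(in_dir)
        labels = pd.read_csv(in_dir / "labels.csv")
        feats = pd.read_csv(in_dir / "features.csv").set_index("patient_id")
        img_cols = [f"img_{j}" for j in range(MODALITY_DIMS["img"])]
        rna_cols = [f"rna_{j}" for j in range(MODALITY_DIMS["rna"])]
        txt_cols = [f"txt_{j}" for j in range(MODALITY_DIMS["txt"])]
        records = []
        for row in labels.itertuples(index=False):
            frow = feats.loc[row.patient_id]
            rna = frow[rna_cols].to_numpy(float) if frow["has_rna"] else None
            txt = frow[txt_cols].to_numpy(float) if frow["has_txt"] else None
            records.append(
                PatientRecord(
                    patient_id=str(row.patient_id),
                    cancer_type=str(row.cancer_type),
                    institution=str(row.institution),
                    time=float(row.time_days),
                    event=int(row.event),
                    img=frow[img_cols].to_numpy(float),
                    rna=rna,
                    txt=txt,
                )
            )
        return cls(records)


@dataclasses.dataclass
class Batch:
    """Stacked pooled features with availability mask and labels.

    ``mask`` is B×3 binary over (img, rna, txt) with the image column all
    ones; rows of ``x_rna``/``x_txt`` are exactly zero wherever the mask is 0.
    ``cancer_index`` holds 0-based head indices; ``tau`` the 1-based time bin.
    """

    patient_ids: list[str]
    x_img: np.ndarray
    x_rna: np.ndarray
    x_txt: np.ndarray
    mask: np.ndarray
    cancer_index: np.ndarray
    tau: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("availability mask must be binary")
        if not np.all(self.mask[:, 0] == 1):
            raise ValueError("pathological image modality must be available")
        for x, col in ((self.x_rna, 1), (self.x_txt, 2)):
            absent = self.mask[:, col] == 0
            if absent.any() and np.any(x[absent] != 0.0):
                raise ValueError("unavailable modality rows must be zero")

    def __len__(self) -> int:
        return len(self.patient_ids)

    def take(self, idx: np.ndarray) -> "Batch":
        return Batch(
            patient_ids=[self.patient_ids[i] for i in idx],
            x_img=self.x_img[idx],
            x_rna=self.x_rna[idx],
            x_txt=self.x_txt[idx],
            mask=self.mask[idx],
            cancer_index=self.cancer_index[idx],
            tau=self.tau[idx],
            event=self.event[idx],
        )


def build_batch(
    records: Sequence[PatientRecord],
    cancer_types: Sequence[str],
    tau: Sequence[int],
) -> Batch:
    """Stack records into a dense batch; absent modalities become zero rows."""
    index = {c: i for i, c in enumerate(cancer_types)}
    n = len(records)
    x_img = np.zeros((n, MODALITY_DIMS["img"]))
    x_rna = np.zeros((n, MODALITY_DIMS["rna"]))
    x_txt = np.zeros((n, MODALITY_DIMS["txt"]))
    mask = np.zeros((n, 3), dtype=np.int64)
    cancer_index = np.zeros(n, dtype=np.int64)
    for i, r in enumerate(records):
        if r.cancer_type not in index:
            raise KeyError(f"unknown cancer type {r.cancer_type!r}")
        x_img[i] = r.img
        mask[i, 0] = 1
        if r.rna is not None:
            x_rna[i] = r.rna
            mask[i, 1] = 1
        if r.txt is not None:
            x_txt[i] = r.txt
            mask[i, 2] = 1
        cancer_index[i] = index[r.cancer_type]
    return Batch(
        patient_ids=[r.patient_id for r in records],
        x_img=x_img,
        x_rna=x_rna,
        x_txt=x_txt,
        mask=mask,
        cancer_index=cancer_index,
        tau=np.asarray(tau, dtype=np.int64),
        event=np.array([r.event for r in records], dtype=np.int64),
    )
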