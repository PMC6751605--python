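"""Pedigree container shared by all modules.

Animals are stored in topological order (parents before offspring) and are
referenced throughout the package by their positional index; ``sire`` and
``dam`` hold positional indices with ``-1`` for an unknown parent.  The
CSV form uses animal identifiers with ``0`` for an unknown parent.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd


@dataclasses.dataclass
class Pedigree:
    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    time_step: np.ndarray
    environment: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.sex = np.asarray(self.sex, dtype="<U1")
        self.time_step = np.asarray(self.time_step, dtype=np.int64)
        if self.environment is not None:
            self.environment = np.asarray(self.environment, dtype="<U1")

    @property
    def n(self) -> int:
        return len(self.ids)

    def validate(self) -> None:
        n = self.n
        if len(np.unique(self.ids)) != n:
            raise ValueError("duplicate animal identifiers")
        for name, parent in (("sire", self.sire), ("dam", self.dam)):
            if np.any(parent >= np.arange(n)):
                bad = int(np.argmax(parent >= np.arange(n)))
                raise ValueError(
                    f"pedigree not topologically ordered: {name} of animal at "
                    f"position {bad} does not precede it"
                )
            if np.any(parent < -1):
                raise ValueError(f"invalid {name} index")

    def index_of(self, labels: np.ndarray) -> np.ndarray:
        """Positional indices of the given animal identifiers."""
        lookup = pd.Index(self.ids)
        pos = lookup.get_indexer(np.asarray(labels, dtype=np.int64))
        if np.any(pos < 0):
            missing = np.asarray(labels)[pos < 0][:5]
            raise KeyError(f"animals not in pedigree: {missing}")
        return pos

    def founders(self) -> np.ndarray:
        return np.flatnonzero((self.sire < 0) & (self.dam < 0))

    def to_frame(self) -> pd.DataFrame:
        sire_id = np.where(self.sire >= 0, self.ids[np.maximum(self.sire, 0)], 0)
        dam_id = np.where(self.dam >= 0, self.ids[np.maximum(self.dam, 0)], 0)
        df = pd.DataFrame(
            {
                "animal": self.ids,
                "sire": sire_id,
                "dam": dam_id,
                "sex": self.sex,
                "time_step": self.time_step,
            }
        )
        if self.environment is not None:
            df["environment"] = self.environment
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        ids = df["animal"].to_numpy(np.int64)
        lookup = pd.Index(ids)

        def to_pos(col: pd.Series) -> np.ndarray:
            labels = col.to_numpy(np.int64)
            pos = lookup.get_indexer(labels)
            pos[labels == 0] = -1
            if np.any((pos < 0) & (labels != 0)):
                raise ValueError("parent identifier absent from pedigree")
            return pos

        env = df["environment"].to_numpy("<U1") if "environment" in df else None
        ped = cls(
            ids=ids,
            sire=to_pos(df["sire"]),
            dam=to_pos(df["dam"]),
            sex=df["sex"].to_numpy("<U1"),
            time_step=df["time_step"].to_numpy(np.int64),
            environment=env,
        )
        ped.validate()
        return ped

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path))
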