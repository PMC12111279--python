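"""Pedigree container and validation.

A pedigree is an ordered list of animals with sire/dam links, sex and a
genotyped flag. Internally animals are stored by dense 0-based position;
``-1`` marks an unknown parent. On disk the conventional 1-based coding with
``0`` for an unknown parent is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Pedigree", "PedigreeError"]

MALE = 0
FEMALE = 1

UNKNOWN = -1


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (unordered, cyclic, bad links)."""


@dataclass
class Pedigree:
    """Ordered pedigree: parents precede offspring.

    Parameters
    ----------
    sire, dam
        0-based positions of the parents, ``-1`` if unknown.
    sex
        0 = male (stallion), 1 = female (mare).
    genotyped
        Boolean flag per animal; defines the genotyped block of H.
    ids
        Optional external labels; defaults to ``1..n`` as strings of ints.
    """

    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    genotyped: np.ndarray = None  # type: ignore[assignment]
    ids: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.sex = np.asarray(self.sex, dtype=np.int64)
        n = self.sire.size
        if self.dam.size != n or self.sex.size != n:
            raise PedigreeError("sire, dam and sex must have equal length")
        if self.genotyped is None:
            self.genotyped = np.zeros(n, dtype=bool)
        self.genotyped = np.asarray(self.genotyped, dtype=bool)
        if self.ids is None:
            self.ids = np.arange(1, n + 1)
        self.ids = np.asarray(self.ids)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return self.sire.size

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    @property
    def females(self) -> np.ndarray:
        return np.flatnonzero(self.sex == FEMALE)

    @property
    def males(self) -> np.ndarray:
        return np.flatnonzero(self.sex == MALE)

    @property
    def genotyped_index(self) -> np.ndarray:
        return np.flatnonzero(self.genotyped)

    def validate(self) -> None:
        """Check ordering (parents precede offspring) and link sanity."""
        n = self.n
        idx = np.arange(n)
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            known = par != UNKNOWN
            if np.any((par[known] < 0) | (par[known] >= n)):
                raise PedigreeError(f"{name} links out of range")
            if np.any(par[known] >= idx[known]):
                bad = int(np.flatnonzero(known & (par >= idx))[0])
                raise PedigreeError(
                    f"pedigree not ordered: animal {bad} has {name} {int(par[bad])} "
                    "at or after its own position; recode so parents precede offspring"
                )
        if not np.all(np.isin(self.sex, (MALE, FEMALE))):
            raise PedigreeError("sex must be coded 0 (male) / 1 (female)")
        # parents must have consistent sex where known
        s = self.sire[self.sire != UNKNOWN]
        d = self.dam[self.dam != UNKNOWN]
        if np.any(self.sex[s] != MALE):
            raise PedigreeError("a dam appears as a sire (sex inconsistency)")
        if np.any(self.sex[d] != FEMALE):
            raise PedigreeError("a sire appears as a dam (sex inconsistency)")

    # ------------------------------------------------------------------
    def progeny_counts(self) -> np.ndarray:
        """Number of recorded offspring per animal (as sire or dam)."""
        counts = np.zeros(self.n, dtype=np.int64)
        for par in (self.sire, self.dam):
            known = par[par != UNKNOWN]
            np.add.at(counts, known, 1)
        return counts

    def to_frame(self) -> pd.DataFrame:
        """1-based encoding with 0 for unknown parents."""
        return pd.DataFrame(
            {
                "animal": np.arange(1, self.n + 1),
                "sire": np.where(self.sire == UNKNOWN, 0, self.sire + 1),
                "dam": np.where(self.dam == UNKNOWN, 0, self.dam + 1),
                "sex": self.sex,
                "birth_order": np.arange(1, self.n + 1),
                "genotyped": self.genotyped.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        sire = frame["sire"].to_numpy(dtype=np.int64) - 1
        dam = frame["dam"].to_numpy(dtype=np.int64) - 1
        geno = (
            frame["genotyped"].to_numpy(dtype=bool)
            if "genotyped" in frame.columns
            else None
        )
        return cls(
            sire=sire,
            dam=dam,
            sex=frame["sex"].to_numpy(dtype=np.int64),
            genotyped=geno,
        )
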