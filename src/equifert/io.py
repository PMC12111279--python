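"""Plain-text readers and writers.

All on-disk animal identifiers are 1-based with 0 for an unknown parent
(the studbook convention); in memory everything is 0-based positions.
Formats: pedigree CSV, foaling-record CSV, phenotype/trait CSV, truth CSV,
PLINK PED/MAP text, dosage CSV, and coordinate-triplet matrix text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pedigree import Pedigree
from .relmat import GenotypeMatrix
from .traits import ReproHistory

__all__ = [
    "write_pedigree_csv", "read_pedigree_csv",
    "write_foaling_csv", "read_foaling_csv",
    "write_phenotypes_csv", "read_phenotypes_csv",
    "write_plink", "read_plink",
    "write_dosage_csv", "read_dosage_csv",
    "write_matrix_triplets", "read_matrix_triplets",
]


# -- pedigree ----------------------------------------------------------


def write_pedigree_csv(pedigree: Pedigree, path) -> None:
    pedigree.to_frame().to_csv(path, index=False)


def read_pedigree_csv(path) -> Pedigree:
    return Pedigree.from_frame(pd.read_csv(path))


# -- foaling records ---------------------------------------------------


def write_foaling_csv(histories: list[ReproHistory], path) -> None:
    """Long format: one row per foaling (mare_id, foaling_age_months),
    plus the mare's culling age repeated (empty if still active)."""
    rows = []
    for h in histories:
        for age in h.foaling_ages:
            rows.append(
                {
                    "mare_id": h.mare_id,
                    "foaling_age_months": age,
                    "culling_age_months": h.culling_age,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_foaling_csv(path) -> list[ReproHistory]:
    df = pd.read_csv(path)
    histories = []
    for mare, grp in df.groupby("mare_id", sort=False):
        cull = grp["culling_age_months"].iloc[0]
        histories.append(
            ReproHistory(
                mare_id=mare,
                foaling_ages=sorted(grp["foaling_age_months"].tolist()),
                culling_age=None if pd.isna(cull) else float(cull),
            )
        )
    return histories


# -- phenotypes / traits ----------------------------------------------


def write_phenotypes_csv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    if "animal" in out.columns:
        out["animal"] = out["animal"] + 1  # 1-based on disk
    out.to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "animal" in table.columns:
        table["animal"] = table["animal"] - 1
    return table


# -- PLINK PED/MAP text ------------------------------------------------

_ALLELES = ("A", "B")


def write_plink(genotypes: GenotypeMatrix, prefix, pedigree: Pedigree | None = None):
    """PED/MAP text files; dosage d is coded as d copies of allele B,
    missing as '0 0'. Returns the two paths."""
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for i, snp in enumerate(genotypes.snp_ids):
            fh.write(f"1 {snp} 0 {i + 1}\n")
    with open(ped_path, "w") as fh:
        for r, animal in enumerate(genotypes.animal_index):
            if pedigree is not None:
                sire = pedigree.sire[animal] + 1 if pedigree.sire[animal] >= 0 else 0
                dam = pedigree.dam[animal] + 1 if pedigree.dam[animal] >= 0 else 0
                sex = 1 if pedigree.sex[animal] == 0 else 2
            else:
                sire = dam = 0
                sex = 0
            fields = ["FAM", str(animal + 1), str(sire), str(dam), str(sex), "-9"]
            for d in genotypes.dosages[r]:
                if np.isnan(d):
                    fields += ["0", "0"]
                else:
                    k = int(round(d))
                    fields += [_ALLELES[1]] * k + [_ALLELES[0]] * (2 - k)
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def read_plink(prefix) -> GenotypeMatrix:
    """Read PED/MAP text back into a dosage matrix (B-allele count)."""
    prefix = Path(prefix)
    snp_ids = []
    with open(prefix.with_suffix(".map")) as fh:
        for line in fh:
            parts = line.split()
            if parts:
                snp_ids.append(parts[1])
    m = len(snp_ids)
    dosages, animals = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            animals.append(int(parts[1]) - 1)
            alleles = parts[6:]
            if len(alleles) != 2 * m:
                raise ValueError(
                    f"PED row for animal {parts[1]} has {len(alleles)} alleles, "
                    f"expected {2 * m}"
                )
            row = np.empty(m)
            for i in range(m):
                a, b = alleles[2 * i], alleles[2 * i + 1]
                if a == "0" or b == "0":
                    row[i] = np.nan
                else:
                    row[i] = (a == _ALLELES[1]) + (b == _ALLELES[1])
            dosages.append(row)
    return GenotypeMatrix(
        dosages=np.array(dosages),
        animal_index=np.array(animals, dtype=np.int64),
        snp_ids=np.array(snp_ids),
    )


# -- dosage CSV --------------------------------------------------------


def write_dosage_csv(genotypes: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(genotypes.dosages, columns=genotypes.snp_ids)
    df.insert(0, "animal", genotypes.animal_index + 1)
    df.to_csv(path, index=False)


def read_dosage_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path)
    animals = df.pop("animal").to_numpy(dtype=np.int64) - 1
    return GenotypeMatrix(
        dosages=df.to_numpy(dtype=float),
        animal_index=animals,
        snp_ids=np.array(df.columns),
    )


# -- matrix triplets ---------------------------------------------------


def write_matrix_triplets(M, path) -> None:
    """Coordinate text (i, j, value), 1-based, lower triangle of a
    symmetric matrix included fully (both triangles written for clarity
    of round-trips)."""
    M = sp.coo_matrix(M)
    with open(path, "w") as fh:
        fh.write(f"# {M.shape[0]} {M.shape[1]}\n")
        for i, j, v in zip(M.row, M.col, M.data):
            fh.write(f"{i + 1} {j + 1} {float(v)!r}\n")


def read_matrix_triplets(path) -> sp.csr_matrix:
    with open(path) as fh:
        header = fh.readline().split()
        shape = (int(header[1]), int(header[2]))
        rows, cols, vals = [], [], []
        for line in fh:
            i, j, v = line.split()
            rows.append(int(i) - 1)
            cols.append(int(j) - 1)
            vals.append(float(v))
    return sp.coo_matrix((vals, (rows, cols)), shape=shape).tocsr()
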