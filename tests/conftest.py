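import numpy as np
import pytest

import equifert as eq
from equifert.relmat import qc_filter


@pytest.fixture(scope="session")
def small_dataset():
    """~320-animal population with genotypes, histories and phenotypes."""
    cfg = eq.SimConfig(
        n_founders=80, n_generations=3, n_snps=600, seed=202, prop_genotyped=0.25
    )
    return cfg, eq.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_matrices(small_dataset):
    """A, F, Ainv, G, H, Hinv for the small population."""
    cfg, (ped, geno, hist, table, truth) = small_dataset
    A = eq.build_A(ped)
    F = eq.inbreeding(ped)
    Ainv = eq.build_Ainv(ped, F)
    gi = ped.genotyped_index
    qc = qc_filter(eq.GenotypeMatrix(dosages=geno.dosages[gi], animal_index=gi))
    A22 = A[np.ix_(qc.animal_index, qc.animal_index)]
    G = eq.build_G(qc, A22)
    Hinv = eq.build_Hinv(Ainv, G, A22, qc.animal_index)
    H = eq.build_H(A, G, qc.animal_index)
    return {"A": A, "F": F, "Ainv": Ainv, "G": G, "A22": A22,
            "Hinv": Hinv, "H": H, "geno_idx": qc.animal_index}


def make_pedigree(triples, sex=None):
    """Pedigree from 1-based (animal, sire, dam) triples, 0 = unknown."""
    triples = np.asarray(triples)
    sire = triples[:, 1] - 1
    dam = triples[:, 2] - 1
    n = len(triples)
    if sex is None:
        sex = np.zeros(n, dtype=int)
        sex[dam[dam >= 0]] = 1
        # any animal never used as parent: alternate to keep both sexes
        used = set(sire[sire >= 0]) | set(dam[dam >= 0])
        free = [i for i in range(n) if i not in used]
        for k, i in enumerate(free):
            sex[i] = k % 2
    return eq.Pedigree(sire=sire, dam=dam, sex=np.asarray(sex))
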