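"""High-level workflows tying the pipeline together.

Builds every relationship matrix from one population, and runs the paired
pedigree vs single-step evaluation that the reliability comparison needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import relmat
from .mme import ModelSpec
from .pedigree import Pedigree
from .relmat import GenotypeMatrix
from .reml import FitResult, VarianceComponents, blup_evaluate, estimate_reml, stack_fits

__all__ = ["RelMatrices", "build_matrices", "paired_single_trait_evaluation"]


@dataclass
class RelMatrices:
    """All relationship matrices of one evaluation."""

    A: np.ndarray
    F: np.ndarray
    Ainv: sp.csr_matrix
    A22: np.ndarray | None
    G: np.ndarray | None
    Hinv: sp.csr_matrix | None
    H: np.ndarray | None
    genotyped_index: np.ndarray
    n_snps: int = 0  # SNPs surviving quality control


def build_matrices(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix | None = None,
    min_call_rate: float = 0.95,
    min_maf: float = 0.05,
    blend: float = 0.95,
) -> RelMatrices:
    """A, F, A^-1 and, when genotypes are given, QC'd G, H and H^-1.

    ``genotypes`` may cover the whole pedigree; the genotyped panel is
    taken from the pedigree's flags before quality control.
    """
    A = relmat.build_A(pedigree)
    F = relmat.inbreeding(pedigree)
    Ainv = relmat.build_Ainv(pedigree, F)
    gi = pedigree.genotyped_index
    if genotypes is None or gi.size == 0:
        return RelMatrices(A=A, F=F, Ainv=Ainv, A22=None, G=None,
                           Hinv=None, H=None, genotyped_index=np.array([], int))
    rows = np.flatnonzero(np.isin(genotypes.animal_index, gi))
    panel = GenotypeMatrix(
        dosages=genotypes.dosages[rows],
        animal_index=genotypes.animal_index[rows],
        snp_ids=genotypes.snp_ids,
    )
    qc = relmat.qc_filter(panel, min_call_rate=min_call_rate, min_maf=min_maf)
    A22 = A[np.ix_(qc.animal_index, qc.animal_index)]
    G = relmat.build_G(qc, A22, blend=blend)
    Hinv = relmat.build_Hinv(Ainv, G, A22, qc.animal_index)
    H = relmat.build_H(A, G, qc.animal_index)
    return RelMatrices(A=A, F=F, Ainv=Ainv, A22=A22, G=G, Hinv=Hinv, H=H,
                       genotyped_index=qc.animal_index, n_snps=qc.n_snps)


def paired_single_trait_evaluation(
    pedigree: Pedigree,
    matrices: RelMatrices,
    table,
    vc_per_trait: dict,
    traits: tuple,
    estimate: bool = False,
    **reml_kwargs,
) -> tuple[FitResult, FitResult]:
    """Evaluate each trait under A and under H, stacked into two fits.

    With ``estimate=False`` the given variance components are used as-is
    (isolating the relationship-matrix effect on reliability); with
    ``estimate=True`` components are re-estimated by REML per trait and
    per matrix.
    """
    fits = {}
    for key, Kinv, K in (("ped", matrices.Ainv, matrices.A),
                         ("ss", matrices.Hinv, matrices.H)):
        if Kinv is None:
            Kinv, K = matrices.Ainv, matrices.A
        per_trait = []
        for tr in traits:
            spec = ModelSpec.default((tr,))
            vc = vc_per_trait[tr]
            if estimate:
                fit = estimate_reml(spec, table, Kinv, start=vc, K=K,
                                    F=matrices.F, **reml_kwargs)
            else:
                fit = blup_evaluate(spec, table, Kinv, vc, F=matrices.F)
            per_trait.append(fit)
        fits[key] = stack_fits(per_trait)
    return fits["ped"], fits["ss"]
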