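"""Henderson's mixed model equations for the fertility evaluation.

The model per trait is ``y = Xb + Za + e`` with ``var(a) = K (x) G0`` (K is
A for the pedigree model or H for single-step) and a residual covariance
``R0`` across traits. Each mare carries at most one record per trait;
missing traits are handled by inverting the observed-trait submatrix of R0
per missing-data pattern (the canonical unequal-design treatment).

Effect ordering in the system: trait-wise fixed-effect blocks first, then
random animal effects animal-major / trait-minor, penalized by
``Kinv (x) G0^-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .traits import TRAIT_NAMES

__all__ = ["ModelSpec", "ModelError", "MMESystem", "assemble_mme", "solve_blup",
           "build_design", "AGE_EXEMPT_TRAITS", "DEFAULT_CLASS_EFFECTS"]

AGE_EXEMPT_TRAITS = ("AFF", "ALF", "IF12")
DEFAULT_CLASS_EFFECTS = ("ancestral_origin", "geo_zone", "stud_size")


class ModelError(ValueError):
    """Raised for invalid model/data combinations (confounding, bad index)."""


@dataclass
class ModelSpec:
    """Fixed- and random-effect layout of the evaluation model.

    ``covariates[trait]`` lists covariate columns for that trait;
    ``class_effects`` are categorical columns whose first observed level is
    constrained to zero. ``relationship`` is bookkeeping only ("pedigree" or
    "single-step"): the matrix actually used is whatever ``Kinv`` is passed.
    """

    traits: tuple
    covariates: dict = None  # type: ignore[assignment]
    class_effects: tuple = DEFAULT_CLASS_EFFECTS
    intercept: bool = True
    relationship: str = "pedigree"

    def __post_init__(self) -> None:
        self.traits = tuple(self.traits)
        if self.covariates is None:
            self.covariates = {
                t: ("inbreeding",) if t in AGE_EXEMPT_TRAITS
                else ("inbreeding", "age_last_foaling")
                for t in self.traits
            }

    @classmethod
    def default(cls, traits=TRAIT_NAMES, relationship: str = "pedigree") -> "ModelSpec":
        """The standard fertility model: inbreeding covariate for every trait, age at
        last foaling except for the age traits, and the three class effects."""
        return cls(traits=tuple(traits), relationship=relationship)

    @classmethod
    def intercept_only(cls, traits, relationship: str = "pedigree") -> "ModelSpec":
        return cls(traits=tuple(traits), covariates={t: () for t in traits},
                   class_effects=(), relationship=relationship)


def build_design(table: pd.DataFrame, spec: ModelSpec, trait: str):
    """Fixed-effect design matrix over all table rows for one trait.

    Returns (D, labels). Class effects are one-hot with the first observed
    level dropped (constrained to zero).
    """
    cols = []
    labels = []
    n = len(table)
    if spec.intercept:
        cols.append(np.ones(n))
        labels.append(f"{trait}:intercept")
    for cov in spec.covariates.get(trait, ()):
        if cov not in table.columns:
            raise ModelError(f"covariate column {cov!r} missing from trait table")
        cols.append(table[cov].to_numpy(dtype=float))
        labels.append(f"{trait}:{cov}")
    for cls_col in spec.class_effects:
        if cls_col not in table.columns:
            raise ModelError(f"class column {cls_col!r} missing from trait table")
        levels = np.sort(pd.unique(table[cls_col].dropna()))
        for lev in levels[1:]:
            cols.append((table[cls_col] == lev).to_numpy(dtype=float))
            labels.append(f"{trait}:{cls_col}={lev}")
    D = np.column_stack(cols) if cols else np.zeros((n, 0))
    return D, labels


@dataclass
class MMESystem:
    """Assembled mixed model equations plus the pieces REML needs."""

    C: sp.csr_matrix
    rhs: np.ndarray
    spec: ModelSpec
    q: int  # animals in Kinv
    t: int  # traits
    p_offsets: list  # start column of each trait's fixed block
    p_total: int
    fixed_labels: list  # per trait
    designs: list  # per trait: D over table rows
    animal: np.ndarray  # table row -> Kinv index
    Y: np.ndarray  # table rows x t, NaN where missing
    obs_mask: np.ndarray  # table rows x t boolean
    patterns: dict  # observed-trait tuple -> table row indices
    G0: np.ndarray
    R0: np.ndarray
    Kinv: sp.spmatrix

    @property
    def n_eq(self) -> int:
        return self.p_total + self.q * self.t

    def random_index(self, animal: np.ndarray, trait: int) -> np.ndarray:
        return self.p_total + np.asarray(animal) * self.t + trait


def _pattern_groups(obs_mask: np.ndarray) -> dict:
    patterns: dict = {}
    keys = [tuple(np.flatnonzero(row)) for row in obs_mask]
    for r, key in enumerate(keys):
        if key:
            patterns.setdefault(key, []).append(r)
    return {k: np.asarray(v) for k, v in patterns.items()}


def assemble_mme(
    spec: ModelSpec,
    table: pd.DataFrame,
    Kinv: sp.spmatrix | np.ndarray,
    G0: np.ndarray,
    R0: np.ndarray,
) -> MMESystem:
    """Assemble Henderson's MME for the given variance components.

    ``table`` must hold an ``animal`` column (0-based index into Kinv) plus
    trait and effect columns; NaN trait cells are missing records. Traits
    with no records contribute no data and no fixed-effect equations.
    """
    t = len(spec.traits)
    q = Kinv.shape[0]
    G0 = np.asarray(G0, dtype=float).reshape(t, t)
    R0 = np.asarray(R0, dtype=float).reshape(t, t)
    animal = table["animal"].to_numpy(dtype=np.int64)
    if animal.size and (animal.min() < 0 or animal.max() >= q):
        bad = animal[(animal < 0) | (animal >= q)]
        raise ModelError(
            f"phenotyped animals absent from the relationship matrix: {bad[:5]}..."
        )
    if np.unique(animal).size != animal.size:
        raise ModelError("more than one row per animal in the trait table")

    Y = np.column_stack(
        [
            table[tr].to_numpy(dtype=float)
            if tr in table.columns
            else np.full(len(table), np.nan)
            for tr in spec.traits
        ]
    )
    obs_mask = ~np.isnan(Y)
    has_data = obs_mask.any(axis=0)

    designs, fixed_labels, p_offsets = [], [], []
    p_total = 0
    for j, tr in enumerate(spec.traits):
        if has_data[j]:
            D, labels = build_design(table, spec, tr)
        else:  # no records: drop the (unidentifiable) fixed block
            D, labels = np.zeros((len(table), 0)), []
        designs.append(D)
        fixed_labels.append(labels)
        p_offsets.append(p_total)
        p_total += D.shape[1]

    n_eq = p_total + q * t
    Cbb = np.zeros((p_total, p_total))
    rhs = np.zeros(n_eq)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    patterns = _pattern_groups(obs_mask)

    for key, S in patterns.items():
        O = list(key)
        Einv = np.linalg.inv(R0[np.ix_(O, O)])
        anim = animal[S]
        for jj, j in enumerate(O):
            Dj = designs[j][S]
            oj = p_offsets[j]
            for kk, k in enumerate(O):
                Dk = designs[k][S]
                ok = p_offsets[k]
                w = Einv[jj, kk]
                # fixed x fixed
                if Dj.shape[1] and Dk.shape[1]:
                    Cbb[oj : oj + Dj.shape[1], ok : ok + Dk.shape[1]] += (
                        w * Dj.T @ Dk
                    )
                # random x random (diagonal per animal)
                ra = p_total + anim * t + j
                rb = p_total + anim * t + k
                rows.append(ra)
                cols.append(rb)
                vals.append(np.full(S.size, w))
                # fixed x random (and transpose)
                if Dj.shape[1]:
                    for c in range(Dj.shape[1]):
                        rows.append(np.full(S.size, oj + c))
                        cols.append(rb)
                        vals.append(w * Dj[:, c])
                        rows.append(rb)
                        cols.append(np.full(S.size, oj + c))
                        vals.append(w * Dj[:, c])
            # right-hand side
            ytil = sum(Einv[jj, kk] * Y[S, k] for kk, k in enumerate(O))
            if Dj.shape[1]:
                rhs[oj : oj + Dj.shape[1]] += Dj.T @ ytil
            np.add.at(rhs, p_total + anim * t + j, ytil)

    data_coo = sp.coo_matrix(
        (np.concatenate(vals) if vals else np.array([]),
         (np.concatenate(rows) if rows else np.array([], dtype=int),
          np.concatenate(cols) if cols else np.array([], dtype=int))),
        shape=(n_eq, n_eq),
    )
    penalty = sp.kron(sp.csr_matrix(Kinv), np.linalg.inv(G0), format="coo")
    pen = sp.coo_matrix(
        (penalty.data, (penalty.row + p_total, penalty.col + p_total)),
        shape=(n_eq, n_eq),
    )
    C = (data_coo + pen).tocsr()
    C_bb = sp.coo_matrix(Cbb)
    C = (C + sp.csr_matrix((C_bb.data, (C_bb.row, C_bb.col)), shape=(n_eq, n_eq))).tocsr()

    return MMESystem(
        C=C, rhs=rhs, spec=spec, q=q, t=t, p_offsets=p_offsets, p_total=p_total,
        fixed_labels=fixed_labels, designs=designs, animal=animal, Y=Y,
        obs_mask=obs_mask, patterns=patterns, G0=G0, R0=R0,
        Kinv=sp.csr_matrix(Kinv),
    )


@dataclass
class BlupSolution:
    """Solutions of one MME solve."""

    sol: np.ndarray
    b: dict  # trait -> pd.Series of fixed-effect solutions
    a: np.ndarray  # q x t breeding values
    residual_norm: float


def _diagnose_singular(system: MMESystem) -> str:
    msgs = []
    for j, tr in enumerate(system.spec.traits):
        D = system.designs[j][system.obs_mask[:, j]]
        if D.shape[1] == 0:
            continue
        rank = np.linalg.matrix_rank(D)
        if rank < D.shape[1]:
            _, R = np.linalg.qr(D)
            dep = np.flatnonzero(np.abs(np.diag(R)) < 1e-8 * max(1, np.abs(R).max()))
            names = [system.fixed_labels[j][c] for c in dep]
            msgs.append(f"{tr}: confounded fixed-effect columns {names}")
    return "; ".join(msgs) or "coefficient matrix singular"


def solve_blup(system: MMESystem, method: str = "auto") -> BlupSolution:
    """Solve the assembled MME for fixed effects and breeding values.

    Direct sparse LU for desk-scale systems; ``method='cg'`` selects Jacobi
    preconditioned conjugate gradients. The solution is checked against the
    right-hand side (residual norm below 1e-8 of ||rhs||).
    """
    C, rhs = system.C, system.rhs
    try:
        if method == "cg":
            M = sp.diags(1.0 / C.diagonal())
            sol, info = spla.cg(C, rhs, M=M, rtol=1e-12, atol=0.0, maxiter=20000)
            if info != 0:
                raise ModelError(f"conjugate gradients did not converge (info={info})")
        else:
            sol = spla.spsolve(C.tocsc(), rhs)
        if not np.all(np.isfinite(sol)):
            raise ModelError(_diagnose_singular(system))
    except RuntimeError as exc:  # singular factorization
        raise ModelError(_diagnose_singular(system)) from exc
    res = np.linalg.norm(C @ sol - rhs)
    scale = np.linalg.norm(rhs)
    if scale > 0 and res > 1e-8 * scale:
        raise ModelError(
            f"solver residual {res:.2e} exceeds tolerance ({1e-8 * scale:.2e}); "
            + _diagnose_singular(system)
        )
    b = {}
    for j, tr in enumerate(system.spec.traits):
        oj = system.p_offsets[j]
        pj = system.designs[j].shape[1]
        b[tr] = pd.Series(sol[oj : oj + pj], index=system.fixed_labels[j])
    a = sol[system.p_total :].reshape(system.q, system.t)
    return BlupSolution(sol=sol, b=b, a=a, residual_norm=res)
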