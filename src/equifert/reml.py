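"""REML variance components and PEV reliabilities on the mixed model.

The estimator runs EM-REML with average-information (AI) acceleration on
Henderson's equations: each iterate factorizes the coefficient matrix C,
takes the EM update (always inside the parameter space) or an AI/Newton
step with step-halving when it improves the restricted likelihood, and
stops when every (co)variance component changes by less than ``tol`` in
relative terms.

Animals without records are absorbed before iterating: the restricted
likelihood depends on the relationship matrix only through its submatrix at
recorded animals, so variance components from the reduced system are exact.
The full system is solved once at convergence for breeding values and,
optionally, inverted once for prediction error variances (PEV).

Reliability per animal and trait defaults to the inbreeding-adjusted form

    r2_i = 1 - PEV_i / ((1 + F_i) sigma_a2)

with the unadjusted ``1 - PEV/sigma_a2`` behind a flag. Reported
log-likelihoods omit an additive constant that does not depend on the
variance components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve

from .mme import ModelSpec, MMESystem, assemble_mme, solve_blup

__all__ = [
    "VarianceComponents",
    "FitResult",
    "heritability",
    "estimate_reml",
    "blup_evaluate",
    "reliability",
]


def heritability(sigma_a2, sigma_e2):
    """h2 = additive variance over total phenotypic variance."""
    sigma_a2 = np.asarray(sigma_a2, dtype=float)
    sigma_e2 = np.asarray(sigma_e2, dtype=float)
    return sigma_a2 / (sigma_a2 + sigma_e2)


@dataclass
class VarianceComponents:
    """Additive (G0) and residual (R0) covariance matrices across traits."""

    G0: np.ndarray
    R0: np.ndarray
    traits: tuple = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.G0 = np.atleast_2d(np.asarray(self.G0, dtype=float))
        self.R0 = np.atleast_2d(np.asarray(self.R0, dtype=float))
        t = self.G0.shape[0]
        if self.traits is None:
            self.traits = tuple(f"trait{i + 1}" for i in range(t))
        for name, M in (("G0", self.G0), ("R0", self.R0)):
            if M.shape != (t, t) or not np.allclose(M, M.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric {t}x{t}")

    @classmethod
    def single(cls, sigma_a2: float, sigma_e2: float, trait: str = "trait1"):
        return cls(G0=[[sigma_a2]], R0=[[sigma_e2]], traits=(trait,))

    def sigma_a2(self, trait=None):
        d = np.diag(self.G0)
        return d if trait is None else d[self.traits.index(trait)]

    def sigma_e2(self, trait=None):
        d = np.diag(self.R0)
        return d if trait is None else d[self.traits.index(trait)]

    def heritability(self):
        return heritability(np.diag(self.G0), np.diag(self.R0))


@dataclass
class FitResult:
    """Variance components, solutions and reliabilities of one evaluation."""

    vc: VarianceComponents
    b: dict
    ebv: np.ndarray  # q x t
    pev: np.ndarray | None  # q x t
    r2: np.ndarray | None  # q x t
    F: np.ndarray | None
    converged: bool
    n_iter: int
    loglik: float
    loglik_trace: list
    boundary: bool
    method: str
    vc_se: dict = field(default_factory=dict)  # h2_se / component SEs per trait
    r2_clipped: int = 0

    @property
    def h2(self) -> np.ndarray:
        return self.vc.heritability()

    def solutions_frame(self) -> pd.DataFrame:
        """Long-format (animal, trait, ebv, pev, r2) table."""
        q, t = self.ebv.shape
        recs = []
        for j, tr in enumerate(self.vc.traits):
            recs.append(
                pd.DataFrame(
                    {
                        "animal": np.arange(q),
                        "trait": tr,
                        "ebv": self.ebv[:, j],
                        "pev": self.pev[:, j] if self.pev is not None else np.nan,
                        "r2": self.r2[:, j] if self.r2 is not None else np.nan,
                    }
                )
            )
        return pd.concat(recs, ignore_index=True)


def reliability(
    pev: np.ndarray,
    sigma_a2: np.ndarray,
    F: np.ndarray | None = None,
    adjusted: bool = True,
):
    """PEV-based reliability per animal and trait, clipped to [0, 1].

    Returns (r2, n_clipped). ``sigma_a2`` is per trait; ``F`` per animal.
    Traits with zero additive variance yield NaN.
    """
    pev = np.atleast_2d(pev)
    sigma_a2 = np.atleast_1d(np.asarray(sigma_a2, dtype=float))
    denom = np.broadcast_to(sigma_a2[None, :], pev.shape).copy()
    if adjusted:
        if F is None:
            raise ValueError("adjusted reliability requires inbreeding coefficients F")
        denom = denom * (1.0 + np.asarray(F, dtype=float))[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sigma_a2[None, :] > 0, 1.0 - pev / denom, np.nan)
    clipped = int(np.sum((r2 < 0) | (r2 > 1)))
    return np.clip(r2, 0.0, 1.0), clipped


# ----------------------------------------------------------------------
# internal REML machinery
# ----------------------------------------------------------------------


def _param_layout(t: int, co_observed: np.ndarray, diagonal: bool = False):
    """(matrix, j, k) triples for the estimable (co)variance parameters."""
    params = []
    for j in range(t):
        for k in range(j, t):
            if j == k or not diagonal:
                params.append(("G", j, k))
    for j in range(t):
        for k in range(j, t):
            if j == k or (not diagonal and co_observed[j, k]):
                params.append(("R", j, k))
    return params


def _pack(params, G0, R0):
    return np.array([(G0 if m == "G" else R0)[j, k] for m, j, k in params])


def _unpack(params, theta, G0, R0):
    G0, R0 = G0.copy(), R0.copy()
    for val, (m, j, k) in zip(theta, params):
        M = G0 if m == "G" else R0
        M[j, k] = M[k, j] = val
    return G0, R0


def _is_pd(M: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(M)
        return True
    except np.linalg.LinAlgError:
        return False


class _IterState:
    """Everything computed from one factorization of the reduced system."""

    def __init__(self, system: MMESystem, G0, R0):
        self.system = system
        C = system.C.toarray()
        try:
            self.cho = cho_factor(C, lower=True)
        except np.linalg.LinAlgError as exc:
            from .mme import ModelError, _diagnose_singular

            raise ModelError(
                f"coefficient matrix not positive definite: {_diagnose_singular(system)}"
            ) from exc
        self.Cinv = cho_solve(self.cho, np.eye(C.shape[0]))
        self.sol = self.Cinv @ system.rhs
        p, q, t = system.p_total, system.q, system.t
        self.A_hat = self.sol[p:].reshape(q, t)
        self.Caa4 = self.Cinv[p:, p:].reshape(q, t, q, t)
        self.G0, self.R0 = G0, R0
        self.G0inv = np.linalg.inv(G0)
        Kinv = system.Kinv.toarray()
        # EM trace matrix T[j,k] = tr(Kinv C^{aj,ak})
        self.T = np.einsum("il,ijlk->jk", Kinv, self.Caa4, optimize=True)

        # per-record working residuals e~ = Roo^-1 (y - Xb - a), zero-padded
        n = len(system.animal)
        self.Etil = np.zeros((n, t))
        self.Ehat = np.zeros((n, t))  # raw residuals y - Xb - a
        self.Phi = {}  # pattern -> (|S|, |O|, |O|) prediction-error blocks
        self.Einv = {}  # pattern -> Roo^-1
        yRy = 0.0
        logdetR = 0.0
        for key, S in system.patterns.items():
            O = list(key)
            Roo = R0[np.ix_(O, O)]
            Einv = np.linalg.inv(Roo)
            self.Einv[key] = Einv
            anim = system.animal[S]
            Yo = system.Y[np.ix_(S, O)]
            res = np.empty_like(Yo)
            for jj, j in enumerate(O):
                D = system.designs[j][S]
                oj = system.p_offsets[j]
                mu = D @ self.sol[oj : oj + D.shape[1]] if D.shape[1] else 0.0
                res[:, jj] = system.Y[S, j] - mu - self.A_hat[anim, j]
            self.Ehat[np.ix_(S, O)] = res
            self.Etil[np.ix_(S, O)] = res @ Einv
            yRy += float(np.einsum("ij,jk,ik->", Yo, Einv, Yo))
            logdetR += S.size * np.linalg.slogdet(Roo)[1]
            # prediction-error covariance of the observed residuals,
            # Phi = W_i C^-1 W_i' on the observed coordinates
            Phi = np.empty((S.size, len(O), len(O)))
            for jj, j in enumerate(O):
                Dj = system.designs[j][S]
                oj, pj = system.p_offsets[j], system.designs[j].shape[1]
                rj = p + anim * t + j
                for kk, k in enumerate(O):
                    if kk < jj:
                        Phi[:, jj, kk] = Phi[:, kk, jj]
                        continue
                    Dk = system.designs[k][S]
                    ok, pk = system.p_offsets[k], system.designs[k].shape[1]
                    rk = p + anim * t + k
                    val = self.Cinv[rj, rk]
                    if pj:
                        val = val + np.einsum(
                            "ip,pi->i", Dj, self.Cinv[oj : oj + pj, :][:, rk]
                        )
                    if pk:
                        val = val + np.einsum(
                            "ip,pi->i", Dk, self.Cinv[ok : ok + pk, :][:, rj]
                        )
                    if pj and pk:
                        val = val + np.einsum(
                            "ip,pq,iq->i",
                            Dj,
                            self.Cinv[oj : oj + pj, ok : ok + pk],
                            Dk,
                        )
                    Phi[:, jj, kk] = val
            self.Phi[key] = Phi

        # restricted log-likelihood up to a theta-independent constant
        logdetC = 2.0 * np.sum(np.log(np.diag(self.cho[0])))
        logdetG = q * np.linalg.slogdet(G0)[1]
        self.loglik = -0.5 * (
            logdetC + logdetR + logdetG + yRy - float(self.sol @ system.rhs)
        )

    # -- EM updates ----------------------------------------------------
    def em_update(self):
        system = self.system
        q, t = system.q, system.t
        Kinv = system.Kinv
        G0_new = (self.A_hat.T @ (Kinv @ self.A_hat) + self.T) / q
        G0_new = 0.5 * (G0_new + G0_new.T)

        R_sum = np.zeros((t, t))
        n_anim = 0
        for key, S in system.patterns.items():
            O = list(key)
            M = [j for j in range(t) if j not in key]
            n_anim += S.size
            res = self.Ehat[np.ix_(S, O)]
            Eee = np.einsum("ij,ik->ijk", res, res) + self.Phi[key]
            full = np.zeros((S.size, t, t))
            ixO = np.ix_(range(S.size), O, O)
            full[ixO] = Eee
            if M:
                B = self.R0[np.ix_(M, O)] @ self.Einv[key]
                EmO = np.einsum("mo,iop->imp", B, Eee)
                full[np.ix_(range(S.size), M, O)] = EmO
                full[np.ix_(range(S.size), O, M)] = EmO.transpose(0, 2, 1)
                # E[e_M e_M'] = R_MM - B R_OM + B E[e_O e_O'] B'
                Emm = (
                    self.R0[np.ix_(M, M)][None, :, :]
                    - (B @ self.R0[np.ix_(O, M)])[None, :, :]
                    + np.einsum("iop,mo,np->imn", Eee, B, B)
                )
                full[np.ix_(range(S.size), M, M)] = Emm
            R_sum += full.sum(axis=0)
        R0_new = R_sum / n_anim
        R0_new = 0.5 * (R0_new + R0_new.T)
        return G0_new, R0_new

    # -- gradient ------------------------------------------------------
    def score_matrices(self):
        """dlogL/dG0 and dlogL/dR0 as full symmetric matrices.

        The score for parameter (j,k) is the (j,k) element for j = k and
        twice it for j != k (symmetric duplication).
        """
        system = self.system
        q, t = system.q, system.t
        KU = self.A_hat @ self.G0inv  # (K (x) I) Z'Py, reshaped q x t
        M_G = self.Etil.T @ KU[system.animal]  # U' K U over recorded animals
        M_G = 0.5 * (M_G + M_G.T)
        Gscore = -0.5 * (
            q * self.G0inv - self.G0inv @ self.T @ self.G0inv - M_G
        )

        M_R = self.Etil.T @ self.Etil
        RinvSum = np.zeros((t, t))
        RPhiSum = np.zeros((t, t))
        for key, S in system.patterns.items():
            O = list(key)
            Einv = self.Einv[key]
            RinvSum[np.ix_(O, O)] += S.size * Einv
            RPhiSum[np.ix_(O, O)] += np.einsum(
                "op,ipq,qr->or", Einv, self.Phi[key], Einv
            )
        Rscore = -0.5 * (RinvSum - RPhiSum - M_R)
        return Gscore, Rscore

    # -- average information -------------------------------------------
    def _f_vector(self, m, j, k):
        """Working variate f = (dV/dtheta) P y as a record x trait matrix."""
        system = self.system
        t = system.t
        Esym = np.zeros((t, t))
        Esym[j, k] = 1.0
        Esym[k, j] = 1.0
        if m == "G":
            KU = self.A_hat @ self.G0inv
            W2 = KU @ Esym
            f = W2[system.animal] * system.obs_mask
        else:
            f = (self.Etil @ Esym) * system.obs_mask
        return f

    def _apply_P(self, f: np.ndarray) -> np.ndarray:
        """P f = R^-1 (f - W C^-1 W' R^-1 f), record-space."""
        system = self.system
        p, q, t = system.p_total, system.q, system.t
        g = np.zeros_like(f)
        for key, S in system.patterns.items():
            O = list(key)
            g[np.ix_(S, O)] = f[np.ix_(S, O)] @ self.Einv[key]
        # r1 = W' g
        r1 = np.zeros(p + q * t)
        for j in range(t):
            obs = system.obs_mask[:, j]
            D = system.designs[j]
            oj, pj = system.p_offsets[j], system.designs[j].shape[1]
            if pj:
                r1[oj : oj + pj] = D[obs].T @ g[obs, j]
            np.add.at(r1, p + system.animal[obs] * t + j, g[obs, j])
        s = self.Cinv @ r1
        Ws = np.zeros_like(f)
        a_part = s[p:].reshape(q, t)
        for j in range(t):
            obs = system.obs_mask[:, j]
            D = system.designs[j]
            oj, pj = system.p_offsets[j], system.designs[j].shape[1]
            mu = D[obs] @ s[oj : oj + pj] if pj else 0.0
            Ws[obs, j] = mu + a_part[system.animal[obs], j]
        h = f - Ws
        Pf = np.zeros_like(f)
        for key, S in system.patterns.items():
            O = list(key)
            Pf[np.ix_(S, O)] = h[np.ix_(S, O)] @ self.Einv[key]
        return Pf

    def ai_matrix(self, params):
        F = [self._f_vector(*prm) for prm in params]
        PF = [self._apply_P(f) for f in F]
        npar = len(params)
        AI = np.empty((npar, npar))
        for i in range(npar):
            for l in range(i, npar):
                AI[i, l] = AI[l, i] = 0.5 * float(np.sum(F[i] * PF[l]))
        return AI

    def score_vector(self, params):
        Gs, Rs = self.score_matrices()
        out = []
        for m, j, k in params:
            M = Gs if m == "G" else Rs
            out.append(M[j, k] if j == k else 2.0 * M[j, k])
        return np.array(out)


def _reduce_problem(table, Kinv, K=None):
    """Restrict table + relationship matrix to recorded animals."""
    recorded = np.unique(table["animal"].to_numpy(dtype=np.int64))
    q = Kinv.shape[0]
    if recorded.size == q:
        return table, Kinv, None
    if K is None:
        Kdense = np.linalg.inv(
            Kinv.toarray() if sp.issparse(Kinv) else np.asarray(Kinv)
        )
    else:
        Kdense = np.asarray(K)
    Kred = Kdense[np.ix_(recorded, recorded)]
    Kinv_red = np.linalg.inv(Kred)
    remap = {a: i for i, a in enumerate(recorded)}
    table_red = table.copy()
    table_red["animal"] = table["animal"].map(remap)
    return table_red, Kinv_red, recorded


def estimate_reml(
    spec: ModelSpec,
    table: pd.DataFrame,
    Kinv,
    start: VarianceComponents | None = None,
    method: str = "ai",
    tol: float = 1e-8,
    max_iter: int = 500,
    K=None,
    F: np.ndarray | None = None,
    compute_reliability: bool = True,
    reliability_adjusted: bool = True,
    reduce: bool = True,
    constrain_diagonal: bool = False,
) -> FitResult:
    """REML variance components and BLUP evaluation in one call.

    ``method`` is "ai" (EM-REML with AI/Newton acceleration, the default)
    or "em" (pure EM). ``K`` optionally supplies the dense relationship
    matrix to avoid inverting ``Kinv`` when absorbing unrecorded animals.
    ``F`` (inbreeding coefficients, full index set) enables the
    (1+F)-adjusted reliability. ``constrain_diagonal`` pins every genetic
    and residual covariance at zero (independent-traits model).
    """
    t = len(spec.traits)
    table = table.loc[
        table[[tr for tr in spec.traits if tr in table.columns]].notna().any(axis=1)
    ].reset_index(drop=True)
    Y0 = np.column_stack(
        [
            table[tr].to_numpy(dtype=float) if tr in table.columns
            else np.full(len(table), np.nan)
            for tr in spec.traits
        ]
    )
    pheno_var = np.array([np.nanvar(Y0[:, j]) if np.isfinite(Y0[:, j]).any() else 1.0
                          for j in range(t)])
    pheno_var[pheno_var <= 0] = 1.0
    if start is None:
        start = VarianceComponents(
            G0=np.diag(0.5 * pheno_var), R0=np.diag(0.5 * pheno_var),
            traits=spec.traits,
        )
    G0 = start.G0.copy()
    R0 = start.R0.copy()

    obs_mask0 = ~np.isnan(Y0)
    co_observed = (obs_mask0.astype(int).T @ obs_mask0.astype(int)) > 0
    params = _param_layout(t, co_observed, diagonal=constrain_diagonal)
    floor = 1e-8 * pheno_var

    if reduce:
        table_red, Kinv_red, recorded = _reduce_problem(table, Kinv, K)
    else:
        table_red, Kinv_red, recorded = table, Kinv, None

    trace = []
    converged = False
    boundary = False
    state = None
    prev_ll = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        system = assemble_mme(spec, table_red, Kinv_red, G0, R0)
        state = _IterState(system, G0, R0)
        trace.append(state.loglik)
        use_em = method == "em" or n_iter == 1 or state.loglik < prev_ll - 1e-10
        prev_ll = max(prev_ll, state.loglik)

        G0_em, R0_em = state.em_update()
        if use_em:
            G0_new, R0_new = G0_em, R0_em
        else:
            score = state.score_vector(params)
            AI = state.ai_matrix(params)
            theta = _pack(params, G0, R0)
            try:
                delta = np.linalg.solve(
                    AI + 1e-12 * np.eye(len(params)) * np.abs(AI).max(), score
                )
            except np.linalg.LinAlgError:
                delta = None
            G0_new = R0_new = None
            if delta is not None:
                step = 1.0
                for _ in range(12):
                    cand = _unpack(params, theta + step * delta, G0, R0)
                    if _is_pd(cand[0]) and _is_pd(cand[1]):
                        G0_new, R0_new = cand
                        break
                    step *= 0.5
            if G0_new is None:
                G0_new, R0_new = G0_em, R0_em

        # keep unobserved cross-covariances at zero; floor tiny variances
        for j in range(t):
            for k in range(j + 1, t):
                if constrain_diagonal:
                    G0_new[j, k] = G0_new[k, j] = 0.0
                if constrain_diagonal or not co_observed[j, k]:
                    R0_new[j, k] = R0_new[k, j] = 0.0
        if np.any(np.diag(G0_new) < floor) or np.any(np.diag(R0_new) < floor):
            boundary = True
            G0_new[np.diag_indices(t)] = np.maximum(np.diag(G0_new), floor)
            R0_new[np.diag_indices(t)] = np.maximum(np.diag(R0_new), floor)

        theta_old = _pack(params, G0, R0)
        theta_new = _pack(params, G0_new, R0_new)
        rel = np.abs(theta_new - theta_old) / (np.abs(theta_old) + 1e-10 * pheno_var.mean())
        # a variance collapsing toward zero counts as converged (boundary)
        at_floor = np.array(
            [j == k and theta_new[i] <= 1e-6 * pheno_var[j]
             and theta_new[i] <= theta_old[i] * (1 + 1e-12)
             for i, (m, j, k) in enumerate(params)]
        )
        if at_floor.any():
            boundary = True
            rel[at_floor] = 0.0
        G0, R0 = G0_new, R0_new
        if np.max(rel) < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"REML did not converge in {max_iter} iterations "
            f"(last max relative change {np.max(rel):.2e})",
            RuntimeWarning,
        )
    if np.any(np.diag(G0) < 1e-4 * pheno_var):
        boundary = True

    # standard errors from the AI matrix at the converged estimates
    vc_se: dict = {}
    try:
        system = assemble_mme(spec, table_red, Kinv_red, G0, R0)
        state = _IterState(system, G0, R0)
        AI = state.ai_matrix(params)
        cov = np.linalg.inv(AI)
        comp_se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        vc_se["components"] = {
            prm: se for prm, se in zip(params, comp_se)
        }
        h2_se = np.full(t, np.nan)
        for j in range(t):
            ig = params.index(("G", j, j))
            ir = params.index(("R", j, j))
            g, r = G0[j, j], R0[j, j]
            grad = np.array([r, -g]) / (g + r) ** 2
            sub = cov[np.ix_([ig, ir], [ig, ir])]
            h2_se[j] = np.sqrt(max(float(grad @ sub @ grad), 0.0))
        vc_se["h2_se"] = h2_se
    except np.linalg.LinAlgError:
        vc_se["h2_se"] = np.full(t, np.nan)

    vc = VarianceComponents(G0=G0, R0=R0, traits=spec.traits)
    fit = blup_evaluate(
        spec, table, Kinv, vc, F=F,
        compute_reliability=compute_reliability,
        reliability_adjusted=reliability_adjusted,
    )
    fit.converged = converged
    fit.n_iter = n_iter
    fit.loglik = trace[-1] if trace else np.nan
    fit.loglik_trace = trace
    fit.boundary = boundary
    fit.method = method
    fit.vc_se = vc_se
    return fit


def stack_fits(fits: list) -> FitResult:
    """Combine single-trait fits over the same animal index into one result.

    Convenient when the seven traits are evaluated trait-by-trait but the
    comparison machinery wants one multi-trait object.
    """
    traits = tuple(tr for f in fits for tr in f.vc.traits)
    if len(set(f.ebv.shape[0] for f in fits)) != 1:
        raise ValueError("fits cover different animal sets")
    G0 = np.diag([f.vc.G0[j, j] for f in fits for j in range(f.vc.G0.shape[0])])
    R0 = np.diag([f.vc.R0[j, j] for f in fits for j in range(f.vc.R0.shape[0])])
    vc = VarianceComponents(G0=G0, R0=R0, traits=traits)
    b = {}
    for f in fits:
        b.update(f.b)
    has_pev = all(f.pev is not None for f in fits)
    return FitResult(
        vc=vc,
        b=b,
        ebv=np.column_stack([f.ebv for f in fits]),
        pev=np.column_stack([f.pev for f in fits]) if has_pev else None,
        r2=np.column_stack([f.r2 for f in fits]) if has_pev else None,
        F=fits[0].F,
        converged=all(f.converged for f in fits),
        n_iter=max(f.n_iter for f in fits),
        loglik=np.nan,
        loglik_trace=[],
        boundary=any(f.boundary for f in fits),
        method=fits[0].method,
        r2_clipped=sum(f.r2_clipped for f in fits),
    )


def reml_loglik(spec, table, Kinv, vc: VarianceComponents) -> float:
    """Restricted log-likelihood at fixed components (additive constant
    omitted); useful for profiling and for comparing candidate estimates."""
    table = table.loc[
        table[[tr for tr in vc.traits if tr in table.columns]].notna().any(axis=1)
    ].reset_index(drop=True)
    table_red, Kinv_red, _ = _reduce_problem(table, Kinv)
    system = assemble_mme(spec, table_red, Kinv_red, vc.G0, vc.R0)
    return _IterState(system, vc.G0, vc.R0).loglik


def blup_evaluate(
    spec: ModelSpec,
    table: pd.DataFrame,
    Kinv,
    vc: VarianceComponents,
    F: np.ndarray | None = None,
    compute_reliability: bool = True,
    reliability_adjusted: bool = True,
) -> FitResult:
    """BLUP solutions (and PEV reliabilities) at fixed variance components."""
    system = assemble_mme(spec, table, Kinv, vc.G0, vc.R0)
    q, t, p = system.q, system.t, system.p_total
    pev = r2 = None
    n_clip = 0
    if compute_reliability:
        C = system.C.toarray()
        cho = cho_factor(C, lower=True)
        Cinv_diag_cols = cho_solve(cho, np.eye(C.shape[0]))
        sol = Cinv_diag_cols @ system.rhs
        pev = np.diag(Cinv_diag_cols)[p:].reshape(q, t).copy()
        r2, n_clip = reliability(
            pev, np.diag(vc.G0), F=F if reliability_adjusted else None,
            adjusted=reliability_adjusted and F is not None,
        )
        b = {}
        for j, tr in enumerate(spec.traits):
            oj = system.p_offsets[j]
            pj = system.designs[j].shape[1]
            b[tr] = pd.Series(sol[oj : oj + pj], index=system.fixed_labels[j])
        a = sol[p:].reshape(q, t)
    else:
        solution = solve_blup(system)
        b, a = solution.b, solution.a
    return FitResult(
        vc=vc, b=b, ebv=a, pev=pev, r2=r2, F=F,
        converged=True, n_iter=0, loglik=np.nan, loglik_trace=[],
        boundary=False, method="blup", r2_clipped=n_clip,
    )
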