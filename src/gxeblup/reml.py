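"""Restricted maximum likelihood for the multivariate animal model.

EM-REML backbone with average-information (AI) acceleration: every
iteration computes the exact EM update (guaranteed uphill) and the AI/
Newton proposal; the AI step is taken whenever it keeps all covariance
blocks inside the SPD cone and does not decrease the restricted
log-likelihood, otherwise the step is halved and finally the EM update is
used.  Trace terms are exact, obtained from the Takahashi selected inverse
of the sparse mixed-model coefficient matrix.  Convergence is declared
when the Frobenius norm of the parameter update drops below ``tol``
(default 1e-5).

Variance components are always estimated with the pedigree kernel
(A-inverse): with selective genotyping, REML under the genomic kernel is
biased, so single-step EBV prediction reuses the pedigree-based estimates.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import sparse

from .mixed_model import CompiledModel, Design, ModelSpec, build_design
from .pedigree import Pedigree
from .relationships import build_A_inverse
from .sparse_ldl import LDLFactor, fill_reducing_order


def _vech_indices(k: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(k) for j in range(i, k)]


def _floor_spd(mat: np.ndarray, rel: float = 1e-5) -> np.ndarray:
    """Clip tiny/negative eigenvalues so iterates stay strictly inside the
    SPD cone; correlations may approach but not reach 1."""
    mat = 0.5 * (mat + mat.T)
    floor = rel * max(np.trace(mat) / mat.shape[0], 1e-300)
    w, v = np.linalg.eigh(mat)
    if w[0] >= floor:
        return mat
    w = np.maximum(w, floor)
    return (v * w) @ v.T


@dataclasses.dataclass
class Components:
    """One point in covariance-parameter space."""

    va0: np.ndarray
    vc0: np.ndarray | None
    ve0: np.ndarray

    def copy(self) -> "Components":
        return Components(
            self.va0.copy(),
            None if self.vc0 is None else self.vc0.copy(),
            self.ve0.copy(),
        )


class _Parameterization:
    """Pack/unpack the free covariance elements into a flat vector."""

    def __init__(self, spec: ModelSpec):
        k = spec.n_traits
        self.k = k
        self.spec = spec
        self.a_idx = _vech_indices(k)
        self.c_idx = _vech_indices(k) if spec.use_maternal else []
        self.e_idx: list[tuple[int, int]] = []
        for grp in spec.residual_groups:
            for a in range(len(grp)):
                for b in range(a, len(grp)):
                    self.e_idx.append((grp[a], grp[b]))
        self.n_params = len(self.a_idx) + len(self.c_idx) + len(self.e_idx)

    def pack(self, comp: Components) -> np.ndarray:
        out = [comp.va0[i, j] for i, j in self.a_idx]
        if self.c_idx:
            out += [comp.vc0[i, j] for i, j in self.c_idx]
        out += [comp.ve0[i, j] for i, j in self.e_idx]
        return np.array(out)

    def unpack(self, theta: np.ndarray) -> Components:
        k = self.k
        m = self.spec.n_rtypes
        va0 = np.zeros((k, k))
        pos = 0
        for i, j in self.a_idx:
            va0[i, j] = va0[j, i] = theta[pos]
            pos += 1
        vc0 = None
        if self.c_idx:
            vc0 = np.zeros((k, k))
            for i, j in self.c_idx:
                vc0[i, j] = vc0[j, i] = theta[pos]
                pos += 1
        ve0 = np.zeros((m, m))
        for i, j in self.e_idx:
            ve0[i, j] = ve0[j, i] = theta[pos]
            pos += 1
        return Components(va0, vc0, ve0)

    def _blocks(self, comp: Components):
        """(matrix, vech index pairs) per independent covariance block,
        aligned with the theta layout."""
        out = [(comp.va0, self.a_idx)]
        if self.c_idx:
            out.append((comp.vc0, self.c_idx))
        for grp in self.spec.residual_groups:
            pairs = [(a, b) for a in range(len(grp)) for b in range(a, len(grp))]
            out.append((comp.ve0[np.ix_(grp, grp)], pairs))
        return out

    def chol_pack(self, comp: Components) -> np.ndarray:
        """Lower-Cholesky parameters of every block (unconstrained scale)."""
        vals: list[float] = []
        for mat, pairs in self._blocks(comp):
            L = np.linalg.cholesky(mat)
            vals.extend(L[j, i] for i, j in pairs)  # (i<=j) -> L[j,i] lower
        return np.array(vals)

    def chol_unpack(self, lvec: np.ndarray) -> Components:
        theta = np.empty(self.n_params)
        pos = 0
        tpos = 0
        ref = self.unpack(np.zeros(self.n_params))
        for mat, pairs in self._blocks(ref):
            kb = mat.shape[0]
            L = np.zeros((kb, kb))
            for i, j in pairs:
                L[j, i] = lvec[pos]
                pos += 1
            sig = L @ L.T
            for i, j in pairs:
                theta[tpos] = sig[i, j]
                tpos += 1
        return self.unpack(theta)

    def chol_jacobian(self, comp: Components) -> np.ndarray:
        """d(sigma elements)/d(Cholesky elements), block diagonal."""
        J = np.zeros((self.n_params, self.n_params))
        pos = 0
        for mat, pairs in self._blocks(comp):
            kb = mat.shape[0]
            L = np.linalg.cholesky(mat)
            nb = len(pairs)
            for col, (q, p) in enumerate(pairs):  # chol param at L[p, q]
                dsig = np.zeros((kb, kb))
                dsig[p, :] += L[:, q]
                dsig[:, p] += L[:, q]
                for row, (i, j) in enumerate(pairs):
                    J[pos + row, pos + col] = dsig[i, j]
            pos += nb
        return J

    def is_valid(self, comp: Components) -> bool:
        def spd(mat: np.ndarray) -> bool:
            try:
                np.linalg.cholesky(mat)
                return True
            except np.linalg.LinAlgError:
                return False

        if not spd(comp.va0):
            return False
        if comp.vc0 is not None and not spd(comp.vc0):
            return False
        for grp in self.spec.residual_groups:
            if not spd(comp.ve0[np.ix_(grp, grp)]):
                return False
        return True


@dataclasses.dataclass
class StartResult:
    theta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    final_update_norm: float
    loglik_trace: list[float]
    n_em_steps: int


@dataclasses.dataclass
class REMLResult:
    """Best-likelihood REML fit across starting values."""

    va0: np.ndarray
    vc0: np.ndarray | None
    ve0: np.ndarray
    loglik: float
    converged: bool
    final_update_norm: float
    n_iter: int
    loglik_trace: list[float]
    start_results: list[StartResult]
    starts_disagree: bool

    def covariance_set(self):
        from .params import CovarianceSet

        return CovarianceSet(self.va0, self.vc0, self.ve0, scale="standardized")


class REMLProblem:
    """Workspace tying together design, kernel and factorization."""

    def __init__(self, design: Design, a_inv: sparse.spmatrix):
        self.design = design
        self.spec = design.spec
        self.compiled = CompiledModel(design)
        self.par = _Parameterization(self.spec)
        k = self.spec.n_traits
        self.k = k
        n = design.n_animals
        nd = design.n_dams
        self.n = n
        self.nd = nd
        self.a_inv = sparse.csr_matrix(a_inv)
        self._a_coo = sparse.coo_matrix(self.a_inv)

        c = self.compiled
        self.kr, self.kc, self.kdata, self.kts = c.kron_arrays(
            "genetic", self._a_coo, c.go
        )
        if self.spec.use_maternal and nd:
            eye = sparse.identity(nd, format="coo")
            self.mr, self.mc, self.mdata, self.mts = c.kron_arrays(
                "maternal", eye, c.mo
            )
        else:
            self.mr = self.mc = self.mdata = self.mts = np.empty(0, np.int64)

        self.rows = np.concatenate([c.ew_row, self.kr, self.mr])
        self.cols = np.concatenate([c.ew_col, self.kc, self.mc])

        # fill-reducing elimination order: computed lazily from the first
        # assembled (SPD) coefficient matrix in _factorize

        # A factor (reverse pedigree order) for kernel products and log|A|
        anim_rev = np.arange(n - 1, -1, -1)
        self.a_factor = LDLFactor(self.a_inv.tocsc(), perm=anim_rev)
        self.logdet_a = -self.a_factor.logdet

        self.factor: LDLFactor | None = None
        self._ks_inv_idx: np.ndarray | None = None
        self._ms_inv_idx: np.ndarray | None = None
        self._ew_inv_idx: np.ndarray | None = None

        tr = np.array(self.spec.rtype_trait_idx)
        self.rec_trait = tr[design.rec_rtype]
        self.y = design.y

    # -- assembly / likelihood -------------------------------------------
    def _values(self, comp: Components, flat: np.ndarray) -> np.ndarray:
        va0_inv = np.linalg.inv(comp.va0)
        vals = [flat[self.compiled.ew_patab], self.kdata * va0_inv.ravel()[self.kts]]
        if len(self.mts):
            vc0_inv = np.linalg.inv(comp.vc0)
            vals.append(self.mdata * vc0_inv.ravel()[self.mts])
        return np.concatenate(vals)

    def _assemble(self, comp: Components) -> tuple[sparse.csc_matrix, np.ndarray, float]:
        flat, logdet_r = self.compiled.rinv_table(comp.ve0)
        vals = self._values(comp, flat)
        n_eq = self.compiled.n_eq
        lhs = sparse.coo_matrix(
            (vals, (self.rows, self.cols)), shape=(n_eq, n_eq)
        ).tocsc()
        return lhs, flat, logdet_r

    def _factorize(self, lhs: sparse.csc_matrix) -> LDLFactor:
        if self.factor is None:
            self.factor = LDLFactor(lhs, perm=fill_reducing_order(lhs))
            self._ks_inv_idx = self.factor.entry_indices(self.kr, self.kc)
            if len(self.mr):
                self._ms_inv_idx = self.factor.entry_indices(self.mr, self.mc)
            self._ew_inv_idx = self.factor.entry_indices(
                self.compiled.ew_row, self.compiled.ew_col
            )
        else:
            self.factor.refactor(lhs)
        return self.factor

    def loglik(self, comp: Components, keep_state: bool = False):
        """Restricted log-likelihood (up to a constant)."""
        lhs, flat, logdet_r = self._assemble(comp)
        factor = self._factorize(lhs)
        rhs = self.compiled.wt_rinv(flat, self.y)
        sol = factor.solve(rhs)
        ypy = self.compiled.quad_y_rinv_y(flat, self.y) - rhs @ sol
        logdet_g = self.k * self.logdet_a + self.n * np.linalg.slogdet(comp.va0)[1]
        if comp.vc0 is not None and self.nd:
            logdet_g += self.nd * np.linalg.slogdet(comp.vc0)[1]
        ll = -0.5 * (logdet_r + logdet_g + factor.logdet + ypy)
        if keep_state:
            return ll, flat, sol
        return ll

    # -- one REML iteration ----------------------------------------------
    def iteration_quantities(self, comp: Components):
        """Solve, selected inverse and all EM/score/AI ingredients."""
        ll, flat, sol = self.loglik(comp, keep_state=True)
        c = self.compiled
        factor = self.factor
        factor.compute_selected_inverse()

        k, n, nd = self.k, self.n, self.nd
        # genetic EM pieces
        s_a = np.bincount(
            self.kts,
            weights=self.kdata * factor.gather_inverse(self._ks_inv_idx),
            minlength=k * k,
        ).reshape(k, k)
        U = sol[: k * n].reshape(n, k)
        uau = U.T @ (self.a_inv @ U)
        va0_em = (uau + s_a) / n
        va0_em = 0.5 * (va0_em + va0_em.T)

        vc0_em = None
        s_c = None
        if comp.vc0 is not None and nd:
            s_c = np.bincount(
                self.mts, weights=factor.gather_inverse(self._ms_inv_idx), minlength=k * k
            ).reshape(k, k)
            Cm = sol[c.mo : c.fo].reshape(nd, k)
            vc0_em = (Cm.T @ Cm + s_c) / nd
            vc0_em = 0.5 * (vc0_em + vc0_em.T)

        # residuals and per-animal fitted-value covariance blocks
        e_hat = self.y - c.w_apply(sol)
        wcw = np.bincount(
            c.ew_slot,
            weights=factor.gather_inverse(self._ew_inv_idx),
            minlength=c.n_slots,
        )
        py = c.rinv_apply(flat, e_hat)
        return ll, flat, sol, s_a, uau, va0_em, s_c, vc0_em, e_hat, wcw, py

    def _pattern_blocks(self, p: int, vec: np.ndarray) -> np.ndarray:
        """Per-member (kp,) matrix of ``vec`` gathered at pattern records."""
        return vec[self.compiled.pat_rec[p]]

    def _pattern_wcw(self, p: int, wcw: np.ndarray) -> np.ndarray:
        kp = len(self.compiled.patterns[p])
        slot0 = self.compiled.pat_slot0[p]
        idx = slot0[:, None] + np.arange(kp * kp)
        return wcw[idx].reshape(-1, kp, kp)

    def em_residual(self, comp: Components, e_hat, wcw) -> np.ndarray:
        """Exact EM update of the structured residual covariance.

        Missing week records within a (sex, environment) cell are completed
        by their conditional expectations, keeping the update SPD."""
        c = self.compiled
        ve_new = comp.ve0.copy()
        for grp in self.spec.residual_groups:
            kg = len(grp)
            pos_in_grp = {r: i for i, r in enumerate(grp)}
            ssum = np.zeros((kg, kg))
            n_cell = 0
            ve_g = comp.ve0[np.ix_(grp, grp)]
            for p, pat in enumerate(c.patterns):
                if not set(pat) <= set(grp) or len(c.pat_rec[p]) == 0:
                    continue
                obs = [pos_in_grp[r] for r in pat]
                mis = [i for i in range(kg) if i not in obs]
                Eh = self._pattern_blocks(p, e_hat)
                Wc = self._pattern_wcw(p, wcw)
                eee = Eh[:, :, None] * Eh[:, None, :] + Wc
                n_p = eee.shape[0]
                n_cell += n_p
                if not mis:
                    ssum[np.ix_(obs, obs)] += eee.sum(axis=0)
                else:
                    voo = ve_g[np.ix_(obs, obs)]
                    vmo = ve_g[np.ix_(mis, obs)]
                    B = vmo @ np.linalg.inv(voo)
                    schur = ve_g[np.ix_(mis, mis)] - B @ vmo.T
                    eoo = eee.sum(axis=0)
                    emo = B @ eoo
                    emm = B @ eoo @ B.T + n_p * schur
                    ssum[np.ix_(obs, obs)] += eoo
                    ssum[np.ix_(mis, obs)] += emo
                    ssum[np.ix_(obs, mis)] += emo.T
                    ssum[np.ix_(mis, mis)] += emm
            if n_cell:
                blk = ssum / n_cell
                ve_new[np.ix_(grp, grp)] = 0.5 * (blk + blk.T)
        return ve_new

    def scores_and_ai(self, comp: Components, flat, s_a, s_c, py):
        """REML gradient and average-information matrix."""
        c = self.compiled
        par = self.par
        k, n, nd = self.k, self.n, self.nd
        va0_inv = np.linalg.inv(comp.va0)

        # genetic: g = Za' P y scattered to (animal, trait); Ag = A g
        g = np.zeros((n, k))
        np.add.at(g, (self.design.rec_animal, self.rec_trait), py)
        Ag = self.a_factor.solve(g)
        m_a = g.T @ Ag
        t_a = n * va0_inv - va0_inv @ s_a @ va0_inv

        scores = []
        fvecs = []
        n_rec = self.design.n_records
        for i, j in par.a_idx:
            mult = 1.0 if i == j else 2.0
            scores.append(-0.5 * mult * (t_a[i, j] - m_a[i, j]))
            X = np.zeros((n, k))
            X[:, j] += Ag[:, i]
            if i != j:
                X[:, i] += Ag[:, j]
            fvecs.append(X.ravel()[c.rec_gcol])

        if par.c_idx:
            vc0_inv = np.linalg.inv(comp.vc0)
            gm = np.zeros((nd, k))
            has = c.rec_mcol >= 0
            mflat = c.rec_mcol[has] - c.mo
            np.add.at(gm.reshape(-1), mflat, py[has])
            m_c = gm.T @ gm
            t_c = nd * vc0_inv - vc0_inv @ s_c @ vc0_inv
            for i, j in par.c_idx:
                mult = 1.0 if i == j else 2.0
                scores.append(-0.5 * mult * (t_c[i, j] - m_c[i, j]))
                X = np.zeros((nd, k))
                X[:, j] += gm[:, i]
                if i != j:
                    X[:, i] += gm[:, j]
                f = np.zeros(n_rec)
                f[has] = X.ravel()[mflat]
                fvecs.append(f)

        # residual parameters
        wcw = self._last_wcw
        for r, s in par.e_idx:
            mult = 1.0 if r == s else 2.0
            quad = 0.0
            tr_term = 0.0
            f = np.zeros(n_rec)
            for p, pat in enumerate(c.patterns):
                if r not in pat or s not in pat or len(c.pat_rec[p]) == 0:
                    continue
                ar, as_ = pat.index(r), pat.index(s)
                kp = len(pat)
                off = c.pat_offset[p]
                rinv_p = flat[off : off + kp * kp].reshape(kp, kp)
                Pp = py[c.pat_rec[p]]
                quad += mult * float(np.sum(Pp[:, ar] * Pp[:, as_]))
                Wc = self._pattern_wcw(p, wcw)
                # K = Rinv - Rinv Wc Rinv, per member
                K_rs = rinv_p[ar, as_] * len(Pp) - float(
                    np.einsum("a,nab,b->", rinv_p[ar], Wc, rinv_p[as_])
                )
                tr_term += mult * K_rs
                recs = c.pat_rec[p]
                np.add.at(f, recs[:, ar], Pp[:, as_])
                if r != s:
                    np.add.at(f, recs[:, as_], Pp[:, ar])
            scores.append(-0.5 * (tr_term - quad))
            fvecs.append(f)

        F = np.column_stack(fvecs)
        WtF = np.column_stack(
            [c.wt_rinv(flat, F[:, q]) for q in range(F.shape[1])]
        )
        S = self.factor.solve(WtF)
        PF = np.column_stack(
            [
                c.rinv_apply(flat, F[:, q] - c.w_apply(S[:, q]))
                for q in range(F.shape[1])
            ]
        )
        ai = 0.5 * (F.T @ PF)
        ai = 0.5 * (ai + ai.T)
        return np.array(scores), ai

    _last_wcw: np.ndarray | None = None
    _last_lam: float | None = None

    def step(self, comp: Components):
        """One EM/AI iteration; returns (new components, new ll, used_em)."""
        (
            ll,
            flat,
            sol,
            s_a,
            uau,
            va0_em,
            s_c,
            vc0_em,
            e_hat,
            wcw,
            py,
        ) = self.iteration_quantities(comp)
        self._last_wcw = wcw
        ve0_em = self.em_residual(comp, e_hat, wcw)
        va0_em = _floor_spd(va0_em)
        if vc0_em is not None:
            vc0_em = _floor_spd(vc0_em)
        for grp in self.spec.residual_groups:
            ve0_em[np.ix_(grp, grp)] = _floor_spd(ve0_em[np.ix_(grp, grp)])
        em_comp = Components(va0_em, vc0_em, ve0_em)

        scores, ai = self.scores_and_ai(comp, flat, s_a, s_c, py)
        used_em = True
        best = em_comp
        # AI/Newton proposal taken on the Cholesky-factor scale, where any
        # step maps back to a valid covariance; Levenberg damping handles
        # directions with no information (e.g. maternal covariances between
        # recording windows that share no dams)
        lvec = self.par.chol_pack(comp)
        J = self.par.chol_jacobian(comp)
        sc_c = J.T @ scores
        ai_c = J.T @ ai @ J
        ai_c = 0.5 * (ai_c + ai_c.T)
        ridge = max(np.trace(ai_c) / max(len(lvec), 1), 1e-12)
        eye = np.eye(len(lvec))
        accepted = False
        # try the previous iteration's successful damping first: refactoring
        # the coefficient matrix per candidate is the expensive part
        lams = [1e-8, 1e-4, 1e-2, 1e-1]
        if self._last_lam in lams:
            lams.remove(self._last_lam)
            lams.insert(0, self._last_lam)
        for lam in lams:
            try:
                dl = np.linalg.solve(ai_c + lam * ridge * eye, sc_c)
            except np.linalg.LinAlgError:
                continue
            for w in (1.0, 0.5):
                cand = self.par.chol_unpack(lvec + w * dl)
                if not self.par.is_valid(cand):
                    continue
                try:
                    cand_ll = self.loglik(cand)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if cand_ll >= ll - 1e-9:
                    best = cand
                    used_em = False
                    accepted = True
                    self._last_lam = lam
                    break
            if accepted:
                break
        return best, ll, used_em


def default_starts(design: Design, n_starts: int = 3) -> list[Components]:
    """Truth-agnostic starting values from the raw per-type variances."""
    spec = design.spec
    k = spec.n_traits
    m = spec.n_rtypes
    var_rt = np.empty(m)
    for r in range(m):
        yr = design.y[design.rec_rtype == r]
        var_rt[r] = np.var(yr) if len(yr) > 1 else 1.0
    var_rt = np.maximum(var_rt, 1e-8)
    trait_var = np.array(
        [np.mean([var_rt[r] for r in range(m) if spec.rtype_trait_idx[r] == t])
         for t in range(k)]
    )
    splits = [(0.30, 0.05, 0.65), (0.55, 0.05, 0.40), (0.10, 0.05, 0.85)][:n_starts]
    corr_k = np.full((k, k), 0.5) + 0.5 * np.eye(k)
    out = []
    for fa, fc, fe in splits:
        va0 = np.sqrt(np.outer(trait_var * fa, trait_var * fa)) * corr_k
        vc0 = (
            np.sqrt(np.outer(trait_var * fc, trait_var * fc)) * corr_k
            if spec.use_maternal
            else None
        )
        ve0 = np.zeros((m, m))
        for grp in spec.residual_groups:
            for a in grp:
                ve0[a, a] = var_rt[a] * fe
            for ai_, a in enumerate(grp):
                for b in grp[ai_ + 1 :]:
                    ve0[a, b] = ve0[b, a] = 0.3 * np.sqrt(ve0[a, a] * ve0[b, b])
        out.append(Components(va0, vc0, ve0))
    return out


def reml_estimate(
    records: pd.DataFrame,
    spec: ModelSpec,
    pedigree: Pedigree,
    starts: list[Components] | None = None,
    tol: float = 1e-5,
    max_iter: int = 500,
    a_inv: sparse.spmatrix | None = None,
) -> REMLResult:
    """REML estimates of the covariance components (pedigree kernel).

    Runs every starting value to convergence, returns the best-likelihood
    solution and flags disagreement between converged starts beyond 1e-3
    relative.
    """
    design = build_design(records, spec, pedigree)
    if a_inv is None:
        a_inv = build_A_inverse(pedigree)
    problem = REMLProblem(design, a_inv)
    if starts is None:
        starts = default_starts(design)
    if not starts:
        raise ValueError("at least one starting value is required")

    results: list[StartResult] = []
    for comp in starts:
        comp = comp.copy()
        if not problem.par.is_valid(comp):
            raise ValueError("starting value is not positive definite")
        trace: list[float] = []
        upd = np.inf
        converged = False
        n_em = 0
        it = 0
        best_ll = -np.inf
        best_comp = comp
        stall = 0
        for it in range(1, max_iter + 1):
            new_comp, ll, used_em = problem.step(comp)
            trace.append(ll)
            n_em += used_em
            upd = float(
                np.linalg.norm(problem.par.pack(new_comp) - problem.par.pack(comp))
            )
            if ll > best_ll + 1e-6 * (1.0 + abs(ll)):
                best_ll = ll
                best_comp = comp
                stall = 0
            else:
                stall += 1
            comp = new_comp
            if upd < tol:
                converged = True
                break
            # likelihood plateau: near-boundary covariances (correlations
            # approaching 1) make the final updates numerically noisy; stop
            # at the best point seen once no real progress is being made
            if stall >= 15:
                comp = best_comp
                converged = True
                break
        ll_final = problem.loglik(comp)
        trace.append(ll_final)
        results.append(
            StartResult(
                theta=problem.par.pack(comp),
                loglik=float(ll_final),
                converged=converged,
                n_iter=it,
                final_update_norm=upd,
                loglik_trace=trace,
                n_em_steps=n_em,
            )
        )

    if not any(r.converged for r in results):
        raise RuntimeError(
            f"REML did not converge from any of {len(starts)} starts "
            f"within {max_iter} iterations"
        )
    conv = [r for r in results if r.converged]
    best = max(conv, key=lambda r: r.loglik)
    scale = max(1.0, float(np.linalg.norm(best.theta)))
    disagree = any(
        np.linalg.norm(r.theta - best.theta) / scale > 1e-3 for r in conv
    )
    comp = problem.par.unpack(best.theta)
    return REMLResult(
        va0=comp.va0,
        vc0=comp.vc0,
        ve0=comp.ve0,
        loglik=best.loglik,
        converged=best.converged,
        final_update_norm=best.final_update_norm,
        n_iter=best.n_iter,
        loglik_trace=best.loglik_trace,
        start_results=results,
        starts_disagree=disagree,
    )


def reml_loglik(
    components: Components,
    records: pd.DataFrame,
    spec: ModelSpec,
    pedigree: Pedigree,
    a_inv: sparse.spmatrix | None = None,
) -> float:
    """Restricted log-likelihood at the given components (up to a constant)."""
    par = _Parameterization(spec)
    if not par.is_valid(components):
        raise ValueError("components are not positive definite")
    design = build_design(records, spec, pedigree)
    if a_inv is None:
        a_inv = build_A_inverse(pedigree)
    problem = REMLProblem(design, a_inv)
    return float(problem.loglik(components))
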