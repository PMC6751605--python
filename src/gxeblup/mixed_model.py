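"""Multivariate mixed-model equations for PBLUP and single-step GBLUP.

The model has sex-shared genetic effects: male and female records of the
same (trait, environment) load on one genetic effect per animal (the
between-sex genetic correlation is fixed at 1, giving a reduced-rank
parameterization), a 4-trait maternal permanent-environment effect per dam,
and an 8x8 structured residual that is nonzero only within a (sex,
environment) cell across the week-5/6 pair.

Equations are laid out animal-major: [genetic (k per animal), maternal
(k per dam), fixed].  The single-step kernel is applied matrix-free: the
sparse A-inverse part is explicit and the dense genotyped-block adjustment
(G_w^-1 - A22^-1) is applied through the Kronecker identity
(H^-1 (x) Va0^-1) v = (H^-1 V) Va0^-1 with V the (animal x trait) reshape.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, sparse

from . import params as P
from .pedigree import Pedigree
from .relationships import HInverseParts


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class RecordType:
    sex: str
    week: int
    env: str

    @property
    def trait(self) -> str:
        return P.trait_label(self.week, self.env)


@dataclasses.dataclass
class ModelSpec:
    """Trait structure of a (possibly multivariate) animal model."""

    traits: tuple[str, ...]
    rtypes: tuple[RecordType, ...]
    rtype_trait_idx: tuple[int, ...]
    residual_groups: tuple[tuple[int, ...], ...]
    fixed_factors: tuple[str, ...] = ("hatch_ts", "sire_ts", "dam_ts", "dam_age_wk")
    use_maternal: bool = True
    value_column: str = "value_std"

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def n_rtypes(self) -> int:
        return len(self.rtypes)


def model2_spec(value_column: str = "value_std") -> ModelSpec:
    """The 8-record-type, 4-trait model with sex-shared genetic effects."""
    rtypes = tuple(
        RecordType(sex, P.rtype_week(r), P.rtype_env(r))
        for r, (sex, _) in enumerate(P.RECORD_TYPES)
    )
    return ModelSpec(
        traits=P.GENETIC_TRAITS,
        rtypes=rtypes,
        rtype_trait_idx=tuple(P.rtype_trait(r) for r in range(P.N_RECORD_TYPES)),
        residual_groups=P.RESIDUAL_BLOCKS,
        value_column=value_column,
    )


def model1_spec(sex: str, week: int, env: str, value_column: str = "value_g") -> ModelSpec:
    """Univariate model for one (sex, week, environment) cell."""
    return ModelSpec(
        traits=(P.trait_label(week, env),),
        rtypes=(RecordType(sex, week, env),),
        rtype_trait_idx=(0,),
        residual_groups=((0,),),
        value_column=value_column,
    )


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Design:
    spec: ModelSpec
    pedigree: Pedigree
    y: np.ndarray
    rec_rtype: np.ndarray
    rec_animal: np.ndarray  # pedigree positional index
    rec_dam: np.ndarray  # pedigree positional index, -1 = none
    rec_fixed_cols: list[np.ndarray]
    n_fixed: int
    fixed_labels: list[tuple[int, str, object]]
    dam_list: np.ndarray  # pedigree indices of dams carrying a maternal effect

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_animals(self) -> int:
        return self.pedigree.n

    @property
    def n_dams(self) -> int:
        return len(self.dam_list)

    def n_equations(self) -> int:
        k = self.spec.n_traits
        return k * self.n_animals + k * self.n_dams + self.n_fixed


def build_design(records: pd.DataFrame, spec: ModelSpec, pedigree: Pedigree) -> Design:
    """Compile a phenotype table into model design structures.

    Records not matching any record type of the spec are ignored; a record
    whose animal or dam is absent from the pedigree raises.
    """
    rt_lookup = {
        (rt.sex, rt.week, rt.env): r for r, rt in enumerate(spec.rtypes)
    }
    week = records["trait"].str.slice(2).astype(int)
    keys = list(zip(records["sex"], week, records["env"]))
    rt = np.array([rt_lookup.get(key, -1) for key in keys])
    sub = records.loc[rt >= 0].copy()
    rt = rt[rt >= 0]
    if len(sub) == 0:
        raise ValueError("no records match the model's record types")
    dup = pd.DataFrame({"animal": sub["animal"].to_numpy(), "rt": rt}).duplicated()
    if dup.any():
        raise ValueError("duplicate record for the same animal and record type")

    animal = pedigree.index_of(sub["animal"].to_numpy())
    dam_raw = sub["dam_id"].to_numpy(np.int64)
    dam = np.full(len(sub), -1, np.int64)
    has_dam = dam_raw != 0
    dam[has_dam] = pedigree.index_of(dam_raw[has_dam])

    if spec.value_column not in sub:
        raise KeyError(f"records lack the {spec.value_column!r} column")
    y = sub[spec.value_column].to_numpy(float)

    # fixed-effect columns: first factor keeps all levels (absorbs the cell
    # mean), later factors are reference-coded within each record type
    fixed_labels: list[tuple[int, str, object]] = []
    col_of: dict[tuple[int, str, object], int] = {}
    rec_cols: list[list[int]] = [[] for _ in range(len(sub))]
    for r in range(spec.n_rtypes):
        in_rt = np.flatnonzero(rt == r)
        if len(in_rt) == 0:
            continue
        for fi, factor in enumerate(spec.fixed_factors):
            if factor not in sub:
                raise KeyError(f"records lack fixed factor column {factor!r}")
            values = sub[factor].to_numpy()[in_rt]
            levels = sorted(set(values.tolist()))
            drop = None if fi == 0 else levels[0]
            for lev in levels:
                if lev == drop:
                    continue
                col_of[(r, factor, lev)] = len(fixed_labels)
                fixed_labels.append((r, factor, lev))
            for pos, lev in zip(in_rt, values):
                key = (r, factor, lev)
                if key in col_of:
                    rec_cols[pos].append(col_of[key])

    # drop aliased fixed columns (rank-revealing QR within each record type,
    # where fixed columns are disjoint): keeps the MME full rank without
    # changing the fixed-effect column space, so EBV are unaffected
    keep = _unaliased_columns(rec_cols, rt, len(fixed_labels), spec.n_rtypes)
    if len(keep) < len(fixed_labels):
        remap = {old: new for new, old in enumerate(keep)}
        fixed_labels = [fixed_labels[old] for old in keep]
        rec_cols = [[remap[c] for c in cols if c in remap] for cols in rec_cols]

    dam_list = np.unique(dam[dam >= 0]) if spec.use_maternal else np.empty(0, np.int64)
    return Design(
        spec=spec,
        pedigree=pedigree,
        y=y,
        rec_rtype=rt,
        rec_animal=animal,
        rec_dam=dam,
        rec_fixed_cols=[np.array(c, np.int64) for c in rec_cols],
        n_fixed=len(fixed_labels),
        fixed_labels=fixed_labels,
        dam_list=dam_list,
    )


def _unaliased_columns(
    rec_cols: list[list[int]], rt: np.ndarray, n_cols: int, n_rtypes: int
) -> list[int]:
    """Indices of fixed columns that are not linearly dependent within their
    record type (pivoted-QR rank detection on the 0/1 incidence)."""
    keep: list[int] = []
    for r in range(n_rtypes):
        rows = np.flatnonzero(rt == r)
        cols = sorted({c for i in rows for c in rec_cols[i]})
        if not cols:
            continue
        col_pos = {c: j for j, c in enumerate(cols)}
        X = np.zeros((len(rows), len(cols)))
        for ii, i in enumerate(rows):
            for c in rec_cols[i]:
                X[ii, col_pos[c]] = 1.0
        _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 1.0)
        rank = int(np.sum(diag > max(tol, 1e-10)))
        keep.extend(cols[j] for j in sorted(piv[:rank]))
    return sorted(keep)


# ---------------------------------------------------------------------------
# compiled assembly structures
# ---------------------------------------------------------------------------


class CompiledModel:
    """Vectorized assembly arrays for repeated MME construction.

    All index arrays are computed once; per-iteration work is numeric only
    (new residual inverse table, new covariance inverses).
    """

    def __init__(self, design: Design):
        self.design = design
        spec = design.spec
        k = spec.n_traits
        self.k = k
        n, nd = design.n_animals, design.n_dams
        self.go, self.mo, self.fo = 0, k * n, k * (n + nd)
        self.n_eq = design.n_equations()

        dam_pos = {int(d): i for i, d in enumerate(design.dam_list)}
        tr = np.array(spec.rtype_trait_idx)
        self.rec_gcol = self.go + k * design.rec_animal + tr[design.rec_rtype]
        self.rec_mcol = np.full(design.n_records, -1, np.int64)
        if spec.use_maternal:
            ok = design.rec_dam >= 0
            self.rec_mcol[ok] = self.mo + k * np.array(
                [dam_pos[int(d)] for d in design.rec_dam[ok]]
            ) + tr[design.rec_rtype[ok]]

        # group records by animal
        by_animal: dict[int, list[int]] = {}
        for idx, a in enumerate(design.rec_animal):
            by_animal.setdefault(int(a), []).append(idx)

        # residual patterns (subsets of record types observed together)
        self.patterns: list[tuple[int, ...]] = []
        pat_of: dict[tuple[int, ...], int] = {}
        self.pat_offset: list[int] = []
        offset = 0
        pat_members: dict[int, int] = {}

        ew_row: list[np.ndarray] = []
        ew_col: list[np.ndarray] = []
        ew_patab: list[int] = []
        ew_slot: list[int] = []
        wr_col: list[np.ndarray] = []
        wr_rec: list[int] = []
        wr_patab: list[int] = []
        ra_reca: list[int] = []
        ra_recb: list[int] = []
        ra_patab: list[int] = []
        slot_patab: list[int] = []
        slot_count = 0
        pat_rec_rows: dict[int, list[list[int]]] = {}
        pat_slot0: dict[int, list[int]] = {}

        def cols_of(rec: int) -> np.ndarray:
            cols = [self.fo + c for c in design.rec_fixed_cols[rec]]
            cols.append(self.rec_gcol[rec])
            if self.rec_mcol[rec] >= 0:
                cols.append(self.rec_mcol[rec])
            return np.array(cols, np.int64)

        self._rec_cols = [cols_of(i) for i in range(design.n_records)]

        for a, recs in by_animal.items():
            recs = sorted(recs, key=lambda i: design.rec_rtype[i])
            pat = tuple(int(design.rec_rtype[i]) for i in recs)
            if pat not in pat_of:
                pat_of[pat] = len(self.patterns)
                self.patterns.append(pat)
                self.pat_offset.append(offset)
                offset += len(pat) * len(pat)
            p = pat_of[pat]
            pat_members[p] = pat_members.get(p, 0) + 1
            kp = len(pat)
            base = self.pat_offset[p]
            pat_rec_rows.setdefault(p, []).append(list(recs))
            pat_slot0.setdefault(p, []).append(slot_count)
            for ai, ra in enumerate(recs):
                ca = self._rec_cols[ra]
                for bi, rb in enumerate(recs):
                    patab = base + ai * kp + bi
                    cb = self._rec_cols[rb]
                    ew_row.append(np.repeat(ca, len(cb)))
                    ew_col.append(np.tile(cb, len(ca)))
                    ew_patab.extend([patab] * (len(ca) * len(cb)))
                    ew_slot.extend([slot_count] * (len(ca) * len(cb)))
                    slot_patab.append(patab)
                    slot_count += 1
                    wr_col.append(ca)
                    wr_rec.extend([rb] * len(ca))
                    wr_patab.extend([patab] * len(ca))
                    ra_reca.append(ra)
                    ra_recb.append(rb)
                    ra_patab.append(patab)

        self.pat_count = np.array(
            [pat_members.get(p, 0) for p in range(len(self.patterns))]
        )
        self.rinv_size = offset
        self.ew_row = np.concatenate(ew_row)
        self.ew_col = np.concatenate(ew_col)
        self.ew_patab = np.array(ew_patab, np.int64)
        self.ew_slot = np.array(ew_slot, np.int64)
        self.n_slots = slot_count
        self.slot_patab = np.array(slot_patab, np.int64)
        self.wr_col = np.concatenate(wr_col)
        self.wr_rec = np.array(wr_rec, np.int64)
        self.wr_patab = np.array(wr_patab, np.int64)
        self.ra_reca = np.array(ra_reca, np.int64)
        self.ra_recb = np.array(ra_recb, np.int64)
        self.ra_patab = np.array(ra_patab, np.int64)
        self.wa_rec = np.concatenate(
            [np.full(len(c), i, np.int64) for i, c in enumerate(self._rec_cols)]
        )
        self.wa_col = np.concatenate(self._rec_cols)
        #: per pattern: member record indices (n_members, kp) and the first
        #: slot id of each member (its slots are slot0 + a*kp + b)
        self.pat_rec = [
            np.array(pat_rec_rows.get(p, []), np.int64).reshape(-1, len(pat))
            for p, pat in enumerate(self.patterns)
        ]
        self.pat_slot0 = [
            np.array(pat_slot0.get(p, []), np.int64) for p in range(len(self.patterns))
        ]

        self._kron_cache: dict[str, tuple] = {}

    # -- residual tables --------------------------------------------------
    def rinv_table(self, ve0: np.ndarray) -> tuple[np.ndarray, float]:
        """Flat per-pattern residual-inverse table and log|R|."""
        flat = np.empty(self.rinv_size)
        logdet = 0.0
        for p, pat in enumerate(self.patterns):
            block = ve0[np.ix_(pat, pat)]
            sign, ld = np.linalg.slogdet(block)
            if sign <= 0:
                raise np.linalg.LinAlgError("singular residual sub-block")
            inv = np.linalg.inv(block)
            kp = len(pat)
            self_off = self.pat_offset[p]
            flat[self_off : self_off + kp * kp] = inv.ravel()
            logdet += self.pat_count[p] * ld
        return flat, logdet

    # -- operator pieces ---------------------------------------------------
    def wt_rinv(self, flat: np.ndarray, v: np.ndarray) -> np.ndarray:
        """W' R^-1 v (record space -> equation space)."""
        return np.bincount(
            self.wr_col,
            weights=flat[self.wr_patab] * v[self.wr_rec],
            minlength=self.n_eq,
        )

    def rinv_apply(self, flat: np.ndarray, v: np.ndarray) -> np.ndarray:
        return np.bincount(
            self.ra_reca,
            weights=flat[self.ra_patab] * v[self.ra_recb],
            minlength=self.design.n_records,
        )

    def w_apply(self, s: np.ndarray) -> np.ndarray:
        return np.bincount(
            self.wa_rec, weights=s[self.wa_col], minlength=self.design.n_records
        )

    def quad_y_rinv_y(self, flat: np.ndarray, y: np.ndarray) -> float:
        return float(np.sum(flat[self.ra_patab] * y[self.ra_reca] * y[self.ra_recb]))

    # -- kron helpers ------------------------------------------------------
    def kron_arrays(self, key: str, kernel_coo: sparse.coo_matrix, offset: int):
        """Index arrays of kron(kernel, V^-1) in the equation layout."""
        if key not in self._kron_cache:
            k = self.k
            nnz = kernel_coo.nnz
            t_idx = np.tile(np.repeat(np.arange(k), k), nnz)
            s_idx = np.tile(np.tile(np.arange(k), k), nnz)
            rows = np.repeat(offset + k * kernel_coo.row, k * k) + t_idx
            cols = np.repeat(offset + k * kernel_coo.col, k * k) + s_idx
            data_rep = np.repeat(kernel_coo.data, k * k)
            ts_flat = t_idx * k + s_idx
            self._kron_cache[key] = (rows, cols, data_rep, ts_flat)
        return self._kron_cache[key]

    def w_part_coo(self, flat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.ew_row, self.ew_col, flat[self.ew_patab]


# ---------------------------------------------------------------------------
# MME system
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MMESystem:
    """Assembled (possibly matrix-free) mixed-model equations."""

    compiled: CompiledModel
    sparse_part: sparse.csr_matrix
    rhs: np.ndarray
    va0_inv: np.ndarray
    delta: np.ndarray | None = None  # dense genotyped-block kernel adjustment
    geno_idx: np.ndarray | None = None

    @property
    def n_eq(self) -> int:
        return self.compiled.n_eq

    def matvec(self, v: np.ndarray) -> np.ndarray:
        out = self.sparse_part @ v
        if self.delta is not None:
            k = self.compiled.k
            n = self.compiled.design.n_animals
            V = v[: k * n].reshape(n, k)
            adj = (self.delta @ V[self.geno_idx]) @ self.va0_inv
            block = out[: k * n].reshape(n, k)
            block[self.geno_idx] += adj
        return out

    def to_dense(self) -> np.ndarray:
        lhs = self.sparse_part.toarray()
        if self.delta is not None:
            k = self.compiled.k
            idx = self.geno_idx
            for a, i in enumerate(idx):
                for b, j in enumerate(idx):
                    lhs[k * i : k * i + k, k * j : k * j + k] += (
                        self.delta[a, b] * self.va0_inv
                    )
        return lhs

    def diag_blocks(self) -> tuple[np.ndarray, np.ndarray]:
        """(k x k diagonal blocks over animals+dams, fixed-part diagonal)."""
        k = self.compiled.k
        nblk = self.compiled.design.n_animals + self.compiled.design.n_dams
        lim = k * nblk
        coo = self.sparse_part.tocoo()
        blocks = np.zeros((nblk, k, k))
        inblk = (coo.row < lim) & (coo.col < lim) & (coo.row // k == coo.col // k)
        np.add.at(
            blocks,
            (coo.row[inblk] // k, coo.row[inblk] % k, coo.col[inblk] % k),
            coo.data[inblk],
        )
        if self.delta is not None:
            d = np.diag(self.delta)
            blocks[self.geno_idx] += d[:, None, None] * self.va0_inv
        fixed_diag = self.sparse_part.diagonal()[lim:]
        return blocks, fixed_diag


def assemble_mme(
    design: Design | CompiledModel,
    va0: np.ndarray,
    ve0: np.ndarray,
    kernel_inverse,
    vc0: np.ndarray | None = None,
) -> MMESystem:
    """Henderson mixed-model equations for the given covariance values.

    ``kernel_inverse`` is either a sparse matrix (A-inverse; PBLUP) or an
    :class:`~gxeblup.relationships.HInverseParts` (single-step).
    """
    compiled = design if isinstance(design, CompiledModel) else CompiledModel(design)
    k = compiled.k
    va0 = np.atleast_2d(np.asarray(va0, float))
    va0_inv = np.linalg.inv(va0)
    flat, _ = compiled.rinv_table(np.atleast_2d(np.asarray(ve0, float)))

    delta = None
    geno_idx = None
    if isinstance(kernel_inverse, HInverseParts):
        a_inv = kernel_inverse.a_inv
        delta = kernel_inverse.delta
        geno_idx = np.asarray(kernel_inverse.geno_idx, np.int64)
    else:
        a_inv = kernel_inverse
    a_coo = sparse.coo_matrix(a_inv)
    kr, kc, kdata, kts = compiled.kron_arrays("genetic", a_coo, compiled.go)
    rows = [compiled.ew_row, kr]
    cols = [compiled.ew_col, kc]
    vals = [flat[compiled.ew_patab], kdata * va0_inv.ravel()[kts]]

    if compiled.design.spec.use_maternal and compiled.design.n_dams:
        if vc0 is None:
            raise ValueError("model uses a maternal effect but vc0 is missing")
        vc0_inv = np.linalg.inv(np.atleast_2d(np.asarray(vc0, float)))
        nd = compiled.design.n_dams
        eye = sparse.identity(nd, format="coo")
        mr, mc_, mdata, mts = compiled.kron_arrays("maternal", eye, compiled.mo)
        rows.append(mr)
        cols.append(mc_)
        vals.append(mdata * vc0_inv.ravel()[mts])

    n_eq = compiled.n_eq
    lhs = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_eq, n_eq),
    ).tocsr()
    rhs = compiled.wt_rinv(flat, compiled.design.y)
    return MMESystem(
        compiled=compiled,
        sparse_part=lhs,
        rhs=rhs,
        va0_inv=va0_inv,
        delta=delta,
        geno_idx=geno_idx,
    )


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------

DENSE_LIMIT = 10_000


def solve_direct(system: MMESystem, dense_limit: int = DENSE_LIMIT) -> np.ndarray:
    """Dense symmetric solve (test oracle for small systems)."""
    if system.n_eq > dense_limit:
        raise ValueError(
            f"system has {system.n_eq} equations, above the dense limit {dense_limit}"
        )
    lhs = system.to_dense()
    try:
        c, low = linalg.cho_factor(lhs)
        return linalg.cho_solve((c, low), system.rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "mixed-model equations are rank deficient beyond the applied "
            "identifiability constraints"
        ) from exc


@dataclasses.dataclass
class PCGResult:
    x: np.ndarray
    n_iter: int
    rel_residual: float


def solve_pcg(
    system: MMESystem,
    tol: float = 1e-8,
    max_iter: int = 5000,
    x0: np.ndarray | None = None,
) -> PCGResult:
    """Preconditioned conjugate gradients with a block-Jacobi preconditioner."""
    blocks, fixed_diag = system.diag_blocks()
    block_inv = np.linalg.inv(blocks)
    fixed_inv = np.where(fixed_diag > 0, 1.0 / np.where(fixed_diag > 0, fixed_diag, 1.0), 0.0)
    k = system.compiled.k
    lim = blocks.shape[0] * k

    def precond(r: np.ndarray) -> np.ndarray:
        z = np.empty_like(r)
        R = r[:lim].reshape(-1, k)
        z[:lim] = np.einsum("nij,nj->ni", block_inv, R).ravel()
        z[lim:] = fixed_inv * r[lim:]
        return z

    b = system.rhs
    bnorm = np.linalg.norm(b)
    if bnorm == 0:
        return PCGResult(np.zeros(system.n_eq), 0, 0.0)
    x = np.zeros(system.n_eq) if x0 is None else x0.copy()
    r = b - system.matvec(x)
    if np.linalg.norm(r) / bnorm < tol:
        return PCGResult(x, 0, float(np.linalg.norm(r) / bnorm))
    z = precond(r)
    p = z.copy()
    rz = r @ z
    for it in range(1, max_iter + 1):
        Ap = system.matvec(p)
        alpha = rz / (p @ Ap)
        x += alpha * p
        r -= alpha * Ap
        rel = np.linalg.norm(r) / bnorm
        if rel < tol:
            return PCGResult(x, it, float(rel))
        z = precond(r)
        rz_new = r @ z
        p = z + (rz_new / rz) * p
        rz = rz_new
    raise RuntimeError(
        f"PCG did not converge in {max_iter} iterations "
        f"(relative residual {rel:.3e}, tol {tol:.1e})"
    )


# ---------------------------------------------------------------------------
# EBV prediction
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class EBVTable:
    """EBV (standardized scale) for every pedigree animal."""

    ids: np.ndarray
    values: np.ndarray  # (n_animals, n_traits)
    traits: tuple[str, ...]
    model: str = ""
    dataset: str = ""

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.traits))
        df.insert(0, "animal", self.ids)
        df = df.melt(id_vars="animal", var_name="trait", value_name="ebv")
        df["model"] = self.model
        df["dataset"] = self.dataset
        return df

    def for_animals(self, labels: np.ndarray) -> np.ndarray:
        pos = pd.Index(self.ids).get_indexer(np.asarray(labels, np.int64))
        if np.any(pos < 0):
            raise KeyError("animals missing from EBV table")
        return self.values[pos]


def predict_ebv(
    records: pd.DataFrame,
    spec: ModelSpec,
    pedigree: Pedigree,
    kernel_inverse,
    va0: np.ndarray,
    ve0: np.ndarray,
    vc0: np.ndarray | None = None,
    method: str = "auto",
    tol: float = 1e-8,
    max_iter: int = 5000,
    model: str = "",
    dataset: str = "",
) -> EBVTable:
    """End-to-end EBV prediction: design -> assemble -> solve -> table.

    With no matching records the information content is zero and the EBV
    are identically zero."""
    if len(records) == 0:
        return EBVTable(
            ids=pedigree.ids.copy(),
            values=np.zeros((pedigree.n, spec.n_traits)),
            traits=spec.traits,
            model=model,
            dataset=dataset,
        )
    design = build_design(records, spec, pedigree)
    system = assemble_mme(design, va0, ve0, kernel_inverse, vc0=vc0)
    if method == "direct" or (method == "auto" and system.n_eq <= 2000):
        sol = solve_direct(system, dense_limit=max(DENSE_LIMIT, system.n_eq))
    else:
        sol = solve_pcg(system, tol=tol, max_iter=max_iter).x
    k = spec.n_traits
    ebv = sol[: k * pedigree.n].reshape(pedigree.n, k)
    return EBVTable(
        ids=pedigree.ids.copy(),
        values=ebv,
        traits=spec.traits,
        model=model,
        dataset=dataset,
    )
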