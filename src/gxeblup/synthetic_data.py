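"""Synthetic sib-testing breeding program with selective genotyping.

Generates overlapping-generation pedigrees in which every full-sib family
is split between a bio-secure (B) and a commercial (C) environment, parents
are selected from B only, true breeding values are carried by additive SNP
effects (gene dropping), maternal permanent-environment effects are shared
within dam families and phenotype recording follows a per-time-step
missingness plan.  The defaults emulate the structure of a commercial
broiler program: 16 time-steps, ~2.5 generations, four genetic traits
(body weight at weeks 5/6 in B and C) with a genetic correlation of ~0.5
between environments, sex-specific scaling to grams, and top-phenotype
selective genotyping within B.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from . import params as P
from .pedigree import Pedigree
from .relationships import GenotypeMatrix

MissingnessPlan = Mapping[int, Mapping[str, Mapping[int, float]]]


@dataclasses.dataclass
class SimConfig:
    """Configuration of the synthetic breeding program."""

    n_time_steps: int = 16
    n_sires_per_ts: int = 8
    n_dams_per_ts: int = 16
    offspring_per_dam: int = 12
    prop_to_C: float = 0.3
    prop_genotyped_B: float = 0.3
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    selection_trait: str = "auto"
    missingness_plan: MissingnessPlan | None = None
    seed: int = 0
    dam_age_range: tuple[int, int] = (30, 60)
    parent_ts_window: int = 3
    random_mating: bool = False
    n_founder_males: int | None = None
    n_founder_females: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_time_steps", "n_sires_per_ts", "n_dams_per_ts",
                     "offspring_per_dam", "n_snps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("prop_to_C", "prop_genotyped_B"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_founder_males is None:
            self.n_founder_males = 2 * self.n_sires_per_ts
        if self.n_founder_females is None:
            self.n_founder_females = 2 * self.n_dams_per_ts

    def plan(self) -> MissingnessPlan:
        if self.missingness_plan is not None:
            return self.missingness_plan
        return default_missingness_plan(self.n_time_steps)


def default_missingness_plan(n_ts: int) -> MissingnessPlan:
    """Recording plan per time-step, mirroring the study design.

    B environment: week-6 weight only during the first ~10/16 of the
    program; afterwards week-5 weight on everyone plus week-6 on a 33%
    random subset.  C environment: testing starts at ~5/16 of the program
    with both weights, only week-5 late.
    """
    b_switch = int(np.floor(n_ts * 10 / 16))
    c_start = int(np.ceil(n_ts * 5 / 16))
    plan: dict[int, dict[str, dict[int, float]]] = {}
    for ts in range(1, n_ts + 1):
        entry: dict[str, dict[int, float]] = {}
        if ts <= b_switch:
            entry["B"] = {6: 1.0}
        else:
            entry["B"] = {5: 1.0, 6: 0.33}
        if c_start <= ts <= b_switch:
            entry["C"] = {5: 1.0, 6: 1.0}
        elif ts > b_switch:
            entry["C"] = {5: 1.0}
        plan[ts] = entry
    return plan


@dataclasses.dataclass
class SimulatedDataset:
    pedigree: Pedigree
    phenotypes: pd.DataFrame
    genotypes: GenotypeMatrix
    true_bv: np.ndarray  # (n_animals, 4), genetic-trait order
    genotyped: np.ndarray  # bool per animal
    environment: np.ndarray

    def true_bv_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.true_bv, columns=list(P.GENETIC_TRAITS))
        df.insert(0, "animal", self.pedigree.ids)
        return df


def _mvn(rng: np.random.Generator, cov: np.ndarray, size: int) -> np.ndarray:
    """MVN(0, cov) draws tolerant of positive semi-definite covariances."""
    cov = np.asarray(cov, float)
    k = cov.shape[0]
    if size == 0:
        return np.zeros((0, k))
    if not np.any(cov):
        return np.zeros((size, k))
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    L = v * np.sqrt(w)
    return rng.standard_normal((size, k)) @ L.T


# ---------------------------------------------------------------------------
# pedigree construction
# ---------------------------------------------------------------------------


class _PedigreeBuilder:
    def __init__(self) -> None:
        self.sire: list[int] = []
        self.dam: list[int] = []
        self.sex: list[str] = []
        self.ts: list[int] = []
        self.env: list[str] = []

    @property
    def n(self) -> int:
        return len(self.sire)

    def add(self, sire: int, dam: int, sex: str, ts: int, env: str) -> int:
        self.sire.append(sire)
        self.dam.append(dam)
        self.sex.append(sex)
        self.ts.append(ts)
        self.env.append(env)
        return self.n - 1

    def build(self) -> Pedigree:
        n = self.n
        ped = Pedigree(
            ids=np.arange(1, n + 1),
            sire=np.array(self.sire, np.int64),
            dam=np.array(self.dam, np.int64),
            sex=np.array(self.sex),
            time_step=np.array(self.ts, np.int64),
            environment=np.array(self.env),
        )
        ped.validate()
        return ped


def _family_assignments(
    rng: np.random.Generator, config: SimConfig, ts: int
) -> tuple[list[str], list[str]]:
    """Sexes (1:1) and environments (floor rule) for one full-sib family."""
    size = config.offspring_per_dam
    n_c = int(np.floor(config.prop_to_C * size))
    plan = config.plan().get(ts, {})
    needs_b = bool(plan.get("B"))
    needs_c = bool(plan.get("C"))
    if needs_c and n_c == 0 and config.prop_to_C > 0:
        raise ValueError(
            f"prop_to_C={config.prop_to_C} leaves families without members in C "
            f"at time-step {ts} although C records are required"
        )
    if needs_b and n_c == size:
        raise ValueError(
            f"prop_to_C={config.prop_to_C} leaves families without members in B "
            f"at time-step {ts} although B records are required"
        )
    envs = ["C"] * n_c + ["B"] * (size - n_c)
    rng.shuffle(envs)
    half = size // 2
    sexes = ["M"] * half + ["F"] * (size - half)
    if size % 2 == 1 and rng.random() < 0.5:
        sexes[-1] = "M"
    rng.shuffle(sexes)
    return sexes, envs


def _select_parents(
    rng: np.random.Generator,
    builder: _PedigreeBuilder,
    config: SimConfig,
    ts: int,
    selection_score: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick sires and dams for time-step ``ts`` from the B candidate pool."""
    lo = ts - config.parent_ts_window
    ts_arr = np.array(builder.ts)
    env_arr = np.array(builder.env)
    sex_arr = np.array(builder.sex)
    pool = np.flatnonzero((ts_arr >= lo) & (ts_arr < ts) & (env_arr == "B"))
    males = pool[sex_arr[pool] == "M"]
    females = pool[sex_arr[pool] == "F"]
    if len(males) < config.n_sires_per_ts or len(females) < config.n_dams_per_ts:
        raise ValueError(
            f"candidate pool at time-step {ts} too small "
            f"({len(males)} males, {len(females)} females)"
        )

    def pick(cands: np.ndarray, k: int) -> np.ndarray:
        if config.random_mating or selection_score is None:
            return rng.choice(cands, size=k, replace=False)
        score = selection_score[cands]
        # animals without a score (unphenotyped, e.g. founders) rank last
        score = np.where(np.isnan(score), -np.inf, score)
        order = np.lexsort((cands, -score))
        return cands[order[:k]]

    sires = pick(males, config.n_sires_per_ts)
    dams = pick(females, config.n_dams_per_ts)
    return sires, dams


def simulate_pedigree(config: SimConfig, rng_seed: int) -> Pedigree:
    """Overlapping-generation pedigree with random parent draws.

    Founders sit in time-step 0; each later time-step draws its parents
    from the B-environment animals of the preceding time-steps, mates each
    dam to one sire, and splits every full-sib family between B and C.
    The deterministic floor rule sends floor(prop_to_C * family size)
    members to C.  Phenotype-truncation parent selection is performed by
    :func:`simulate_dataset`, which interleaves selection with phenotype
    generation.
    """
    rng = np.random.default_rng(rng_seed)
    builder = _PedigreeBuilder()
    _add_founders(builder, config)
    for ts in range(1, config.n_time_steps + 1):
        sires, dams = _select_parents(rng, builder, config, ts, None)
        _mate_and_drop(rng, builder, config, ts, sires, dams)
    return builder.build()


def _add_founders(builder: _PedigreeBuilder, config: SimConfig) -> None:
    for _ in range(config.n_founder_males):
        builder.add(-1, -1, "M", 0, "B")
    for _ in range(config.n_founder_females):
        builder.add(-1, -1, "F", 0, "B")


def _mate_and_drop(
    rng: np.random.Generator,
    builder: _PedigreeBuilder,
    config: SimConfig,
    ts: int,
    sires: np.ndarray,
    dams: np.ndarray,
) -> list[tuple[int, int, int]]:
    """Mate dams to sires and append offspring; returns (child, sire, dam)."""
    sire_of_dam = np.tile(sires, int(np.ceil(len(dams) / len(sires))))[: len(dams)]
    out = []
    for dam, sire in zip(dams, sire_of_dam):
        sexes, envs = _family_assignments(rng, config, ts)
        for sex, env in zip(sexes, envs):
            child = builder.add(int(sire), int(dam), sex, ts, env)
            out.append((child, int(sire), int(dam)))
    return out


# ---------------------------------------------------------------------------
# genotypes and true breeding values
# ---------------------------------------------------------------------------


def _founder_frequencies(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=config.n_snps)


def _drop_genotypes(
    rng: np.random.Generator,
    pedigree: Pedigree,
    freqs: np.ndarray,
) -> np.ndarray:
    """Gene dropping: HW founders, one allele per parent, no linkage."""
    n, m = pedigree.n, len(freqs)
    M = np.empty((n, m))
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        pat = (
            rng.binomial(1, M[s] / 2.0)
            if s >= 0
            else rng.binomial(1, freqs)
        )
        mat = (
            rng.binomial(1, M[d] / 2.0)
            if d >= 0
            else rng.binomial(1, freqs)
        )
        M[i] = pat + mat
    return M


def simulate_genotypes(
    pedigree: Pedigree, config: SimConfig, rng_seed: int
) -> GenotypeMatrix:
    """SNP dosages for every pedigree animal by gene dropping."""
    pedigree.validate()
    rng = np.random.default_rng(rng_seed)
    freqs = _founder_frequencies(rng, config)
    M = _drop_genotypes(rng, pedigree, freqs)
    snp_ids = np.array([f"SNP{j + 1}" for j in range(config.n_snps)])
    return GenotypeMatrix(pedigree.ids.copy(), snp_ids, M)


def _snp_effects(
    rng: np.random.Generator,
    dosages: np.ndarray,
    founder_rows: np.ndarray,
    va0: np.ndarray,
) -> np.ndarray:
    """Additive 4-trait SNP effects with base-population genetic covariance
    exactly ``va0``.

    The effects are rescaled so that the locus-weighted effect covariance
    sum_j 2 p_j (1 - p_j) beta_j beta_j' equals ``va0``: this makes both
    the expected founder covariance and the Mendelian-sampling covariance
    consistent with the same base-population parameters, as the animal
    model assumes.  (Forcing the founder *sample* covariance instead would
    push the locus-effect covariance away from ``va0`` by the inverse of
    the founder sampling noise and make the data internally inconsistent.)
    """
    m = dosages.shape[1]
    pf = dosages[founder_rows].mean(axis=0) / 2.0
    denom = 2.0 * np.sum(pf * (1.0 - pf))
    if denom <= 0 or not np.any(va0):
        return np.zeros((m, va0.shape[0]))
    beta = _mvn(rng, va0 / denom, m)
    s_eff = (beta.T * (2.0 * pf * (1.0 - pf))) @ beta
    try:
        Ls = np.linalg.cholesky(s_eff)
        La = np.linalg.cholesky(va0)
        T = La @ np.linalg.inv(Ls)
        beta = beta @ T.T
    except np.linalg.LinAlgError:
        scale = np.sqrt(np.diag(va0) / np.maximum(np.diag(s_eff), 1e-12))
        beta = beta * scale
    return beta


def _breeding_values(
    dosages: np.ndarray, founder_rows: np.ndarray, beta: np.ndarray
) -> np.ndarray:
    pf = dosages[founder_rows].mean(axis=0) / 2.0
    return (dosages - 2.0 * pf) @ beta


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


class _PhenotypeEngine:
    """Draws fixed-effect levels, maternal effects and residuals on demand."""

    def __init__(self, params, config: SimConfig, rng: np.random.Generator):
        self.params = params
        self.config = config
        self.rng = rng
        sizes = params.fixed_effect_sizes
        self._level_effects: dict[tuple[str, int], float] = {}
        self._sizes = {
            "hatch_ts": sizes.get("hatch_ts", 0.0),
            "sire_ts": sizes.get("parent_ts", 0.0),
            "dam_ts": sizes.get("parent_ts", 0.0),
            "dam_age": sizes.get("dam_age", 0.0),
        }
        self._maternal: dict[int, np.ndarray] = {}
        self._dam_age: dict[tuple[int, int], int] = {}
        bad = (~np.isclose(params.ve0, 0.0)) & P.residual_zero_mask()
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "Ve0_true violates the structural-zero pattern at "
                f"({P.RECORD_TYPES[i]}, {P.RECORD_TYPES[j]})"
            )

    def level_effect(self, factor: str, level: int) -> float:
        key = (factor, int(level))
        if key not in self._level_effects:
            self._level_effects[key] = self.rng.normal(0.0, self._sizes[factor])
        return self._level_effects[key]

    def maternal(self, dam: int) -> np.ndarray:
        if dam not in self._maternal:
            self._maternal[dam] = _mvn(self.rng, self.params.vc0, 1)[0]
        return self._maternal[dam]

    def dam_age(self, dam: int, ts: int) -> int:
        key = (dam, ts)
        if key not in self._dam_age:
            lo, hi = self.config.dam_age_range
            self._dam_age[key] = int(self.rng.integers(lo, hi + 1))
        return self._dam_age[key]

    def records_for_ts(
        self,
        pedigree_arrays: dict,
        animals: np.ndarray,
        ts: int,
        true_bv: np.ndarray,
    ) -> list[dict]:
        """Generate phenotype rows for the given animals of one time-step."""
        plan = self.config.plan().get(ts, {})
        if not plan:
            return []
        sire = pedigree_arrays["sire"]
        dam = pedigree_arrays["dam"]
        sex = pedigree_arrays["sex"]
        env = pedigree_arrays["env"]
        ts_arr = pedigree_arrays["ts"]
        ids = pedigree_arrays["ids"]
        rows: list[dict] = []
        for i in animals:
            e = env[i]
            cell = plan.get(e)
            if not cell:
                continue
            sx = sex[i]
            # joint residual for the week-5/6 pair of this animal's cell
            r5 = P.rtype_index(sx, 5, e)
            r6 = P.rtype_index(sx, 6, e)
            block = self.params.ve0[np.ix_((r5, r6), (r5, r6))]
            resid = _mvn(self.rng, block, 1)[0]
            d = dam[i]
            mat = self.maternal(int(d)) if d >= 0 else np.zeros(P.N_TRAITS)
            for wk_pos, week in enumerate((5, 6)):
                frac = cell.get(week, 0.0)
                if frac <= 0.0 or (frac < 1.0 and self.rng.random() >= frac):
                    continue
                t = P.trait_index(week, e)
                key = (sx, week, e)
                sd = self.params.sex_sd[key]
                baseline = self.params.mean_g.get(key, 0.0) / sd
                s_ts = int(ts_arr[sire[i]]) if sire[i] >= 0 else -1
                d_ts = int(ts_arr[d]) if d >= 0 else -1
                age = self.dam_age(int(d), ts) if d >= 0 else -1
                y0 = (
                    baseline
                    + self.level_effect("hatch_ts", ts)
                    + self.level_effect("sire_ts", s_ts)
                    + self.level_effect("dam_ts", d_ts)
                    + self.level_effect("dam_age", age)
                    + true_bv[i, t]
                    + mat[t]
                    + resid[wk_pos]
                )
                rows.append(
                    {
                        "animal": int(ids[i]),
                        "trait": f"BW{week}",
                        "env": e,
                        "sex": sx,
                        "value_g": y0 * sd,
                        "hatch_ts": ts,
                        "sire_ts": s_ts,
                        "dam_ts": d_ts,
                        "dam_id": int(ids[d]) if d >= 0 else 0,
                        "dam_age_wk": age,
                    }
                )
        return rows


def _pedigree_arrays(pedigree: Pedigree) -> dict:
    return {
        "ids": pedigree.ids,
        "sire": pedigree.sire,
        "dam": pedigree.dam,
        "sex": pedigree.sex,
        "env": pedigree.environment,
        "ts": pedigree.time_step,
    }


_PHENO_COLUMNS = [
    "animal", "trait", "env", "sex", "value_g",
    "hatch_ts", "sire_ts", "dam_ts", "dam_id", "dam_age_wk",
]


def simulate_phenotypes(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    params,
    config: SimConfig,
    rng_seed: int,
) -> SimulatedDataset:
    """Phenotypes for an existing pedigree (one shot, no selection loop)."""
    if pedigree.environment is None:
        raise ValueError("pedigree carries no environment assignment")
    rng = np.random.default_rng(rng_seed)
    founder_rows = pedigree.founders()
    beta = _snp_effects(rng, genotypes.dosages, founder_rows, params.va0)
    true_bv = _breeding_values(genotypes.dosages, founder_rows, beta)
    engine = _PhenotypeEngine(params, config, rng)
    arrays = _pedigree_arrays(pedigree)
    rows: list[dict] = []
    for ts in sorted(set(pedigree.time_step.tolist())):
        animals = np.flatnonzero(pedigree.time_step == ts)
        rows.extend(engine.records_for_ts(arrays, animals, int(ts), true_bv))
    phenotypes = pd.DataFrame(rows, columns=_PHENO_COLUMNS)
    return SimulatedDataset(
        pedigree=pedigree,
        phenotypes=phenotypes,
        genotypes=genotypes,
        true_bv=true_bv,
        genotyped=np.ones(pedigree.n, dtype=bool),
        environment=pedigree.environment.copy(),
    )


def _auto_selection_week(plan_cell: Mapping[int, float]) -> int | None:
    """Week recorded on every B animal of a time-step, else None."""
    for week in (5, 6):
        if plan_cell.get(week, 0.0) >= 1.0:
            return week
    return None


def simulate_dataset(config: SimConfig, params, rng_seed: int) -> SimulatedDataset:
    """Full forward simulation of the breeding program.

    Interleaves parent selection (truncation on the B-environment selection
    phenotype unless ``config.random_mating``), mating, gene dropping and
    phenotype generation time-step by time-step, then applies selective
    genotyping.  This is the generator used by the analysis pipeline.
    """
    rng = np.random.default_rng(rng_seed)
    builder = _PedigreeBuilder()
    _add_founders(builder, config)
    freqs = _founder_frequencies(rng, config)

    n_cap = builder.n + config.n_time_steps * config.n_dams_per_ts * config.offspring_per_dam
    M = np.empty((n_cap, config.n_snps))
    for i in range(builder.n):
        M[i] = rng.binomial(1, freqs) + rng.binomial(1, freqs)
    founder_rows = np.arange(builder.n)
    beta = _snp_effects(rng, M[: builder.n], founder_rows, params.va0)
    pf = M[founder_rows].mean(axis=0) / 2.0
    bv = np.empty((n_cap, P.N_TRAITS))
    bv[: builder.n] = (M[: builder.n] - 2.0 * pf) @ beta

    engine = _PhenotypeEngine(params, config, rng)
    rows: list[dict] = []
    selection_score = np.full(n_cap, np.nan)

    for ts in range(1, config.n_time_steps + 1):
        sires, dams = _select_parents(rng, builder, config, ts, selection_score)
        children = _mate_and_drop(rng, builder, config, ts, sires, dams)
        for child, s, d in children:
            M[child] = rng.binomial(1, M[s] / 2.0) + rng.binomial(1, M[d] / 2.0)
            bv[child] = (M[child] - 2.0 * pf) @ beta
        arrays = {
            "ids": np.arange(1, builder.n + 1),
            "sire": np.array(builder.sire),
            "dam": np.array(builder.dam),
            "sex": np.array(builder.sex),
            "env": np.array(builder.env),
            "ts": np.array(builder.ts),
        }
        child_idx = np.array([c for c, _, _ in children])
        new_rows = engine.records_for_ts(arrays, child_idx, ts, bv)
        rows.extend(new_rows)
        # update selection scores (standardized within sex via grams ranking)
        week = _auto_selection_week(config.plan().get(ts, {}).get("B", {}))
        for row in new_rows:
            if row["env"] != "B":
                continue
            rec_week = int(row["trait"][2])
            use = (
                config.selection_trait == "auto" and week == rec_week
            ) or config.selection_trait == row["trait"]
            if use:
                selection_score[row["animal"] - 1] = row["value_g"]

    pedigree = builder.build()
    n = pedigree.n
    snp_ids = np.array([f"SNP{j + 1}" for j in range(config.n_snps)])
    genotypes = GenotypeMatrix(pedigree.ids.copy(), snp_ids, M[:n])
    dataset = SimulatedDataset(
        pedigree=pedigree,
        phenotypes=pd.DataFrame(rows, columns=_PHENO_COLUMNS),
        genotypes=genotypes,
        true_bv=bv[:n],
        genotyped=np.ones(n, dtype=bool),
        environment=pedigree.environment.copy(),
    )
    return apply_selective_genotyping(dataset, config)


def apply_selective_genotyping(
    dataset: SimulatedDataset, config: SimConfig
) -> SimulatedDataset:
    """Flag genotyped animals: all of C, all parents, and the top
    ``prop_genotyped_B`` fraction of B animals per (sex, time-step) ranked
    by the selection trait (ties broken by animal identifier)."""
    ped = dataset.pedigree
    n = ped.n
    flags = np.zeros(n, dtype=bool)
    flags[dataset.environment == "C"] = True
    parents = np.union1d(ped.sire[ped.sire >= 0], ped.dam[ped.dam >= 0])
    flags[parents] = True

    prop = config.prop_genotyped_B
    if prop >= 1.0:
        flags[dataset.environment == "B"] = True
    elif prop > 0.0:
        phen = dataset.phenotypes
        plan = config.plan()
        b_idx = np.flatnonzero((dataset.environment == "B") & (ped.time_step > 0))
        for ts in np.unique(ped.time_step[b_idx]):
            cell = plan.get(int(ts), {}).get("B", {})
            if config.selection_trait == "auto":
                week = _auto_selection_week(cell)
                if week is None:
                    raise ValueError(
                        f"no fully recorded B trait at time-step {ts} to rank on"
                    )
                trait = f"BW{week}"
            else:
                trait = config.selection_trait
            sub = phen[
                (phen["env"] == "B")
                & (phen["hatch_ts"] == ts)
                & (phen["trait"] == trait)
            ]
            scores = dict(zip(sub["animal"], sub["value_g"]))
            group_idx = b_idx[ped.time_step[b_idx] == ts]
            for sex in P.SEXES:
                members = group_idx[ped.sex[group_idx] == sex]
                if len(members) == 0:
                    continue
                missing = [i for i in members if int(ped.ids[i]) not in scores]
                if missing:
                    raise ValueError(
                        f"selection trait {trait} unrecorded for B animal "
                        f"{ped.ids[missing[0]]} at time-step {ts}"
                    )
                k = int(np.floor(prop * len(members)))
                vals = np.array([scores[int(ped.ids[i])] for i in members])
                order = np.lexsort((ped.ids[members], -vals))
                flags[members[order[:k]]] = True
    return dataclasses.replace(dataset, genotyped=flags)
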