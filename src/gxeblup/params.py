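"""Trait-ordering conventions and covariance containers.

Everything in the package agrees on a single ordering of the four genetic
traits (body weight at week 5/6 in the bio-secure B and commercial C
environment) and of the eight sex-specific record types.  The record-type
order is the order of the diagonal of the scaling matrix used to move
covariance components between the standardized and the gram scale:

    male BW5.B, female BW5.B, male BW6.B, female BW6.B,
    male BW5.C, female BW5.C, male BW6.C, female BW6.C
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np

WEEKS = (5, 6)
ENVS = ("B", "C")
SEXES = ("M", "F")

#: Genetic traits, canonical order used for Va0 / Vc0 and EBV tables.
GENETIC_TRAITS = ("BW5.B", "BW6.B", "BW5.C", "BW6.C")

#: Sex-specific record types, canonical order (scaling-matrix diagonal).
RECORD_TYPES = tuple((sex, trait) for trait in GENETIC_TRAITS for sex in SEXES)

N_TRAITS = len(GENETIC_TRAITS)
N_RECORD_TYPES = len(RECORD_TYPES)

#: Residual covariance blocks: record types allowed to covary.  Residual
#: covariances between sexes and between the B and C environments are
#: structural zeros; within a (sex, environment) cell the week-5 and week-6
#: records share a 2x2 residual block.
RESIDUAL_BLOCKS = ((0, 2), (1, 3), (4, 6), (5, 7))


def trait_label(week: int, env: str) -> str:
    return f"BW{week}.{env}"


def trait_index(week: int, env: str) -> int:
    return GENETIC_TRAITS.index(trait_label(week, env))


def rtype_index(sex: str, week: int, env: str) -> int:
    return 2 * trait_index(week, env) + SEXES.index(sex)


def rtype_trait(r: int) -> int:
    """Genetic-trait index of record type ``r``."""
    return r // 2


def rtype_sex(r: int) -> str:
    return SEXES[r % 2]


def rtype_env(r: int) -> str:
    return "B" if r // 2 < 2 else "C"


def rtype_week(r: int) -> int:
    return WEEKS[(r // 2) % 2]


def expansion_matrix() -> np.ndarray:
    """The 8x4 0/1 matrix mapping genetic traits to record types.

    Row order is the record-type order, column order the genetic-trait
    order; each genetic trait expands to its male and female record.
    """
    t1 = np.zeros((N_RECORD_TYPES, N_TRAITS))
    for r in range(N_RECORD_TYPES):
        t1[r, rtype_trait(r)] = 1.0
    return t1


def residual_zero_mask() -> np.ndarray:
    """Boolean 8x8 mask, True where the residual covariance must be zero."""
    mask = np.ones((N_RECORD_TYPES, N_RECORD_TYPES), dtype=bool)
    for i, j in RESIDUAL_BLOCKS:
        mask[i, i] = mask[j, j] = mask[i, j] = mask[j, i] = False
    return mask


def _check_spd(mat: np.ndarray, name: str) -> None:
    mat = np.asarray(mat, float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    try:
        np.linalg.cholesky(mat)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} is not positive definite") from exc


@dataclasses.dataclass
class CovarianceSet:
    """Covariance components of the multi-trait model on one scale.

    ``va0`` and ``vc0`` are 4x4 (genetic-trait order), ``ve0`` is 8x8
    (record-type order) with the structural zeros of the residual model.
    """

    va0: np.ndarray
    vc0: np.ndarray
    ve0: np.ndarray
    scale: str = "standardized"

    def __post_init__(self) -> None:
        self.va0 = np.asarray(self.va0, float)
        self.vc0 = np.asarray(self.vc0, float)
        self.ve0 = np.asarray(self.ve0, float)

    def validate(self) -> None:
        _check_spd(self.va0, "Va0")
        _check_spd(self.vc0, "Vc0")
        if self.ve0.shape != (N_RECORD_TYPES, N_RECORD_TYPES):
            raise ValueError("Ve0 must be 8x8")
        bad = (~np.isclose(self.ve0, 0.0)) & residual_zero_mask()
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "Ve0 violates the structural-zero pattern at "
                f"({RECORD_TYPES[i]}, {RECORD_TYPES[j]})"
            )
        for i, j in RESIDUAL_BLOCKS:
            _check_spd(self.ve0[np.ix_((i, j), (i, j))], f"Ve0 block {(i, j)}")

    def copy(self) -> "CovarianceSet":
        return CovarianceSet(self.va0.copy(), self.vc0.copy(), self.ve0.copy(), self.scale)


@dataclasses.dataclass
class RescaledCovariances:
    """Components on the original gram scale (all 8x8, record-type order)."""

    va: np.ndarray
    vc: np.ndarray
    ve: np.ndarray
    scale: str = "original"


@dataclasses.dataclass
class ScalingFactors:
    """Sex-wise phenotypic standard deviations in grams.

    ``sd`` maps (sex, week, env) to the phenotypic SD estimated from the
    univariate animal model; the T2 matrix is its diagonal arrangement in
    record-type order and T1 the genetic-trait expansion.
    """

    sd: Mapping[tuple[str, int, str], float]

    def sd_vector(self) -> np.ndarray:
        out = np.empty(N_RECORD_TYPES)
        for r in range(N_RECORD_TYPES):
            key = (rtype_sex(r), rtype_week(r), rtype_env(r))
            if key not in self.sd:
                raise KeyError(f"missing scaling factor for {key}")
            val = float(self.sd[key])
            if not val > 0:
                raise ValueError(f"scaling factor for {key} must be > 0")
            out[r] = val
        return out

    @property
    def t1(self) -> np.ndarray:
        return expansion_matrix()

    @property
    def t2(self) -> np.ndarray:
        return np.diag(self.sd_vector())


def make_covariances(
    h2: Mapping[str, float],
    c2: float,
    genetic_corr: np.ndarray,
    maternal_corr: np.ndarray,
    residual_week_corr: float = 0.55,
) -> CovarianceSet:
    """Build a standardized-scale CovarianceSet from heritabilities.

    On the standardized scale the phenotypic variance of every record type
    is ~1, so the genetic variance of a trait equals its heritability and
    the residual variance is the remainder 1 - h2 - c2.
    """
    va_diag = np.array([h2[t] for t in GENETIC_TRAITS])
    va0 = np.sqrt(np.outer(va_diag, va_diag)) * np.asarray(genetic_corr, float)
    vc_diag = np.full(N_TRAITS, c2)
    vc0 = np.sqrt(np.outer(vc_diag, vc_diag)) * np.asarray(maternal_corr, float)
    ve0 = np.zeros((N_RECORD_TYPES, N_RECORD_TYPES))
    for r in range(N_RECORD_TYPES):
        t = rtype_trait(r)
        ve0[r, r] = 1.0 - va_diag[t] - c2
    for i, j in RESIDUAL_BLOCKS:
        cov = residual_week_corr * np.sqrt(ve0[i, i] * ve0[j, j])
        ve0[i, j] = ve0[j, i] = cov
    out = CovarianceSet(va0, vc0, ve0, scale="standardized")
    out.validate()
    return out


#: Genetic correlations among (BW5.B, BW6.B, BW5.C, BW6.C), chosen inside the
#: range reported for broiler body weight across B and C environments: high
#: within-environment week-to-week correlations and ~0.5 across environments.
DEFAULT_GENETIC_CORR = np.array(
    [
        [1.00, 0.96, 0.50, 0.49],
        [0.96, 1.00, 0.50, 0.48],
        [0.50, 0.50, 1.00, 0.98],
        [0.49, 0.48, 0.98, 1.00],
    ]
)

#: Maternal permanent-environment correlations (same trait order).
DEFAULT_MATERNAL_CORR = np.array(
    [
        [1.00, 0.95, 0.69, 0.72],
        [0.95, 1.00, 0.59, 0.63],
        [0.69, 0.59, 1.00, 0.97],
        [0.72, 0.63, 0.97, 1.00],
    ]
)

#: Phenotypic SD (g) per (sex, week, env); typical magnitudes for broiler
#: body weight at 5-6 weeks in bio-secure vs commercial conditions.
DEFAULT_SEX_SD = {
    ("M", 5, "B"): 213.0,
    ("F", 5, "B"): 180.0,
    ("M", 6, "B"): 269.0,
    ("F", 6, "B"): 217.0,
    ("M", 5, "C"): 302.0,
    ("F", 5, "C"): 248.0,
    ("M", 6, "C"): 364.0,
    ("F", 6, "C"): 290.0,
}

#: Mean body weight (g) per (sex, week, env) used as simulation baselines.
DEFAULT_MEAN_G = {
    ("M", 5, "B"): 2183.0,
    ("F", 5, "B"): 1882.0,
    ("M", 6, "B"): 2758.0,
    ("F", 6, "B"): 2329.0,
    ("M", 5, "C"): 1735.0,
    ("F", 5, "C"): 1550.0,
    ("M", 6, "C"): 2231.0,
    ("F", 6, "C"): 1940.0,
}


@dataclasses.dataclass
class TrueParams:
    """Ground-truth simulation parameters (standardized scale).

    ``fixed_effect_sizes`` gives the SDs of the random draws of the fixed
    factor level effects (hatch time-step, sire/dam time-step, dam age) on
    the standardized scale.
    """

    va0: np.ndarray
    vc0: np.ndarray
    ve0: np.ndarray
    sex_sd: Mapping[tuple[str, int, str], float]
    mean_g: Mapping[tuple[str, int, str], float]
    fixed_effect_sizes: Mapping[str, float]

    def validate(self) -> None:
        CovarianceSet(self.va0, self.vc0, self.ve0).validate()
        for key, val in self.sex_sd.items():
            if not val > 0:
                raise ValueError(f"sex_sd for {key} must be > 0")

    def covariances(self) -> CovarianceSet:
        return CovarianceSet(self.va0.copy(), self.vc0.copy(), self.ve0.copy())


def default_true_params(
    h2_b: float = 0.30,
    h2_c: float = 0.35,
    c2: float = 0.035,
    rg_bc: float | None = None,
) -> TrueParams:
    """Default ground truth for the synthetic breeding program.

    Heritabilities 0.30 (B) / 0.35 (C), maternal ratio 0.035 and a genetic
    correlation of ~0.5 between environments.
    """
    gcorr = DEFAULT_GENETIC_CORR.copy()
    if rg_bc is not None:
        for i in (0, 1):
            for j in (2, 3):
                gcorr[i, j] = gcorr[j, i] = rg_bc
    h2 = {
        "BW5.B": h2_b,
        "BW6.B": h2_b,
        "BW5.C": h2_c,
        "BW6.C": h2_c,
    }
    cov = make_covariances(h2, c2, gcorr, DEFAULT_MATERNAL_CORR)
    return TrueParams(
        va0=cov.va0,
        vc0=cov.vc0,
        ve0=cov.ve0,
        sex_sd=dict(DEFAULT_SEX_SD),
        mean_g=dict(DEFAULT_MEAN_G),
        fixed_effect_sizes={"hatch_ts": 0.25, "parent_ts": 0.10, "dam_age": 0.05},
    )
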