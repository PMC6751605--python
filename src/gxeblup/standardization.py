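"""Sex-wise standardization of body-weight records and back-rescaling.

Male and female body weight differ mainly by a scaling factor, so each
record is divided by the phenotypic standard deviation of its (sex, week,
environment) cell.  The SD is the total variance of the univariate animal
model for that cell (additive + maternal permanent environment +
residual), estimated by REML.  Covariance components estimated on the
standardized scale are returned to grams through the congruence transform
V = T2 (T1 V0 T1') T2' with T1 the genetic-trait expansion and T2 the
diagonal of cell SDs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse

from . import params as P
from .mixed_model import model1_spec
from .params import CovarianceSet, RescaledCovariances, ScalingFactors
from .pedigree import Pedigree
from .reml import REMLResult, reml_estimate


def apply_outlier_filter(records: pd.DataFrame, n_sd: float = 4.0) -> pd.DataFrame:
    """Drop records more than ``n_sd`` raw standard deviations from their
    (trait, sex, environment) cell mean (single pass, grams)."""
    grp = records.groupby(["trait", "sex", "env"])["value_g"]
    z = (records["value_g"] - grp.transform("mean")) / grp.transform("std")
    return records.loc[z.abs().fillna(0.0) <= n_sd].copy()


def estimate_phenotypic_sd(
    records: pd.DataFrame,
    sex: str,
    week: int,
    env: str,
    pedigree: Pedigree,
    tol: float = 1e-6,
    max_iter: int = 200,
    a_inv: sparse.spmatrix | None = None,
    return_result: bool = False,
):
    """Phenotypic SD (g) of one cell from the univariate animal model.

    Fits fixed hatch/parental time-step and dam-age factors, a pedigree
    additive effect and a dam permanent-environment effect, and returns
    sqrt(sigma_a^2 + sigma_c^2 + sigma_e^2).
    """
    spec = model1_spec(sex, week, env, value_column="value_g")
    mask = (
        (records["sex"] == sex)
        & (records["trait"] == f"BW{week}")
        & (records["env"] == env)
    )
    cell = records.loc[mask]
    if len(cell) == 0:
        raise ValueError(f"no records for cell ({sex}, BW{week}, {env})")
    if np.isclose(cell["value_g"].std(ddof=1), 0.0):
        raise ValueError(
            f"degenerate cell ({sex}, BW{week}, {env}): all records equal"
        )
    result = reml_estimate(
        cell, spec, pedigree, tol=tol, max_iter=max_iter, a_inv=a_inv
    )
    sd = float(np.sqrt(result.va0[0, 0] + result.vc0[0, 0] + result.ve0[0, 0]))
    if return_result:
        return sd, result
    return sd


def estimate_scaling_factors(
    records: pd.DataFrame,
    pedigree: Pedigree,
    tol: float = 1e-6,
    max_iter: int = 200,
    method: str = "model",
) -> ScalingFactors:
    """Scaling factors for all eight (sex, week, environment) cells.

    ``method='model'`` runs the univariate REML model per cell (the
    analysis default); ``method='sample'`` uses the raw cell SD, an
    inexpensive option for simulation studies.
    """
    sd: dict[tuple[str, int, str], float] = {}
    a_inv = None
    if method == "model":
        from .relationships import build_A_inverse

        a_inv = build_A_inverse(pedigree)
    for r in range(P.N_RECORD_TYPES):
        key = (P.rtype_sex(r), P.rtype_week(r), P.rtype_env(r))
        if method == "sample":
            sex, week, env = key
            cell = records.loc[
                (records["sex"] == sex)
                & (records["trait"] == f"BW{week}")
                & (records["env"] == env),
                "value_g",
            ]
            if len(cell) < 2:
                raise ValueError(f"no records for cell {key}")
            sd[key] = float(cell.std(ddof=1))
        else:
            sd[key] = estimate_phenotypic_sd(
                records, *key, pedigree, tol=tol, max_iter=max_iter, a_inv=a_inv
            )
    return ScalingFactors(sd=sd)


def standardize_records(
    records: pd.DataFrame, factors: ScalingFactors
) -> pd.DataFrame:
    """Divide every record by its cell SD; grams are kept alongside."""
    week = records["trait"].str.slice(2).astype(int)
    keys = list(zip(records["sex"], week, records["env"]))
    try:
        sd = np.array([factors.sd[key] for key in keys], float)
    except KeyError as exc:
        raise KeyError(f"no scaling factor for cell {exc.args[0]}") from exc
    if np.any(sd <= 0):
        raise ValueError("scaling factors must be positive")
    out = records.copy()
    out["value_std"] = out["value_g"].to_numpy(float) / sd
    return out


def rescale_covariances(
    std: CovarianceSet, factors: ScalingFactors
) -> RescaledCovariances:
    """Return components to the gram scale: V = T2 (T1 V0 T1') T2'.

    The residual, already sex-specific, is transformed by T2 alone.  The
    same congruence transform applies to an asymptotic covariance matrix
    of estimates via :func:`rescale_estimate_covariance`.
    """
    if std.scale != "standardized":
        raise ValueError("input components must be on the standardized scale")
    t1 = factors.t1
    t2 = factors.t2
    va0 = np.asarray(std.va0, float)
    vc0 = np.asarray(std.vc0, float)
    ve0 = np.asarray(std.ve0, float)
    if va0.shape != (P.N_TRAITS, P.N_TRAITS) or ve0.shape != t2.shape:
        raise ValueError("component dimensions do not match the trait layout")
    va = t2 @ (t1 @ va0 @ t1.T) @ t2.T
    vc = t2 @ (t1 @ vc0 @ t1.T) @ t2.T
    ve = t2 @ ve0 @ t2.T
    return RescaledCovariances(va=va, vc=vc, ve=ve, scale="original")


def rescale_estimate_covariance(
    cov_vech: np.ndarray, factors: ScalingFactors, which: str = "va"
) -> np.ndarray:
    """Congruence-transform an asymptotic covariance of estimates.

    ``cov_vech`` is the covariance of the vech of Va0/Vc0 (10 parameters)
    or of the free Ve0 elements; returns the covariance of the vech of the
    rescaled 8x8 matrix via the (linear) transform's Jacobian.
    """
    t2d = factors.sd_vector()
    if which in ("va", "vc"):
        k = P.N_TRAITS
        pairs_in = [(i, j) for i in range(k) for j in range(i, k)]
        m = P.N_RECORD_TYPES
        pairs_out = [(i, j) for i in range(m) for j in range(i, m)]
        J = np.zeros((len(pairs_out), len(pairs_in)))
        for row, (i, j) in enumerate(pairs_out):
            ti, tj = P.rtype_trait(i), P.rtype_trait(j)
            a, b = min(ti, tj), max(ti, tj)
            J[row, pairs_in.index((a, b))] = t2d[i] * t2d[j]
    elif which == "ve":
        m = P.N_RECORD_TYPES
        pairs = [(i, j) for i in range(m) for j in range(i, m)]
        J = np.diag([t2d[i] * t2d[j] for i, j in pairs])
    else:
        raise ValueError("which must be va, vc or ve")
    return J @ np.asarray(cov_vech, float) @ J.T


def _corr(mat: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(mat))
    return mat / np.outer(d, d)


def derive_genetic_parameters(
    cov: CovarianceSet, factors: ScalingFactors | None = None
) -> dict[str, pd.DataFrame]:
    """Heritabilities, maternal ratios and correlation matrices.

    Variance ratios use the per-record-type phenotypic variance sigma_a^2 +
    sigma_c^2 + sigma_e^2; ratios are scale invariant, while sigma_a^2 is
    reported in g^2 when scaling factors are supplied.
    """
    if factors is not None:
        resc = rescale_covariances(cov, factors)
        va_d = np.diag(resc.va)
        vc_d = np.diag(resc.vc)
        ve_d = np.diag(resc.ve)
    else:
        t1 = P.expansion_matrix()
        va_d = np.diag(t1 @ cov.va0 @ t1.T)
        vc_d = np.diag(t1 @ cov.vc0 @ t1.T)
        ve_d = np.diag(cov.ve0)
    phen = va_d + vc_d + ve_d
    if np.any(phen <= 0):
        raise ValueError("non-positive phenotypic variance")
    rows = []
    for r in range(P.N_RECORD_TYPES):
        rows.append(
            {
                "sex": P.rtype_sex(r),
                "week": P.rtype_week(r),
                "env": P.rtype_env(r),
                "sigma_a2": va_d[r],
                "h2": va_d[r] / phen[r],
                "c2": vc_d[r] / phen[r],
                "sigma_p2": phen[r],
            }
        )
    labels = list(P.GENETIC_TRAITS)
    return {
        "parameters": pd.DataFrame(rows),
        "genetic_correlations": pd.DataFrame(
            _corr(cov.va0), index=labels, columns=labels
        ),
        "maternal_correlations": pd.DataFrame(
            _corr(cov.vc0), index=labels, columns=labels
        ),
    }
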