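"""Full/reduced cross-validation with the Legarra-Reverter statistics.

EBV are predicted twice, from the full dataset and from a reduced dataset
truncated at a cutoff time-step; for the validation animals (B-environment
birds hatched after the cutoff) three statistics compare the two sets of
EBV: the correlation rho_f,r (indicator of population accuracy), the
regression slope b_f,r of EBV_f on EBV_r (dispersion; expectation 1) and
the mean difference d_f,r (bias; expectation 0).  Under nested information
the expectation of rho_f,r is acc_r / acc_f, the ratio of population
accuracies.  Standard errors come from a nonparametric bootstrap over
validation animals.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .mixed_model import EBVTable
from .pedigree import Pedigree

logger = logging.getLogger(__name__)


def split_full_reduced(
    records: pd.DataFrame, cutoff_ts: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(full, reduced) phenotype tables; reduced keeps hatch TS <= cutoff."""
    ts = records["hatch_ts"]
    if not (ts.min() <= cutoff_ts <= ts.max()):
        raise ValueError(
            f"cutoff {cutoff_ts} outside observed time-steps "
            f"[{ts.min()}, {ts.max()}]"
        )
    reduced = records.loc[ts <= cutoff_ts].copy()
    if len(reduced) == 0:
        raise ValueError("reduced dataset is empty")
    removed = records.loc[ts > cutoff_ts]
    counts = removed.groupby("env")["animal"].nunique().to_dict()
    logger.info(
        "reduced dataset: removed %d records of %s animals per environment",
        len(removed),
        counts,
    )
    return records.copy(), reduced


def validation_animals(pedigree: Pedigree, cutoff_ts: int) -> np.ndarray:
    """Identifiers of B-environment animals hatched after the cutoff."""
    if pedigree.environment is None:
        raise ValueError("pedigree has no environment assignment")
    mask = (pedigree.environment == "B") & (pedigree.time_step > cutoff_ts)
    return pedigree.ids[mask]


@dataclasses.dataclass
class LRStatistics:
    rho: float
    b: float
    d: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.rho, self.b, self.d)


def lr_statistics(ebv_f: np.ndarray, ebv_r: np.ndarray) -> LRStatistics:
    """(rho_f,r, b_f,r, d_f,r) for paired EBV vectors."""
    ebv_f = np.asarray(ebv_f, float)
    ebv_r = np.asarray(ebv_r, float)
    if ebv_f.shape != ebv_r.shape or ebv_f.ndim != 1:
        raise ValueError("EBV vectors must be 1-D and of equal length")
    if len(ebv_f) < 3:
        raise ValueError("need at least 3 paired EBV")
    var_r = np.var(ebv_r, ddof=1)
    var_f = np.var(ebv_f, ddof=1)
    if var_r <= 0 or var_f <= 0:
        raise ValueError("zero variance in an EBV vector")
    cov = np.cov(ebv_f, ebv_r, ddof=1)[0, 1]
    return LRStatistics(
        rho=float(cov / np.sqrt(var_f * var_r)),
        b=float(cov / var_r),
        d=float(np.mean(ebv_f) - np.mean(ebv_r)),
    )


def lr_bootstrap_se(
    ebv_f: np.ndarray,
    ebv_r: np.ndarray,
    n_boot: int = 1000,
    rng_seed: int = 0,
) -> LRStatistics:
    """Bootstrap standard errors of (rho, b, d) over validation animals."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    ebv_f = np.asarray(ebv_f, float)
    ebv_r = np.asarray(ebv_r, float)
    n = len(ebv_f)
    rng = np.random.default_rng(rng_seed)
    stats = np.empty((n_boot, 3))
    degenerate = 0
    for bidx in range(n_boot):
        take = rng.integers(0, n, n)
        f, r = ebv_f[take], ebv_r[take]
        if np.var(r, ddof=1) <= 0 or np.var(f, ddof=1) <= 0:
            degenerate += 1
            stats[bidx] = np.nan
            continue
        stats[bidx] = lr_statistics(f, r).as_tuple()
    if degenerate > 0.01 * n_boot:
        raise ValueError(
            f"{degenerate}/{n_boot} bootstrap resamples degenerate"
        )
    se = np.nanstd(stats, axis=0, ddof=1)
    return LRStatistics(rho=float(se[0]), b=float(se[1]), d=float(se[2]))


def expectation_check(
    ebv_f: np.ndarray, ebv_r: np.ndarray, true_bv: np.ndarray
) -> dict[str, float | bool]:
    """Compare the realized LR statistics with their expectations.

    Only meaningful in simulation, where true breeding values exist:
    acc_r / acc_f is the expected rho_f,r; b and d are expected at 1 and 0.
    """
    stats = lr_statistics(ebv_f, ebv_r)
    true_bv = np.asarray(true_bv, float)
    acc_r = float(np.corrcoef(true_bv, ebv_r)[0, 1])
    acc_f = float(np.corrcoef(true_bv, ebv_f)[0, 1])
    unstable = abs(acc_f) < 0.05
    expected_rho = acc_r / acc_f if not unstable else float("nan")
    return {
        "rho": stats.rho,
        "b": stats.b,
        "d": stats.d,
        "acc_r": acc_r,
        "acc_f": acc_f,
        "expected_rho": expected_rho,
        "rho_gap": stats.rho - expected_rho if not unstable else float("nan"),
        "b_deviation": stats.b - 1.0,
        "d_deviation": stats.d,
        "ratio_unstable": unstable,
    }


def relative_increase(rho_from: float, rho_to: float) -> float:
    """Relative increase in rho_f,r between two models, in percent."""
    if rho_from == 0:
        raise ValueError("reference rho is zero")
    return 100.0 * (rho_to - rho_from) / rho_from


def lr_report(
    ebv_tables: dict[tuple[str, str], EBVTable],
    groups: dict[str, np.ndarray],
    n_boot: int = 1000,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """LR statistics per (model, trait, validation group) with bootstrap SEs.

    ``ebv_tables`` maps (model, dataset) -> EBVTable for dataset in
    {'full', 'reduced'}; ``groups`` maps group names (genotyped /
    non-genotyped) to animal identifiers.  Animals missing from either EBV
    table are dropped with a logged count.
    """
    models = sorted({m for m, _ in ebv_tables})
    rows = []
    for model in models:
        tab_f = ebv_tables[(model, "full")]
        tab_r = ebv_tables[(model, "reduced")]
        common = np.intersect1d(tab_f.ids, tab_r.ids)
        for gname, ids in groups.items():
            ids = np.asarray(ids, np.int64)
            kept = np.intersect1d(ids, common)
            if len(kept) < len(ids):
                logger.info(
                    "group %s: dropped %d animals missing from EBV tables",
                    gname,
                    len(ids) - len(kept),
                )
            if len(kept) < 3:
                continue
            vf = tab_f.for_animals(kept)
            vr = tab_r.for_animals(kept)
            for t, trait in enumerate(tab_f.traits):
                stats = lr_statistics(vf[:, t], vr[:, t])
                se = lr_bootstrap_se(
                    vf[:, t], vr[:, t], n_boot=n_boot, rng_seed=rng_seed
                )
                rows.append(
                    {
                        "model": model,
                        "trait": trait,
                        "group": gname,
                        "n": len(kept),
                        "rho": stats.rho,
                        "b": stats.b,
                        "d": stats.d,
                        "se_rho": se.rho,
                        "se_b": se.b,
                        "se_d": se.d,
                    }
                )
    return pd.DataFrame(rows)
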