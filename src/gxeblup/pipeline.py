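"""End-to-end genomic-evaluation pipeline.

Order of stages: simulate (or load) -> outlier filter -> descriptive
statistics -> sex-wise scaling -> standardization -> REML variance
components (pedigree kernel, full data) -> EBV prediction for
{PBLUP, ssGBLUP} x {full, reduced} reusing the one set of components ->
Legarra-Reverter cross-validation for genotyped and non-genotyped
B-environment validation birds -> parameter and report tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import params as P
from .lr_validation import (
    lr_report,
    relative_increase,
    split_full_reduced,
    validation_animals,
)
from .mixed_model import EBVTable, model2_spec, predict_ebv
from .params import CovarianceSet, ScalingFactors, TrueParams, default_true_params
from .pedigree import Pedigree
from .relationships import build_A_inverse, make_h_inverse_parts, qc_genotypes
from .reml import REMLResult, default_starts, reml_estimate
from .standardization import (
    apply_outlier_filter,
    derive_genetic_parameters,
    estimate_scaling_factors,
    standardize_records,
)
from .synthetic_data import SimConfig, SimulatedDataset, simulate_dataset

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Everything a pipeline run depends on; the seed feeds every stage."""

    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    truth: TrueParams | None = None
    omega: float = 0.01
    snp_missing_max: float = 0.05
    animal_callrate_min: float = 0.95
    maf_min: float = 0.01
    pcg_tol: float = 1e-8
    pcg_max_iter: int = 5000
    reml_tol: float = 1e-5
    reml_max_iter: int = 200
    n_reml_starts: int = 3
    cutoff_ts: int | None = None
    n_boot: int = 1000
    seed: int = 0
    outdir: str | None = None
    variance_components: str = "reml"  # "reml" | "true"
    scaling: str = "model"  # "model" | "sample"
    outlier_sd: float = 4.0
    use_genomics: bool = True

    def resolved_cutoff(self) -> int:
        if self.cutoff_ts is not None:
            return self.cutoff_ts
        return int(np.floor(self.sim.n_time_steps * 12 / 16))

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        truth = out.pop("truth")
        if truth is not None:
            out["truth"] = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in truth.items()
            }
        sim = out["sim"]
        if sim.get("missingness_plan"):
            sim["missingness_plan"] = {
                str(ts): {e: {str(w): f for w, f in cell.items()}
                          for e, cell in entry.items()}
                for ts, entry in sim["missingness_plan"].items()
            }
        return out

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclasses.dataclass
class RunReport:
    config_hash: str
    seed: int
    descriptive: pd.DataFrame
    scaling: ScalingFactors
    covariances: CovarianceSet
    reml: REMLResult | None
    parameters: dict[str, pd.DataFrame]
    variance_ratios: pd.DataFrame
    lr: pd.DataFrame
    rho_increase: pd.DataFrame
    ebv: dict[tuple[str, str], EBVTable]
    dataset: SimulatedDataset

    def summary(self) -> dict[str, Any]:
        par = self.parameters["parameters"]
        rg = self.parameters["genetic_correlations"]
        out: dict[str, Any] = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "n_animals": int(self.dataset.pedigree.n),
            "n_records": int(len(self.dataset.phenotypes)),
            "n_genotyped": int(self.dataset.genotyped.sum()),
            "h2": {
                f"{r.sex}_BW{r.week}_{r.env}": round(float(r.h2), 6)
                for r in par.itertuples()
            },
            "c2": {
                f"{r.sex}_BW{r.week}_{r.env}": round(float(r.c2), 6)
                for r in par.itertuples()
            },
            "genetic_correlations": {
                f"{a}|{b}": round(float(rg.loc[a, b]), 6)
                for i, a in enumerate(rg.index)
                for b in rg.columns[i + 1 :]
            },
            "lr": [
                {k: (round(v, 6) if isinstance(v, float) else v)
                 for k, v in row.items()}
                for row in self.lr.to_dict("records")
            ],
            "rho_relative_increase_pct": [
                {k: (round(v, 6) if isinstance(v, float) else v)
                 for k, v in row.items()}
                for row in self.rho_increase.to_dict("records")
            ],
        }
        return out

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.descriptive.to_csv(outdir / "descriptive_stats.csv", index=False)
        self.parameters["parameters"].to_csv(
            outdir / "genetic_parameters.csv", index=False
        )
        self.parameters["genetic_correlations"].to_csv(
            outdir / "genetic_correlations.csv"
        )
        self.parameters["maternal_correlations"].to_csv(
            outdir / "maternal_correlations.csv"
        )
        self.variance_ratios.to_csv(outdir / "variance_ratios.csv", index=False)
        self.lr.to_csv(outdir / "lr_validation.csv", index=False)
        self.rho_increase.to_csv(outdir / "rho_increase.csv", index=False)
        for (model, dataset), tab in self.ebv.items():
            tab.to_frame().to_csv(
                outdir / f"ebv_{model.lower()}_{dataset}.csv", index=False
            )
        from .io import write_scaling

        write_scaling(self.scaling, outdir / "scaling_factors.csv")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)


def descriptive_stats(records: pd.DataFrame) -> pd.DataFrame:
    """Record counts, means, SDs and CV per (week, sex, environment)."""
    if len(records) == 0:
        raise ValueError("no records")
    df = records.copy()
    df["week"] = df["trait"].str.slice(2).astype(int)
    rows = []
    for (week, sex, env), cell in df.groupby(["week", "sex", "env"]):
        vals = cell["value_g"].to_numpy(float)
        if len(vals) == 0:
            raise ValueError(f"empty cell ({week}, {sex}, {env})")
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append(
            {
                "week": week,
                "sex": sex,
                "env": env,
                "n": len(vals),
                "mean_g": round(mean),
                "sd_g": round(sd),
                "cv": coefficient_of_variation(mean, sd),
            }
        )
    return pd.DataFrame(rows)


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV = SD / mean, rounded to 3 decimals as printed in report tables."""
    if mean == 0:
        raise ValueError("zero mean")
    return round(sd / mean, 3)


def variance_ratio(var_c: float, var_b: float) -> float:
    """sigma_a^2(C) / sigma_a^2(B), rounded to 2 decimals."""
    if var_b == 0:
        raise ValueError("zero denominator variance")
    return round(var_c / var_b, 2)


def variance_ratio_table(parameters: pd.DataFrame) -> pd.DataFrame:
    """Relative C/B differences in additive genetic variance per sex-week."""
    rows = []
    for (sex, week), cell in parameters.groupby(["sex", "week"]):
        by_env = cell.set_index("env")["sigma_a2"]
        rows.append(
            {
                "sex": sex,
                "week": week,
                "ratio_C_over_B": variance_ratio(
                    float(by_env["C"]), float(by_env["B"])
                ),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis; every stage seeded from ``config.seed``."""
    truth = config.truth if config.truth is not None else default_true_params()
    logger.info("simulating breeding program (seed %d)", config.seed)
    dataset = simulate_dataset(config.sim, truth, config.seed)
    ped = dataset.pedigree

    records = apply_outlier_filter(dataset.phenotypes, n_sd=config.outlier_sd)
    descriptive = descriptive_stats(records)

    logger.info("estimating scaling factors (%s)", config.scaling)
    factors = estimate_scaling_factors(records, ped, method=config.scaling)
    std_records = standardize_records(records, factors)

    a_inv = build_A_inverse(ped)
    spec = model2_spec()

    reml_result: REMLResult | None = None
    if config.variance_components == "true":
        cov = truth.covariances()
    else:
        logger.info("REML variance components (PBLUP, full data)")
        from .mixed_model import build_design

        design = build_design(std_records, spec, ped)
        starts = default_starts(design, n_starts=config.n_reml_starts)
        reml_result = reml_estimate(
            std_records,
            spec,
            ped,
            starts=starts,
            tol=config.reml_tol,
            max_iter=config.reml_max_iter,
            a_inv=a_inv,
        )
        cov = reml_result.covariance_set()

    kernels: dict[str, Any] = {"PBLUP": a_inv}
    if config.use_genomics and dataset.genotyped.any():
        logger.info("building single-step kernel (omega=%g)", config.omega)
        geno = dataset.genotypes.subset_animals(ped.ids[dataset.genotyped])
        geno = qc_genotypes(
            geno,
            snp_missing_max=config.snp_missing_max,
            animal_callrate_min=config.animal_callrate_min,
            maf_min=config.maf_min,
        )
        kernels["ssGBLUP"] = make_h_inverse_parts(
            ped, geno, omega=config.omega, a_inv=a_inv
        )

    cutoff = config.resolved_cutoff()
    full, reduced = split_full_reduced(std_records, cutoff)
    ebv: dict[tuple[str, str], EBVTable] = {}
    for model, kernel in kernels.items():
        for dname, recs in (("full", full), ("reduced", reduced)):
            logger.info("predicting EBV: %s / %s", model, dname)
            ebv[(model, dname)] = predict_ebv(
                recs,
                spec,
                ped,
                kernel,
                va0=cov.va0,
                ve0=cov.ve0,
                vc0=cov.vc0,
                method="pcg",
                tol=config.pcg_tol,
                max_iter=config.pcg_max_iter,
                model=model,
                dataset=dname,
            )

    val_ids = validation_animals(ped, cutoff)
    flags = pd.Series(dataset.genotyped, index=ped.ids)
    groups = {
        "genotyped": val_ids[flags.loc[val_ids].to_numpy()],
        "non_genotyped": val_ids[~flags.loc[val_ids].to_numpy()],
    }
    lr = lr_report(ebv, groups, n_boot=config.n_boot, rng_seed=config.seed + 1)

    rows = []
    if {"PBLUP", "ssGBLUP"} <= set(kernels):
        for (trait, gname), cell in lr.groupby(["trait", "group"]):
            by_model = cell.set_index("model")["rho"]
            if {"PBLUP", "ssGBLUP"} <= set(by_model.index):
                rows.append(
                    {
                        "trait": trait,
                        "group": gname,
                        "rho_pblup": float(by_model["PBLUP"]),
                        "rho_ssgblup": float(by_model["ssGBLUP"]),
                        "increase_pct": round(
                            relative_increase(
                                float(by_model["PBLUP"]), float(by_model["ssGBLUP"])
                            ),
                            1,
                        ),
                    }
                )
    rho_increase = pd.DataFrame(rows)

    parameters = derive_genetic_parameters(cov, factors)
    ratios = variance_ratio_table(parameters["parameters"])

    report = RunReport(
        config_hash=config.config_hash(),
        seed=config.seed,
        descriptive=descriptive,
        scaling=factors,
        covariances=cov,
        reml=reml_result,
        parameters=parameters,
        variance_ratios=ratios,
        lr=lr,
        rho_increase=rho_increase,
        ebv=ebv,
        dataset=dataset,
    )
    if config.outdir:
        report.write(config.outdir)
    return report


def config_from_yaml(path) -> RunConfig:
    """Load a RunConfig from a YAML file (nested ``sim`` section optional)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = SimConfig(**raw.pop("sim", {}))
    truth_raw = raw.pop("truth", None)
    truth = None
    if truth_raw is not None:
        truth = default_true_params(**truth_raw)
    # YAML parses a bare `true` as a boolean; the option means "reuse the
    # simulation truth as variance components"
    if isinstance(raw.get("variance_components"), bool):
        raw["variance_components"] = (
            "true" if raw["variance_components"] else "reml"
        )
    return RunConfig(sim=sim, truth=truth, **raw)
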