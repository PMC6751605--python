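"""Readers and writers for the package's plain-text formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .params import ScalingFactors
from .pedigree import Pedigree
from .relationships import GenotypeMatrix
from .synthetic_data import SimulatedDataset

PHENO_COLUMNS = [
    "animal", "trait", "env", "sex", "value_g",
    "hatch_ts", "sire_ts", "dam_ts", "dam_id", "dam_age_wk",
]


def write_phenotypes(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file lacks columns: {missing}")
    return df


def write_genotypes_raw(
    geno: GenotypeMatrix, path, pedigree: Pedigree | None = None
) -> None:
    """PLINK-RAW-compatible dosage file (FID IID PAT MAT SEX PHENOTYPE SNP...)."""
    sex_code = {"M": 1, "F": 2}
    lookup = {}
    if pedigree is not None:
        for i, lab in enumerate(pedigree.ids):
            lookup[int(lab)] = i
    with open(path, "w") as fh:
        fh.write("FID IID PAT MAT SEX PHENOTYPE " + " ".join(geno.snp_ids) + "\n")
        for row, animal in enumerate(geno.ids):
            pat = mat = 0
            sx = 0
            if pedigree is not None and int(animal) in lookup:
                i = lookup[int(animal)]
                pat = int(pedigree.ids[pedigree.sire[i]]) if pedigree.sire[i] >= 0 else 0
                mat = int(pedigree.ids[pedigree.dam[i]]) if pedigree.dam[i] >= 0 else 0
                sx = sex_code.get(str(pedigree.sex[i]), 0)
            dosages = " ".join(
                "NA" if np.isnan(d) else str(int(d)) for d in geno.dosages[row]
            )
            fh.write(f"{animal} {animal} {pat} {mat} {sx} -9 {dosages}\n")


def read_genotypes_raw(path) -> GenotypeMatrix:
    """Read the PLINK-RAW dialect, or a plain whitespace matrix with an
    ``IID`` first column."""
    with open(path) as fh:
        header = fh.readline().split()
    if header[:6] == ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]:
        snp_ids = header[6:]
        df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
        ids = df["IID"].to_numpy(np.int64)
        M = df[snp_ids].to_numpy(float)
    else:
        df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
        ids = df.iloc[:, 0].to_numpy(np.int64)
        snp_ids = list(df.columns[1:])
        M = df.iloc[:, 1:].to_numpy(float)
    return GenotypeMatrix(ids, np.array(snp_ids), M)


def write_scaling(factors: ScalingFactors, path) -> None:
    rows = [
        {"sex": sex, "trait": f"BW{week}", "env": env, "sd_g": sd}
        for (sex, week, env), sd in factors.sd.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_scaling(path) -> ScalingFactors:
    df = pd.read_csv(path)
    sd = {
        (r.sex, int(str(r.trait)[2]), r.env): float(r.sd_g)
        for r in df.itertuples()
    }
    return ScalingFactors(sd=sd)


def write_dataset(dataset: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write a simulated dataset as pedigree/phenotype/genotype/BV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.csv",
        "phenotypes": outdir / "phenotypes.csv",
        "genotypes": outdir / "genotypes.raw",
        "true_bv": outdir / "true_bv.csv",
        "genotyped": outdir / "genotyped_animals.csv",
    }
    dataset.pedigree.write_csv(paths["pedigree"])
    write_phenotypes(dataset.phenotypes, paths["phenotypes"])
    geno = dataset.genotypes.subset_animals(dataset.pedigree.ids[dataset.genotyped])
    write_genotypes_raw(geno, paths["genotypes"], pedigree=dataset.pedigree)
    dataset.true_bv_frame().to_csv(paths["true_bv"], index=False)
    pd.DataFrame({"animal": dataset.pedigree.ids[dataset.genotyped]}).to_csv(
        paths["genotyped"], index=False
    )
    return paths
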