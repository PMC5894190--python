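"""Readers and writers for the plain-text interchange formats.

Genotypes travel as a delimited individual x marker dosage table
(missing coded NA) or as minimal unphased VCF (GT only); phenotypes,
weather and family maps as CSV; kernels as square delimited matrices
with an id header; run configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix, KernelSet
from .simulate import SimulationTruth

__all__ = [
    "read_dosage_csv", "write_dosage_csv",
    "read_vcf", "write_vcf",
    "read_kernels", "write_kernels",
    "read_phenotypes", "write_phenotypes",
    "read_family_map", "write_family_map",
    "read_config", "write_config",
    "write_truth", "read_truth",
]

_GT_TO_DOSAGE = {(0, 0): -1.0, (0, 1): 0.0, (1, 0): 0.0, (1, 1): 1.0}


def write_dosage_csv(M: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(M.dosage, index=M.ids, columns=M.markers)
    df.index.name = "individual"
    df.to_csv(path, na_rep="NA", float_format="%g")


def read_dosage_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0, na_values=["NA"])
    return GenotypeMatrix(
        ids=df.index.to_numpy(dtype=object),
        markers=df.columns.to_numpy(dtype=object),
        dosage=df.to_numpy(dtype=float),
    )


def write_vcf(M: GenotypeMatrix, path) -> None:
    """Minimal VCF: biallelic sites, unphased diploid GT only.

    Dosage -1/0/1 maps to 0/0, 0/1, 1/1; missing to ./..  Marker
    coordinates are synthetic (one chromosome, consecutive positions).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(i) for i in M.ids) + "\n")
        code = {-1.0: "0/0", 0.0: "0/1", 1.0: "1/1"}
        for j, marker in enumerate(M.markers):
            calls = [
                "./." if np.isnan(d) else code[d] for d in M.dosage[:, j]
            ]
            fh.write(f"1\t{j + 1}\t{marker}\tA\tB\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic GT calls into dosage coding via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = np.array(vcf.samples, dtype=object)
    markers, rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        markers.append(var.ID or f"{var.CHROM}:{var.POS}")
        col = np.empty(len(ids))
        for k, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            col[k] = np.nan if a < 0 or b < 0 else _GT_TO_DOSAGE[(min(a, 1), min(b, 1))]
        rows.append(col)
    return GenotypeMatrix(
        ids=ids,
        markers=np.array(markers, dtype=object),
        dosage=np.column_stack(rows) if rows else np.empty((len(ids), 0)),
    )


def write_kernels(kernels: KernelSet, directory) -> dict:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("Ga", "D", "Gaa"):
        df = pd.DataFrame(getattr(kernels, name), index=kernels.ids, columns=kernels.ids)
        p = directory / f"{name}.csv"
        df.to_csv(p)
        paths[name] = p
    meta = {"bending_applied": kernels.bending_applied, "epsilon": kernels.epsilon}
    (directory / "kernels_meta.json").write_text(json.dumps(meta, indent=1))
    return paths


def read_kernels(directory) -> KernelSet:
    directory = Path(directory)
    mats, ids = {}, None
    for name in ("Ga", "D", "Gaa"):
        df = pd.read_csv(directory / f"{name}.csv", index_col=0)
        mats[name] = df.to_numpy(dtype=float)
        ids = df.index.to_numpy(dtype=object)
    meta_path = directory / "kernels_meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return KernelSet(
        ids=ids, Ga=mats["Ga"], D=mats["D"], Gaa=mats["Gaa"],
        bending_applied=meta.get("bending_applied", {}),
        epsilon=meta.get("epsilon", 1e-6),
    )


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno[["individual", "year", "trait", "value"]].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_family_map(family_map: dict, path) -> None:
    pd.DataFrame(
        {"individual": list(family_map), "family": list(family_map.values())}
    ).to_csv(path, index=False)


def read_family_map(path) -> dict:
    df = pd.read_csv(path)
    return dict(zip(df["individual"], df["family"]))


def write_config(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def read_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_truth(truth: SimulationTruth, path) -> None:
    """Sidecar record of the generating parameters and effect vectors."""
    payload = {
        "true_sigma2": truth.true_sigma2,
        "residual_variance": truth.residual_variance,
        "residual_corr_matrix": np.asarray(truth.residual_corr_matrix).tolist(),
        "true_fixed": {str(k): v for k, v in truth.true_fixed.items()},
        "true_effects": {k: np.asarray(v).tolist() for k, v in truth.true_effects.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> SimulationTruth:
    d = json.loads(Path(path).read_text())
    return SimulationTruth(
        true_sigma2=d["true_sigma2"],
        residual_variance=d["residual_variance"],
        residual_corr_matrix=np.array(d["residual_corr_matrix"]),
        true_effects={k: np.array(v) for k, v in d["true_effects"].items()},
        true_fixed={int(k): v for k, v in d["true_fixed"].items()},
    )
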