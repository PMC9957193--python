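"""File formats: dosage TSV, kernel TSV, phenotype/pedigree CSV, VCF import.

The on-disk layout a dataset directory uses (and ``simulate`` writes):

* ``males.tsv`` / ``females.tsv`` — dosage matrices, first row marker ids,
  first column line ids, missing as ``NA`` or empty;
* ``pedigree.csv`` — columns ``hybrid,male,female``;
* ``phenotypes.csv`` — long format with columns ``entity_id, entity_role,
  environment, trait, value``; hybrid rows carry an environment, parent
  rows leave it empty;
* kernel TSVs — square matrices with entity ids as header row and first
  column.

VCF import (biallelic GT records only) goes through cyvcf2.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .kernels import HybridPedigree, RelationshipKernel
from .marker_qc import MarkerMatrix
from .parental_covariates import ParentalPhenotypes

logger = logging.getLogger("hybridpred")

MISSING_SENTINELS = ["NA", ""]


class IOError_(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------- dosage TSV

def write_dosage_tsv(markers: MarkerMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        markers.dosages, index=markers.line_ids, columns=markers.marker_ids
    )
    df.index.name = "line_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


def read_dosage_tsv(path: str | Path) -> MarkerMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dups = sorted({m for m in header if header.count(m) > 1})
    if dups:
        raise IOError_(f"duplicate marker ids in {path}: {dups}")
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, dtype=str,
            keep_default_na=False, na_values=MISSING_SENTINELS,
        )
    except pd.errors.ParserError as exc:
        raise IOError_(f"malformed dosage TSV {path}: {exc}") from exc
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise IOError_(f"duplicate line ids in {path}: {dups}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise IOError_(f"non-numeric dosage cell in {path}: {exc}") from exc
    return MarkerMatrix(list(df.index), list(df.columns), values)


# ---------------------------------------------------------------- kernel TSV

def write_kernel_tsv(kernel: RelationshipKernel, path: str | Path) -> None:
    df = pd.DataFrame(kernel.values, index=kernel.entity_ids, columns=kernel.entity_ids)
    df.index.name = "entity_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_kernel_tsv(path: str | Path, kind: str = "GRM") -> RelationshipKernel:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise IOError_(f"kernel row/column ids differ in {path}")
    return RelationshipKernel(list(df.index.astype(str)), df.to_numpy(dtype=float), kind)


# ------------------------------------------------------------- pedigree CSV

def write_pedigree_csv(pedigree: HybridPedigree, path: str | Path) -> None:
    pd.DataFrame(
        {"hybrid": pedigree.hybrid_ids, "male": pedigree.male_ids,
         "female": pedigree.female_ids}
    ).to_csv(path, index=False)


def read_pedigree_csv(path: str | Path) -> HybridPedigree:
    df = pd.read_csv(path, dtype=str)
    required = {"hybrid", "male", "female"}
    if not required.issubset(df.columns):
        raise IOError_(f"pedigree CSV needs columns {sorted(required)}")
    return HybridPedigree(list(df["hybrid"]), list(df["male"]), list(df["female"]))


# ------------------------------------------------------------ phenotype CSV

def write_phenotypes_csv(
    hybrid_records: pd.DataFrame,
    parental: ParentalPhenotypes | None,
    path: str | Path,
) -> None:
    """Write the long-format phenotype file (hybrid + parent rows)."""
    rows = hybrid_records.rename(columns={"hybrid": "entity_id"}).copy()
    rows["entity_role"] = "hybrid"
    parts = [rows[["entity_id", "entity_role", "environment", "trait", "value"]]]
    if parental is not None:
        prow = parental.table.rename(columns={"parent_id": "entity_id"}).copy()
        prow["entity_role"] = "parent"
        prow["environment"] = ""
        parts.append(prow[["entity_id", "entity_role", "environment", "trait", "value"]])
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_phenotypes_csv(
    path: str | Path, pedigree: HybridPedigree | None = None
) -> tuple[pd.DataFrame, ParentalPhenotypes | None]:
    """Read the long phenotype CSV; returns (hybrid records, parental phenotypes).

    Hybrid records come back with columns ``hybrid, environment, trait,
    value``.  Parent rows must have an empty environment field.  When a
    pedigree is given, hybrid ids are validated against it.
    """
    df = pd.read_csv(
        path, dtype={"entity_id": str, "entity_role": str, "environment": str,
                     "trait": str},
        keep_default_na=False, na_values={"value": MISSING_SENTINELS},
    )
    required = {"entity_id", "entity_role", "environment", "trait", "value"}
    if not required.issubset(df.columns):
        raise IOError_(f"phenotype CSV needs columns {sorted(required)}")
    bad_roles = sorted(set(df["entity_role"]) - {"hybrid", "parent"})
    if bad_roles:
        raise IOError_(f"unknown entity_role values: {bad_roles}")
    dup = df.duplicated(subset=["entity_id", "environment", "trait"])
    if dup.any():
        keys = df.loc[dup, ["entity_id", "environment", "trait"]].values.tolist()
        raise IOError_(f"duplicate (entity, environment, trait) records: {keys[:10]}")

    hyb = df[df["entity_role"] == "hybrid"].copy()
    par = df[df["entity_role"] == "parent"].copy()
    if (par["environment"].str.len() > 0).any():
        bad = par.loc[par["environment"].str.len() > 0, "entity_id"].tolist()
        raise IOError_(f"parental records carry an environment: {bad[:10]}")

    hybrid_records = hyb.rename(columns={"entity_id": "hybrid"})[
        ["hybrid", "environment", "trait", "value"]
    ].reset_index(drop=True)
    hybrid_records["value"] = hybrid_records["value"].astype(float)
    if pedigree is not None:
        unknown = sorted(
            set(hybrid_records["hybrid"]) - set(pedigree.hybrid_ids)
        )
        if unknown:
            raise IOError_(f"hybrids not in pedigree: {unknown[:10]}")

    parental = None
    if len(par):
        ptab = par.rename(columns={"entity_id": "parent_id"})[
            ["parent_id", "trait", "value"]
        ].reset_index(drop=True)
        ptab["value"] = ptab["value"].astype(float)
        parental = ParentalPhenotypes(ptab)
    return hybrid_records, parental


# ------------------------------------------------------------------ VCF

def read_vcf_dosage(path: str | Path) -> MarkerMatrix:
    """Import ALT-allele dosages (0/1/2) from a biallelic VCF via cyvcf2.

    Multiallelic records are skipped with a logged warning; missing
    genotypes (``./.``) become NaN.  Marker ids are the VCF ID field or
    ``CHROM:POS`` when absent.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise IOError_(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_multiallelic = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multiallelic += 1
            continue
        genos = v.genotypes
        if genos is None or len(genos) != len(samples):
            raise IOError_(f"record {v.CHROM}:{v.POS} lacks GT genotypes")
        col = np.empty(len(samples))
        for i, g in enumerate(genos):
            alleles = g[:-1]
            if any(a < 0 for a in alleles):
                col[i] = np.nan
            else:
                col[i] = float(sum(1 for a in alleles if a > 0))
        marker_ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        columns.append(col)
    if n_multiallelic:
        logger.warning("skipped %d multiallelic VCF records", n_multiallelic)
    if not columns:
        raise IOError_(f"no usable biallelic records in {path}")
    return MarkerMatrix(samples, marker_ids, np.column_stack(columns))


# ----------------------------------------------------------- dataset folder

DATASET_FILES = ("males.tsv", "females.tsv", "pedigree.csv", "phenotypes.csv")


def save_dataset(dataset, out_dir: str | Path) -> None:
    """Write the four dataset files into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_dosage_tsv(dataset.male_markers, out / "males.tsv")
    write_dosage_tsv(dataset.female_markers, out / "females.tsv")
    write_pedigree_csv(dataset.pedigree, out / "pedigree.csv")
    write_phenotypes_csv(
        dataset.phenotypes, dataset.parental_phenotypes, out / "phenotypes.csv"
    )


def load_dataset(in_dir: str | Path):
    """Load a dataset directory written by :func:`save_dataset`."""
    from .synth import HybridDataset

    d = Path(in_dir)
    for name in DATASET_FILES:
        if not (d / name).exists():
            raise IOError_(f"dataset directory {d} is missing {name}")
    pedigree = read_pedigree_csv(d / "pedigree.csv")
    phenotypes, parental = read_phenotypes_csv(d / "phenotypes.csv", pedigree)
    if parental is None:
        raise IOError_(f"phenotypes.csv in {d} has no parental records")
    return HybridDataset(
        male_markers=read_dosage_tsv(d / "males.tsv"),
        female_markers=read_dosage_tsv(d / "females.tsv"),
        pedigree=pedigree,
        phenotypes=phenotypes,
        parental_phenotypes=parental,
        traits=sorted(phenotypes["trait"].unique()),
    )


# ------------------------------------------------------------------ manifest

def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_manifest(
    out_dir: str | Path, command: str, seed: int, config: dict,
    input_paths: list[str | Path] | None = None,
) -> Path:
    """Record command, seed, config echo and input checksums for a run."""
    from importlib.metadata import PackageNotFoundError, version

    try:
        pkg_version = version("hybridpred")
    except PackageNotFoundError:  # pragma: no cover
        pkg_version = "unknown"
    manifest = {
        "command": command,
        "seed": seed,
        "package_version": pkg_version,
        "config": config,
        "inputs": {
            str(p): _checksum(Path(p)) for p in (input_paths or []) if Path(p).exists()
        },
    }
    out = Path(out_dir) / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return out
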