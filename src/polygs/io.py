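"""File formats: genotype CSV/VCF, pedigree CSV, phenotype CSV, reports.

Genotype CSV: rows = individuals (first column ``id``), columns = SNP
ids, values 0/1/2 as alt-allele dosage, empty cell = missing.  Pedigree
CSV: ``id,dam,sire[,flag]`` with empty or ``0`` for unknown parents.
Phenotype CSV: ``id,site,block[,group]`` plus one numeric column per
trait.  VCF export writes unphased GT on a synthetic single contig; VCF
import accepts biallelic records only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, PedigreeTable, RelationshipMatrix, TraitTable

log = logging.getLogger(__name__)


def write_genotypes_csv(genotypes: GenotypeMatrix, path) -> None:
    df = genotypes.to_frame()
    df.index.name = "id"
    df.to_csv(path, float_format="%.0f")


def read_genotypes_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col="id", dtype=str)
    if df.index.duplicated().any():
        raise ValueError(f"duplicate individual id {df.index[df.index.duplicated()][0]!r}")
    calls = np.full(df.shape, MISSING, dtype=np.int8)
    for j, col in enumerate(df.columns):
        vals = df[col]
        obs = vals.notna() & (vals != "")
        parsed = pd.to_numeric(vals[obs], errors="coerce")
        bad = parsed.isna() | ~parsed.isin([0, 1, 2])
        if bad.any():
            row = parsed.index[bad][0]
            raise ValueError(
                f"invalid genotype value {vals.loc[row]!r} at row {row!r}, column {col!r}"
            )
        calls[obs.to_numpy(), j] = parsed.astype(np.int8)
    return GenotypeMatrix(ids=[str(i) for i in df.index], snp_ids=list(df.columns), calls=calls)


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotypes_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal unphased-GT VCF on one synthetic contig (positions 1..m)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=chrU>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(genotypes.ids) + "\n")
        for j, snp in enumerate(genotypes.snp_ids):
            gts = "\t".join(_GT_CODE[int(c)] for c in genotypes.calls[:, j])
            fh.write(f"chrU\t{j + 1}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read unphased GT dosages from a VCF; multiallelic records skipped."""
    ids: list[str] = []
    snp_ids: list[str] = []
    rows: list[list[int]] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                ids = line.rstrip("\n").split("\t")[9:]
                continue
            parts = line.rstrip("\n").split("\t")
            alt = parts[4]
            if "," in alt or alt == "." or len(parts[3]) != 1 or len(alt) != 1:
                skipped += 1
                continue
            snp_ids.append(parts[2] if parts[2] != "." else f"{parts[0]}:{parts[1]}")
            fmt = parts[8].split(":")
            gt_i = fmt.index("GT")
            row = []
            for sample in parts[9:]:
                gt = sample.split(":")[gt_i].replace("|", "/")
                if "." in gt:
                    row.append(MISSING)
                else:
                    row.append(sum(int(a) for a in gt.split("/")))
            rows.append(row)
    if skipped:
        log.warning("skipped %d non-biallelic VCF records", skipped)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in VCF")
    calls = np.array(rows, dtype=np.int8).T if rows else np.zeros((len(ids), 0), np.int8)
    return GenotypeMatrix(ids=ids, snp_ids=snp_ids, calls=calls)


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("vcf" if "".join(path.suffixes).endswith((".vcf",)) or path.suffix == ".vcf" else "csv")
    return read_genotypes_vcf(path) if fmt == "vcf" else read_genotypes_csv(path)


def write_pedigree_csv(ped: PedigreeTable, path, flags: dict[str, bool] | None = None) -> None:
    df = ped.records.copy()
    df = df.fillna("")
    if flags is not None:
        df["flag"] = [int(flags.get(i, False)) for i in df["id"]]
    df.to_csv(path, index=False)


def read_pedigree(path) -> PedigreeTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return PedigreeTable(df[["id", "dam", "sire"]].replace({"": None}))


def write_phenotypes_csv(traits: TraitTable, path) -> None:
    traits.data.to_csv(path, index=False)


def read_phenotypes(path) -> TraitTable:
    df = pd.read_csv(path)
    df["id"] = df["id"].astype(str)
    return TraitTable(df)


def write_matrix_tsv(matrix: RelationshipMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids)
    df.index.name = matrix.kind
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path, kind: str | None = None) -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RelationshipMatrix(
        ids=[str(i) for i in df.index], values=df.to_numpy(float), kind=kind or df.index.name or "K"
    )


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def write_manifest(path, config, seeds: dict, files: dict[str, str]) -> None:
    """Run manifest: config snapshot, seeds, and input/output digests."""
    snap = asdict(config) if is_dataclass(config) else dict(config)
    payload = {
        "config": _jsonable(snap),
        "seeds": seeds,
        "files": {k: file_digest(v) for k, v in files.items() if Path(v).exists()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if is_dataclass(obj):
        return _jsonable(asdict(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
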