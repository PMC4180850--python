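"""Text-format readers and writers.

PLINK ped/map (whitespace-delimited, alleles coded 1/2, missing 0), GCTA
text GRM (``.grm.gz``-style triplets, written uncompressed, with a
``.grm.id`` companion), and the pedigree/phenotype/EBV CSV conventions
used across the package. Everything is plain text so fixtures and outputs
stay diffable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geno_qc import MISSING, GenotypeTable
from .grm import GRMatrix

__all__ = [
    "write_plink",
    "read_plink",
    "write_grm",
    "read_grm",
    "write_pedigree",
    "read_pedigree",
    "write_json",
]


def write_plink(table: GenotypeTable, prefix: str | Path) -> tuple[Path, Path]:
    """Write a genotype table as PLINK text ``.ped``/``.map``.

    Genotype 0/1/2 (count of allele "2") maps to allele pairs
    ``1 1`` / ``1 2`` / ``2 2``; missing calls become ``0 0``. The .ped
    family/parent/sex/phenotype columns are placeholders (QC and modelling
    use the CSV pedigree, not the .ped columns).
    """
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for r in table.snps.itertuples():
            fh.write(f"{r.chrom} {r.snp_id} {float(r.pos):g} {int(round(float(r.pos) * 1e4))}\n")
    pair = {0: "1 1", 1: "1 2", 2: "2 2", MISSING: "0 0"}
    calls = table.calls
    if not np.issubdtype(np.asarray(calls).dtype, np.integer):
        raise ValueError("write integer (pre-imputation) genotypes to PLINK")
    with open(ped_path, "w") as fh:
        for i, aid in enumerate(table.animal_ids):
            geno = " ".join(pair[int(c)] for c in calls[i])
            fh.write(f"FAM {aid} 0 0 0 -9 {geno}\n")
    return ped_path, map_path


def read_plink(prefix: str | Path) -> GenotypeTable:
    """Read PLINK text ``.ped``/``.map`` written by :func:`write_plink`
    (or any 1/2-coded text fileset)."""
    prefix = Path(prefix)
    snps = pd.read_csv(
        prefix.with_suffix(".map"),
        sep=r"\s+",
        names=["chrom", "snp_id", "pos", "bp"],
        dtype={"chrom": str},
    )[["snp_id", "chrom", "pos"]]
    snps["a1"] = "1"
    snps["a2"] = "2"
    ids, rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            ids.append(parts[1])
            alleles = np.array(parts[6:], dtype=int).reshape(-1, 2)
            calls = np.where(
                (alleles == 0).any(axis=1), MISSING, (alleles == 2).sum(axis=1)
            )
            rows.append(calls.astype(np.int8))
    return GenotypeTable(ids, snps, np.vstack(rows))


def write_grm(g: GRMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write a GRM in GCTA text form: ``<prefix>.grm.txt`` with
    (i, j, n_snps, value) triplets over the lower triangle (1-based) and
    ``<prefix>.grm.id`` with one animal id per line; metadata goes to a
    JSON sidecar."""
    prefix = Path(prefix)
    txt = prefix.parent / f"{prefix.name}.grm.txt"
    idp = prefix.parent / f"{prefix.name}.grm.id"
    n_snps = int(g.meta.get("n_snps", 0))
    with open(txt, "w") as fh:
        for i in range(g.n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{n_snps}\t{g.values[i, j]:.12g}\n")
    with open(idp, "w") as fh:
        for a in g.animal_ids:
            fh.write(f"FAM\t{a}\n")
    meta = {"flavor": g.flavor, "denominator": g.denominator, **g.meta}
    write_json(meta, prefix.parent / f"{prefix.name}.grm.json")
    return txt, idp


def read_grm(prefix: str | Path) -> GRMatrix:
    prefix = Path(prefix)
    ids = [
        line.split()[1]
        for line in open(prefix.parent / f"{prefix.name}.grm.id")
        if line.strip()
    ]
    n = len(ids)
    vals = np.zeros((n, n))
    n_snps = 0
    with open(prefix.parent / f"{prefix.name}.grm.txt") as fh:
        for line in fh:
            i, j, n_snps, v = line.split()
            vals[int(i) - 1, int(j) - 1] = vals[int(j) - 1, int(i) - 1] = float(v)
    meta_path = prefix.parent / f"{prefix.name}.grm.json"
    meta = json.load(open(meta_path)) if meta_path.exists() else {}
    flavor = meta.pop("flavor", "G1")
    denom = meta.pop("denominator", float("nan"))
    meta.setdefault("n_snps", int(n_snps))
    return GRMatrix(ids, vals, flavor, denom, meta)


def write_pedigree(pedigree: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = [c for c in ("id", "sire", "dam", "sex", "breed", "generation", "cohort", "flock")
            if c in pedigree.columns]
    pedigree[cols].to_csv(path, index=False)
    return path


def read_pedigree(path: str | Path) -> pd.DataFrame:
    ped = pd.read_csv(path)
    for col in ("id", "sire", "dam"):
        ped[col] = ped[col].astype(int)
    if "breed" in ped.columns:
        ped["breed"] = ped["breed"].fillna("")
    return ped


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
    return path
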