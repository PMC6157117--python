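"""Readers and writers for the on-disk interchange formats.

Genotypes travel as PLINK-style text PED/MAP with alleles coded A (reference)
and B (alternate); pedigrees as 5-column whitespace-delimited text (id,
father, mother, sex, generation; missing parent = 0); phenotypes as
tab-delimited text with a header; relationship matrices as GCTA-style triplet
text plus a square form, with method/normalization in a JSON sidecar; IBD
truth as a compressed NumPy sidecar with a documented layout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinship import RelationshipMatrix
from .pedigree import Pedigree, PedigreeError, PedigreeRecord
from .simulate import GenotypePanel, IbdTruth

__all__ = [
    "ParseError",
    "write_pedigree", "read_pedigree",
    "write_ped_map", "read_ped_map",
    "write_phenotypes", "read_phenotypes",
    "write_relationship", "read_relationship",
    "write_ibd_truth", "read_ibd_truth",
]


class ParseError(ValueError):
    """Malformed input file; the message names file, line and field."""


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

_SEX_OUT = {"male": "1", "female": "2"}
_SEX_IN = {"1": "male", "2": "female"}


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# id father mother sex generation\n")
        for r in pedigree.records:
            fh.write(f"{r.individual_id} {r.father_id or '0'} "
                     f"{r.mother_id or '0'} {_SEX_OUT[r.sex]} {r.generation}\n")


def read_pedigree(path: str | Path) -> Pedigree:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 fields, "
                                 f"got {len(parts)}")
            iid, fa, mo, sex, gen = parts
            if sex not in _SEX_IN:
                raise ParseError(f"{path}:{lineno}: sex must be 1 or 2, "
                                 f"got {sex!r}")
            try:
                g = int(gen)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: generation not an "
                                 f"integer: {gen!r}") from None
            records.append(PedigreeRecord(iid, None if fa == "0" else fa,
                                          None if mo == "0" else mo,
                                          _SEX_IN[sex], g))
    try:
        return Pedigree(records)
    except PedigreeError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def write_ped_map(panel: GenotypePanel, pedigree: Pedigree | None,
                  prefix: str | Path) -> None:
    """Write ``<prefix>.ped`` and ``<prefix>.map``.

    Dosage d (count of the reference allele A) is coded as the unordered
    allele pair: 2 → ``A A``, 1 → ``A B``, 0 → ``B B``.
    """
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for c, sid, cm, bp in zip(panel.chromosome, panel.snp_ids,
                                  panel.cM, panel.bp):
            fh.write(f"{c} {sid} {cm:.6f} {bp}\n")
    fam = {r.individual_id: r for r in pedigree.records} if pedigree else {}
    allele_pairs = {0: "B B", 1: "A B", 2: "A A"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, iid in enumerate(panel.individual_ids):
            rec = fam.get(iid)
            fa = (rec.father_id or "0") if rec else "0"
            mo = (rec.mother_id or "0") if rec else "0"
            sex = _SEX_OUT[rec.sex] if rec else "0"
            geno = " ".join(allele_pairs[int(d)] for d in panel.dosage[i])
            fh.write(f"FAM {iid} {fa} {mo} {sex} -9 {geno}\n")


def read_ped_map(prefix: str | Path) -> GenotypePanel:
    prefix = Path(prefix)
    map_path, ped_path = prefix.with_suffix(".map"), prefix.with_suffix(".ped")
    chroms, snp_ids, cms, bps = [], [], [], []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 fields")
            chroms.append(int(parts[0]))
            snp_ids.append(parts[1])
            cms.append(float(parts[2]))
            bps.append(int(parts[3]))
    m = len(snp_ids)
    ids, rows = [], []
    code = {("A", "A"): 2, ("A", "B"): 1, ("B", "A"): 1, ("B", "B"): 0}
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ParseError(f"{ped_path}:{lineno}: expected {6 + 2 * m} "
                                 f"fields, got {len(parts)}")
            ids.append(parts[1])
            alleles = parts[6:]
            row = np.empty(m, dtype=np.int8)
            for j in range(m):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                try:
                    row[j] = code[(a, b)]
                except KeyError:
                    raise ParseError(
                        f"{ped_path}:{lineno}: allele code {a!r}/{b!r} at SNP "
                        f"{snp_ids[j]} not in {{A,B}}") from None
            rows.append(row)
    dosage = np.vstack(rows)
    freq = dosage.mean(axis=0) / 2.0
    return GenotypePanel(ids, snp_ids, dosage, np.array(chroms),
                         np.array(cms), np.array(bps), freq)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "individual_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'individual_id'")
    return df


# ---------------------------------------------------------------------------
# Relationship matrices
# ---------------------------------------------------------------------------

def write_relationship(K: RelationshipMatrix, prefix: str | Path,
                       n_snps: int = 0) -> None:
    """Write triplet (``.grm.txt``), square (``.square.txt``), ids and JSON
    sidecar (``.meta.json``)."""
    prefix = Path(prefix)
    with open(f"{prefix}.grm.id", "w") as fh:
        for iid in K.individual_ids:
            fh.write(f"FAM {iid}\n")
    with open(f"{prefix}.grm.txt", "w") as fh:
        for i in range(K.n):
            for j in range(i + 1):
                fh.write(f"{i + 1} {j + 1} {n_snps} {K.values[i, j]:.10g}\n")
    np.savetxt(f"{prefix}.square.txt", K.values, fmt="%.10g", delimiter="\t")
    with open(f"{prefix}.meta.json", "w") as fh:
        json.dump({"method": K.method, "normalized": K.normalized,
                   "n_individuals": K.n, "n_snps": n_snps}, fh, indent=2)
        fh.write("\n")


def read_relationship(prefix: str | Path) -> RelationshipMatrix:
    prefix = Path(prefix)
    with open(f"{prefix}.meta.json") as fh:
        meta = json.load(fh)
    ids = []
    with open(f"{prefix}.grm.id") as fh:
        for line in fh:
            parts = line.split()
            if parts:
                ids.append(parts[1])
    n = len(ids)
    v = np.zeros((n, n))
    with open(f"{prefix}.grm.txt") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ParseError(f"{prefix}.grm.txt:{lineno}: expected 4 fields")
            i, j = int(parts[0]) - 1, int(parts[1]) - 1
            v[i, j] = v[j, i] = float(parts[3])
    return RelationshipMatrix(ids, v, meta["method"], meta["normalized"])


# ---------------------------------------------------------------------------
# IBD truth sidecar
# ---------------------------------------------------------------------------

def write_ibd_truth(ibd: IbdTruth, path: str | Path) -> None:
    """Compressed sidecar.  Layout: ``labels`` (n, 2, m) int32 founder-haplotype
    indices; ``chromosome`` (m,) int; ``cM`` (m,) float; ``individual_ids``
    (n,) unicode."""
    np.savez_compressed(path, labels=ibd.labels, chromosome=ibd.chromosome,
                        cM=ibd.cM,
                        individual_ids=np.array(ibd.individual_ids))


def read_ibd_truth(path: str | Path) -> IbdTruth:
    with np.load(path, allow_pickle=False) as z:
        return IbdTruth([str(s) for s in z["individual_ids"]],
                        z["labels"], z["chromosome"], z["cM"])
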