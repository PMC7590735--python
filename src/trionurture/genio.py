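"""Readers and writers for the interchange formats the pipeline touches.

PLINK v1 binary genotypes (bed/bim/fam) carry the trio cohorts — the .fam
parental-ID columns encode the trio links — and GCTA-style binary GRMs
(grm.bin / grm.N.bin / grm.id) carry the relatedness matrices, so fitted
models can be cross-checked against external GREML software. Dosages count
copies of allele1 (the .bim A1 allele).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import MISSING, GenerativeParams, TrioCohort

BED_MAGIC = b"\x6c\x1b\x01"  # magic bytes + SNP-major mode

# 2-bit codes: 00 = hom allele1 (dosage 2), 01 = missing, 10 = het, 11 = hom allele2
_CODE_FROM_DOSAGE = {2: 0, MISSING: 1, 1: 2, 0: 3}
_DOSAGE_FROM_CODE = np.array([2, MISSING, 1, 0], dtype=np.int8)

FAM_COLS = ["fid", "iid", "father_iid", "mother_iid", "sex", "phenotype"]
BIM_COLS = ["chrom", "snp_id", "cm", "pos", "allele1", "allele2"]


class FormatError(ValueError):
    """A file does not conform to its binary specification."""


def _p(prefix, ext: str) -> Path:
    return Path(str(prefix) + ext)


@dataclass
class PlinkDataset:
    genotypes: np.ndarray  # n_individuals x n_snps int8 dosages, MISSING = -1
    fam: pd.DataFrame  # columns FAM_COLS
    bim: pd.DataFrame  # columns BIM_COLS


def _encode_snp_column(dosages: np.ndarray) -> np.ndarray:
    """Pack one SNP's dosages for all individuals into ceil(n/4) bytes."""
    codes = np.empty(len(dosages), dtype=np.uint8)
    for dosage, code in _CODE_FROM_DOSAGE.items():
        codes[dosages == dosage] = code
    pad = (-len(codes)) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)])
    quartets = codes.reshape(-1, 4)
    return (
        quartets[:, 0]
        | (quartets[:, 1] << 2)
        | (quartets[:, 2] << 4)
        | (quartets[:, 3] << 6)
    ).astype(np.uint8)


def write_plink(dataset: PlinkDataset, prefix: str | Path) -> None:
    prefix = Path(prefix)
    geno = np.asarray(dataset.genotypes, dtype=np.int8)
    n, m = geno.shape
    if len(dataset.fam) != n:
        raise ValueError(f"fam has {len(dataset.fam)} rows but genotypes have {n}")
    if len(dataset.bim) != m:
        raise ValueError(f"bim has {len(dataset.bim)} rows but genotypes have {m} SNPs")
    bad = ~np.isin(geno, [0, 1, 2, MISSING])
    if bad.any():
        raise ValueError("genotype dosages must be in {0, 1, 2, missing}")
    with open(_p(prefix, ".bed"), "wb") as fh:
        fh.write(BED_MAGIC)
        for j in range(m):
            fh.write(_encode_snp_column(geno[:, j]).tobytes())
    dataset.fam[FAM_COLS].to_csv(
        _p(prefix, ".fam"), sep=" ", header=False, index=False
    )
    dataset.bim[BIM_COLS].to_csv(
        _p(prefix, ".bim"), sep="\t", header=False, index=False
    )


def read_plink(prefix: str | Path) -> PlinkDataset:
    prefix = Path(prefix)
    fam = pd.read_csv(
        _p(prefix, ".fam"), sep=r"\s+", header=None, names=FAM_COLS, dtype=str
    )
    bim = pd.read_csv(
        _p(prefix, ".bim"), sep=r"\s+", header=None, names=BIM_COLS,
        dtype={"chrom": str, "snp_id": str, "allele1": str, "allele2": str},
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(_p(prefix, ".bed"), dtype=np.uint8)
    if raw.size < 3 or raw[:3].tobytes() != BED_MAGIC:
        raise FormatError(
            f"{_p(prefix, '.bed')}: bad magic/mode bytes at offset 0: "
            f"{raw[:3].tobytes().hex()} (expected {BED_MAGIC.hex()})"
        )
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if raw.size != expected:
        raise FormatError(
            f"{_p(prefix, '.bed')}: payload is {raw.size} bytes, expected "
            f"{expected} for {n} individuals x {m} SNPs (truncated at offset {raw.size})"
        )
    payload = raw[3:].reshape(m, bytes_per_snp)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (payload >> (2 * k)) & 0b11
    geno = _DOSAGE_FROM_CODE[codes[:, :n]].T.copy()
    return PlinkDataset(genotypes=geno, fam=fam, bim=bim)


# ---------------------------------------------------------------------------
# GCTA binary GRM


def write_grm(matrix: np.ndarray, ids: pd.DataFrame, prefix: str | Path, n_snps: int) -> None:
    """Write a symmetric relatedness matrix in GCTA binary form
    (lower triangle, row-major, float32)."""
    prefix = Path(prefix)
    K = np.asarray(matrix, dtype=float)
    n = K.shape[0]
    if K.shape != (n, n) or not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("relatedness matrix must be square and symmetric")
    if ids.shape[0] != n:
        raise ValueError(f"{ids.shape[0]} ids for a {n} x {n} matrix")
    if ids.iloc[:, 1].duplicated().any():
        raise ValueError("individual ids must be unique")
    tri = np.tril_indices(n)
    K[tri].astype(np.float32).tofile(str(prefix) + ".grm.bin")
    np.full(len(tri[0]), n_snps, dtype=np.float32).tofile(str(prefix) + ".grm.N.bin")
    ids.iloc[:, :2].to_csv(str(prefix) + ".grm.id", sep="\t", header=False, index=False)


def read_grm(prefix: str | Path) -> tuple[np.ndarray, pd.DataFrame, float]:
    prefix = Path(prefix)
    ids = pd.read_csv(
        str(prefix) + ".grm.id", sep=r"\s+", header=None, names=["fid", "iid"], dtype=str
    )
    n = len(ids)
    vals = np.fromfile(str(prefix) + ".grm.bin", dtype=np.float32)
    n_expected = n * (n + 1) // 2
    if vals.size != n_expected:
        raise FormatError(
            f"{prefix}.grm.bin holds {vals.size} values but {prefix}.grm.id lists "
            f"{n} individuals (need {n_expected})"
        )
    K = np.zeros((n, n))
    tri = np.tril_indices(n)
    K[tri] = vals
    K = K + K.T - np.diag(np.diag(K))
    counts = np.fromfile(str(prefix) + ".grm.N.bin", dtype=np.float32)
    n_snps = float(counts[0]) if counts.size else float("nan")
    return K, ids, n_snps


# ---------------------------------------------------------------------------
# Phenotype / covariate tables (FID/IID-keyed TSV)


def read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    df = df.rename(columns={df.columns[0]: "fid", df.columns[1]: "iid"})
    return df


def align_by_id(ids: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Align a (FID, IID)-keyed table to a roster of ids.

    Unmatched rows on either side are reported with a warning; roster rows
    without a table entry come back as NaN — nothing is silently dropped.
    """
    roster = ids.iloc[:, :2].copy()
    roster.columns = ["fid", "iid"]
    merged = roster.merge(table, on=["fid", "iid"], how="left", indicator=True)
    missing = int((merged["_merge"] == "left_only").sum())
    extra = int(len(table) - (merged["_merge"] == "both").sum())
    if missing or extra:
        warnings.warn(
            f"id join: {missing} roster individuals without a table row, "
            f"{extra} table rows not in the roster",
            stacklevel=2,
        )
    return merged.drop(columns="_merge")


# ---------------------------------------------------------------------------
# Trio cohorts as PLINK filesets


def write_cohort(cohort: TrioCohort, prefix: str | Path) -> None:
    """Serialize a trio cohort: one PLINK fileset holding children and both
    parents (trio links in .fam), phenotype/mediator TSVs and a truth sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sid = cohort.sample_ids
    n = cohort.n_trios
    geno = np.vstack(
        [cohort.child_genotypes, cohort.mother_genotypes, cohort.father_genotypes]
    )
    fam = pd.DataFrame(
        {
            "fid": pd.concat([sid.fid] * 3, ignore_index=True),
            "iid": pd.concat(
                [sid.child_iid, sid.mother_iid, sid.father_iid], ignore_index=True
            ),
            "father_iid": list(sid.father_iid) + ["0"] * (2 * n),
            "mother_iid": list(sid.mother_iid) + ["0"] * (2 * n),
            "sex": [0] * n + [2] * n + [1] * n,
            "phenotype": -9,
        }
    )
    write_plink(PlinkDataset(geno, fam, cohort.snp_info), prefix)
    pheno = pd.DataFrame(
        {"fid": sid.fid, "iid": sid.child_iid, "phenotype": cohort.child_phenotype}
    )
    pheno.to_csv(str(prefix) + ".pheno.tsv", sep="\t", index=False)
    if cohort.mediator is not None:
        med = pd.DataFrame({"fid": sid.fid, "iid": sid.mother_iid})
        med["mediator"] = cohort.mediator
        if cohort.mediator_timepoints is not None:
            for t in range(cohort.mediator_timepoints.shape[1]):
                med[f"t{t + 1}"] = cohort.mediator_timepoints[:, t]
        med.to_csv(str(prefix) + ".mediator.tsv", sep="\t", index=False)
    if cohort.truth is not None:
        with open(str(prefix) + ".truth.json", "w") as fh:
            json.dump(asdict(cohort.truth), fh, indent=2)


def read_cohort(prefix: str | Path) -> TrioCohort:
    prefix = Path(prefix)
    ds = read_plink(prefix)
    fam = ds.fam
    is_child = (fam.father_iid != "0") & (fam.mother_iid != "0")
    children = fam[is_child]
    row_of = {iid: i for i, iid in enumerate(fam.iid)}
    child_rows = children.index.to_numpy()
    mother_rows = np.array([row_of[i] for i in children.mother_iid])
    father_rows = np.array([row_of[i] for i in children.father_iid])
    pheno = pd.read_csv(str(prefix) + ".pheno.tsv", sep="\t", dtype={"fid": str, "iid": str})
    sid = pd.DataFrame(
        {
            "fid": children.fid.to_numpy(),
            "child_iid": children.iid.to_numpy(),
            "mother_iid": children.mother_iid.to_numpy(),
            "father_iid": children.father_iid.to_numpy(),
        }
    )
    y = align_by_id(
        sid[["fid", "child_iid"]].rename(columns={"child_iid": "iid"}), pheno
    )["phenotype"].to_numpy(float)
    mediator = timepoints = None
    med_path = Path(str(prefix) + ".mediator.tsv")
    if med_path.exists():
        med = pd.read_csv(med_path, sep="\t", dtype={"fid": str, "iid": str})
        aligned = align_by_id(
            sid[["fid", "mother_iid"]].rename(columns={"mother_iid": "iid"}), med
        )
        mediator = aligned["mediator"].to_numpy(float)
        tcols = [c for c in aligned.columns if c.startswith("t")]
        if tcols:
            timepoints = aligned[tcols].to_numpy(float)
    truth = None
    truth_path = Path(str(prefix) + ".truth.json")
    if truth_path.exists():
        with open(truth_path) as fh:
            d = json.load(fh)
        d["maf_range"] = tuple(d["maf_range"])
        truth = GenerativeParams(**d)
    return TrioCohort(
        child_genotypes=ds.genotypes[child_rows],
        mother_genotypes=ds.genotypes[mother_rows],
        father_genotypes=ds.genotypes[father_rows],
        snp_info=ds.bim,
        sample_ids=sid,
        child_phenotype=y,
        mediator=mediator,
        mediator_timepoints=timepoints,
        truth=truth,
    )
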