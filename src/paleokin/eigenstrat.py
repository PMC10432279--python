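"""EIGENSTRAT and metadata text I/O.

EIGENSTRAT stores genotypes as a text matrix (.geno: one row per SNP, one
digit per individual counting reference alleles), site coordinates (.snp)
and individual labels (.ind). For pseudo-haploid data only three digits
occur: ``2`` (the sampled read carried the reference allele), ``0``
(alternate) and ``9`` (no read). A genuine heterozygote digit ``1`` cannot
arise from single-read sampling and is rejected by default.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ALT,
    INDETERMINATE,
    MISSING,
    REF,
    XX,
    XY,
    IndividualRecord,
    PseudoHaploidMatrix,
    ReadCountProfile,
    SNPPanel,
)

logger = logging.getLogger(__name__)

_SEX_TO_IND = {XX: "F", XY: "M", INDETERMINATE: "U"}
_IND_TO_SEX = {"F": XX, "M": XY, "U": INDETERMINATE}

METADATA_COLUMNS = [
    "id",
    "sex",
    "age_class",
    "age_min",
    "age_max",
    "mt_hg",
    "y_hg",
    "grave_x",
    "grave_y",
]


def read_eigenstrat(
    geno_path: str | Path,
    snp_path: str | Path,
    ind_path: str | Path,
    het_policy: str = "error",
    rng: Optional[np.random.Generator] = None,
) -> tuple[SNPPanel, PseudoHaploidMatrix, list[str]]:
    """Read an EIGENSTRAT trio into a panel and a pseudo-haploid matrix.

    Parameters
    ----------
    het_policy : {"error", "random"}
        What to do with a genuine heterozygote digit ``1``: reject the file
        (default; the pseudo-haploid contract forbids it) or resolve it to a
        random allele, with a logged warning.
    """
    if het_policy not in ("error", "random"):
        raise ValueError(f"unknown het_policy {het_policy!r}")

    snp = pd.read_csv(
        snp_path,
        sep=r"\s+",
        header=None,
        names=["snp_id", "chrom", "gpos", "pos", "ref", "alt"],
        dtype={"chrom": str},
    )
    if snp.empty:
        raise ValueError(f"{snp_path}: no sites")
    known = {str(c) for c in range(1, 23)} | {"23", "24", "X", "Y", "MT", "90"}
    bad_chrom = sorted(set(snp["chrom"]) - known)
    if bad_chrom:
        raise ValueError(f"{snp_path}: unknown chromosome labels {bad_chrom}")
    panel = SNPPanel(
        chrom=snp["chrom"].to_numpy(dtype=object),
        pos=snp["pos"].to_numpy(dtype=np.int64),
        gpos=snp["gpos"].to_numpy(dtype=float),
        ref=snp["ref"].to_numpy(dtype=object),
        alt=snp["alt"].to_numpy(dtype=object),
    )

    ind = pd.read_csv(
        ind_path, sep=r"\s+", header=None, names=["id", "sex", "pop"], dtype=str
    )
    ids = ind["id"].tolist()

    lines = Path(geno_path).read_text().split()
    if len(lines) == 0:
        raise ValueError(f"{geno_path}: no sites")
    if len(lines) != panel.n_sites:
        raise ValueError(
            f"{geno_path}: {len(lines)} rows but .snp lists {panel.n_sites} sites"
        )
    width = len(ids)
    raw = np.empty((panel.n_sites, width), dtype=np.uint8)
    for s, line in enumerate(lines):
        if len(line) != width:
            raise ValueError(
                f"{geno_path}: row {s} width {len(line)} != {width} individuals"
            )
        row = np.frombuffer(line.encode("ascii"), dtype=np.uint8) - ord("0")
        if np.any(row > 9):
            raise ValueError(f"{geno_path}: non-digit character in row {s}")
        raw[s] = row

    ok = np.isin(raw, (0, 1, 2, 9))
    if not ok.all():
        raise ValueError(f"{geno_path}: genotype digits must be 0/1/2/9")

    calls = np.full(raw.shape, MISSING, dtype=np.int8)
    calls[raw == 2] = REF
    calls[raw == 0] = ALT
    het = raw == 1
    if het.any():
        if het_policy == "error":
            raise ValueError(
                f"{geno_path}: heterozygote digit '1' found "
                "(not pseudo-haploid); pass het_policy='random' to resolve"
            )
        n_het = int(het.sum())
        logger.warning("%s: resolving %d heterozygote calls to random alleles", geno_path, n_het)
        warnings.warn(f"{geno_path}: {n_het} heterozygote calls resolved randomly")
        rng = rng if rng is not None else np.random.default_rng()
        calls[het] = rng.integers(0, 2, size=n_het).astype(np.int8)

    matrix = PseudoHaploidMatrix(ids, calls.T)
    return panel, matrix, ids


def write_eigenstrat(
    panel: SNPPanel,
    matrix: PseudoHaploidMatrix,
    records: Optional[Sequence[IndividualRecord]],
    geno_path: str | Path,
    snp_path: str | Path,
    ind_path: str | Path,
) -> None:
    """Write panel + matrix (+ sexes from ``records``) as an EIGENSTRAT trio."""
    if matrix.n_sites != panel.n_sites:
        raise ValueError("matrix column count != panel site count")
    sex_by_id = {r.id: r.sex for r in records} if records is not None else {}

    digits = np.full(matrix.calls.shape, ord("9"), dtype=np.uint8)
    digits[matrix.calls == REF] = ord("2")
    digits[matrix.calls == ALT] = ord("0")
    geno_rows = digits.T  # sites x individuals
    with open(geno_path, "w") as fh:
        for row in geno_rows:
            fh.write(row.tobytes().decode("ascii"))
            fh.write("\n")

    with open(snp_path, "w") as fh:
        for s in range(panel.n_sites):
            fh.write(
                f"rs{s} {panel.chrom[s]} {panel.gpos[s]:.6f} "
                f"{panel.pos[s]} {panel.ref[s]} {panel.alt[s]}\n"
            )

    with open(ind_path, "w") as fh:
        for ind_id in matrix.ids:
            sex = _SEX_TO_IND.get(sex_by_id.get(ind_id, INDETERMINATE), "U")
            fh.write(f"{ind_id} {sex} POP\n")


def _blank(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == ""


def read_metadata(tsv_path: str | Path) -> list[IndividualRecord]:
    """Read the per-individual metadata table.

    Required columns: ``id``, ``sex``. Optional columns may be blank; unknown
    columns are kept as opaque annotations in ``record.extra``.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    for col in ("id", "sex"):
        if col not in df.columns:
            raise ValueError(f"{tsv_path}: missing required column {col!r}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"{tsv_path}: duplicate ids {dups}")

    extra_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    records = []
    for _, row in df.iterrows():
        def get(col, cast=str):
            if col not in df.columns or _blank(row[col]):
                return None
            return cast(row[col])

        records.append(
            IndividualRecord(
                id=str(row["id"]),
                sex=str(row["sex"]),
                age_class=get("age_class"),
                age_min=get("age_min", float),
                age_max=get("age_max", float),
                mt_hg=get("mt_hg"),
                y_hg=get("y_hg"),
                grave_x=get("grave_x", float),
                grave_y=get("grave_y", float),
                extra={c: row[c] for c in extra_cols if not _blank(row[c])},
            )
        )
    return records


def write_metadata(records: Sequence[IndividualRecord], tsv_path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "sex": r.sex,
                "age_class": r.age_class or "",
                "age_min": "" if r.age_min is None else r.age_min,
                "age_max": "" if r.age_max is None else r.age_max,
                "mt_hg": r.mt_hg or "",
                "y_hg": r.y_hg or "",
                "grave_x": "" if r.grave_x is None else r.grave_x,
                "grave_y": "" if r.grave_y is None else r.grave_y,
                **r.extra,
            }
        )
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def read_readcounts(tsv_path: str | Path) -> dict[str, ReadCountProfile]:
    """Read a per-individual, per-chromosome read-count table.

    Expected columns: ``id``, ``chrom`` (``A`` pooled autosomes, ``X``, ``Y``),
    ``reads``, ``target_bp``.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"id": str, "chrom": str})
    profiles: dict[str, ReadCountProfile] = {}
    for ind_id, grp in df.groupby("id"):
        by = {row["chrom"]: row for _, row in grp.iterrows()}
        for chrom in ("A", "X", "Y"):
            if chrom not in by:
                raise ValueError(f"{tsv_path}: {ind_id} missing chromosome {chrom!r}")
        profiles[str(ind_id)] = ReadCountProfile(
            autosomal_reads=int(by["A"]["reads"]),
            autosomal_target_bp=int(by["A"]["target_bp"]),
            x_reads=int(by["X"]["reads"]),
            x_target_bp=int(by["X"]["target_bp"]),
            y_reads=int(by["Y"]["reads"]),
            y_target_bp=int(by["Y"]["target_bp"]),
        )
    return profiles
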