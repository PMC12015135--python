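"""Readers and writers for the file-based inputs and reports.

All inputs are plain files (TSV with headers, FASTA, Clustal or
aligned-FASTA); there is no network access. Malformed data rows are
rejected with a logged, row-identifying message and counted, rather than
aborting the run; structural problems (duplicate IDs, ragged alignments)
are hard failures.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import AlignIO, SeqIO

from .model import (
    GAP,
    AlignedFamily,
    Kinase,
    KinaseFamily,
    KinaseType,
    MutationRecord,
    PhosphoSite,
)

logger = logging.getLogger(__name__)

CATALOG_COLUMNS = [
    "kinase_id",
    "gene_symbol",
    "group",
    "family",
    "kinase_type",
    "sequence",
    "domains",
    "disorder",
]
SITE_COLUMNS = [
    "kinase_id",
    "residue",
    "position",
    "ht_count",
    "lt_count",
    "function_tags",
    "functional_score",
]
MUTATION_COLUMNS = ["kinase_id", "position", "ref_residue", "alt_residue", "disease_tag"]


class RejectLog:
    """Collects per-row rejection records for the run summary."""

    def __init__(self) -> None:
        self.records: list[dict] = []

    def reject(self, source: str, row: int, reason: str) -> None:
        logger.warning("%s row %d rejected: %s", source, row, reason)
        self.records.append({"source": source, "row": row, "reason": reason})

    def __len__(self) -> int:
        return len(self.records)


def _parse_intervals(text: str) -> list[tuple[int, int]]:
    """Parse a semicolon-separated '"start-end";...' interval field."""
    if not text or pd.isna(text):
        return []
    out = []
    for chunk in str(text).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        start_s, _, end_s = chunk.partition("-")
        out.append((int(start_s), int(end_s)))
    return out


def format_intervals(intervals: Iterable[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in intervals)


def read_kinase_catalog(path: str | Path, reject_log: Optional[RejectLog] = None) -> list[Kinase]:
    """Read the kinase catalog TSV into validated :class:`Kinase` records.

    Rows with malformed intervals (start > end, end > L) are rejected and
    logged; a duplicate ``kinase_id`` is a hard failure.
    """
    log = reject_log if reject_log is not None else RejectLog()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing catalog columns {sorted(missing)}")
    kinases: list[Kinase] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # 1-based file line, after header
        kid = row["kinase_id"]
        if kid in seen:
            raise ValueError(f"{path} row {rowno}: duplicate kinase_id {kid!r}")
        seen.add(kid)
        try:
            kinases.append(
                Kinase(
                    kinase_id=kid,
                    gene_symbol=row["gene_symbol"],
                    group=row["group"],
                    family=row["family"],
                    kinase_type=KinaseType(row["kinase_type"]),
                    sequence=row["sequence"],
                    domain_intervals=_parse_intervals(row["domains"]),
                    disordered_intervals=_parse_intervals(row["disorder"]),
                )
            )
        except (ValueError, KeyError) as exc:
            log.reject("catalog", rowno, str(exc))
    return kinases


def write_kinase_catalog(kinases: Iterable[Kinase], path: str | Path) -> None:
    rows = [
        {
            "kinase_id": k.kinase_id,
            "gene_symbol": k.gene_symbol,
            "group": k.group,
            "family": k.family,
            "kinase_type": k.kinase_type.value,
            "sequence": k.sequence,
            "domains": format_intervals(k.domain_intervals),
            "disorder": format_intervals(k.disordered_intervals),
        }
        for k in kinases
    ]
    pd.DataFrame(rows, columns=CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_site_table(
    path: str | Path,
    catalog: list[Kinase],
    reject_log: Optional[RejectLog] = None,
) -> list[PhosphoSite]:
    """Read the phosphosite TSV, validating each site against the catalog.

    A site is rejected (and logged) when its kinase is unknown or the
    catalog sequence does not carry the stated residue at the stated
    position — the usual symptom of an isoform mismatch in real exports.
    """
    log = reject_log if reject_log is not None else RejectLog()
    by_id = {k.kinase_id: k for k in catalog}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing site columns {sorted(missing)}")
    sites: list[PhosphoSite] = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 2
        kid = row["kinase_id"]
        kinase = by_id.get(kid)
        if kinase is None:
            log.reject("sites", rowno, f"unknown kinase_id {kid!r}")
            continue
        try:
            pos = int(row["position"])
            residue = row["residue"]
            if not (1 <= pos <= kinase.length):
                raise ValueError(f"position {pos} outside 1..{kinase.length}")
            actual = kinase.sequence[pos - 1]
            if actual != residue:
                raise ValueError(
                    f"residue mismatch at {kid}:{pos}: table says {residue!r}, "
                    f"sequence has {actual!r}"
                )
            tags = frozenset(
                t.strip() for t in row["function_tags"].split(",") if t.strip()
            )
            score_s = row["functional_score"].strip()
            site = PhosphoSite(
                kinase_id=kid,
                residue=residue,
                position=pos,
                ht_count=int(row["ht_count"]),
                lt_count=int(row["lt_count"]),
                function_tags=tags,
                functional_score=float(score_s) if score_s else None,
            )
            if site.ht_count + site.lt_count < 1:
                raise ValueError("site with no evidence (ht_count + lt_count = 0)")
        except ValueError as exc:
            log.reject("sites", rowno, str(exc))
            continue
        sites.append(site)
    return sites


def write_site_table(sites: Iterable[PhosphoSite], path: str | Path) -> None:
    rows = [
        {
            "kinase_id": s.kinase_id,
            "residue": s.residue,
            "position": s.position,
            "ht_count": s.ht_count,
            "lt_count": s.lt_count,
            "function_tags": ",".join(sorted(s.function_tags)),
            "functional_score": "" if s.functional_score is None else repr(s.functional_score),
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_mutation_table(
    path: str | Path,
    catalog: list[Kinase],
    reject_log: Optional[RejectLog] = None,
) -> list[MutationRecord]:
    log = reject_log if reject_log is not None else RejectLog()
    by_id = {k.kinase_id: k for k in catalog}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(MUTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing mutation columns {sorted(missing)}")
    out: list[MutationRecord] = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 2
        kid = row["kinase_id"]
        kinase = by_id.get(kid)
        if kinase is None:
            log.reject("mutations", rowno, f"unknown kinase_id {kid!r}")
            continue
        pos = int(row["position"])
        if not (1 <= pos <= kinase.length):
            log.reject("mutations", rowno, f"position {pos} outside 1..{kinase.length}")
            continue
        out.append(
            MutationRecord(
                kinase_id=kid,
                position=pos,
                ref_residue=row["ref_residue"],
                alt_residue=row["alt_residue"],
                disease_tag=row["disease_tag"],
            )
        )
    return out


def write_mutation_table(mutations: Iterable[MutationRecord], path: str | Path) -> None:
    rows = [
        {
            "kinase_id": m.kinase_id,
            "position": m.position,
            "ref_residue": m.ref_residue,
            "alt_residue": m.alt_residue,
            "disease_tag": m.disease_tag,
        }
        for m in mutations
    ]
    pd.DataFrame(rows, columns=MUTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def _build_col_of(aligned: dict[str, str]) -> dict[str, list[int]]:
    """Scan non-gap characters to map ungapped positions to columns."""
    col_of: dict[str, list[int]] = {}
    for kid, row in aligned.items():
        cols = [c + 1 for c, ch in enumerate(row) if ch != GAP]
        col_of[kid] = cols
    return col_of


def aligned_family_from_rows(name: str, aligned: dict[str, str]) -> AlignedFamily:
    """Build an :class:`AlignedFamily` from gapped rows, validating shape.

    Fewer than two members is a hard failure: single-member families are
    excluded from conservation analysis because there is nothing to
    compare against.
    """
    if len(aligned) < 2:
        raise ValueError(
            f"family {name!r} has {len(aligned)} member(s); single-member "
            "families are excluded from conservation analysis"
        )
    lengths = {len(v) for v in aligned.values()}
    if len(lengths) != 1:
        raise ValueError(f"family {name!r}: unequal aligned lengths {sorted(lengths)}")
    family = KinaseFamily(name=name, member_ids=list(aligned))
    return AlignedFamily(family=family, aligned=dict(aligned), col_of=_build_col_of(aligned))


def read_alignment(path: str | Path, format: str = "aligned_fasta", name: Optional[str] = None) -> AlignedFamily:
    """Read a pre-computed family alignment (Clustal or aligned FASTA)."""
    fmt = {"clustal": "clustal", "aligned_fasta": "fasta"}.get(format)
    if fmt is None:
        raise ValueError(f"unknown alignment format {format!r}")
    msa = AlignIO.read(str(path), fmt)
    aligned = {rec.id: str(rec.seq).upper() for rec in msa}
    if len(aligned) != len(msa):
        raise ValueError(f"{path}: duplicate record ids in alignment")
    return aligned_family_from_rows(name or Path(path).stem, aligned)


def write_alignment(af: AlignedFamily, path: str | Path) -> None:
    """Write an aligned-FASTA file (wrapped at 60 columns)."""
    with open(path, "w") as fh:
        for kid in af.family.member_ids:
            fh.write(f">{kid}\n")
            row = af.aligned[kid]
            for i in range(0, len(row), 60):
                fh.write(row[i : i + 60] + "\n")


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for kid, seq in sequences.items():
            fh.write(f">{kid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def map_to_column(af: AlignedFamily, kinase_id: str, position: int) -> int:
    """Return the 1-based alignment column holding ungapped ``position``."""
    cols = af.col_of.get(kinase_id)
    if cols is None:
        raise KeyError(f"kinase {kinase_id!r} not in alignment of family {af.family.name!r}")
    if not (1 <= position <= len(cols)):
        raise ValueError(
            f"{kinase_id}: position {position} outside ungapped length {len(cols)}"
        )
    return cols[position - 1]
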