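"""File formats: FASTA transcripts, Ψ-site TSV tables, order-sheet CSV.

The order sheet is the package's own documented contract: one row per
successful design, columns ``name, transcript_id, psi_position,
adaptor_side, rna_side, oligo_to_order, warnings`` (warnings
semicolon-joined), comma-delimited, double-quote quoting, LF endings,
UTF-8.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple, Union

from Bio import SeqIO

from .bridge import BatchResult, PsiSite
from .seqcore import AlphabetError, NucSequence, PsiBridgeError, auto

PathLike = Union[str, Path]


class FileFormatError(PsiBridgeError):
    """An input file violates its format contract."""


def read_fasta(path: PathLike) -> List[Tuple[str, NucSequence]]:
    """Read transcripts, auto-detecting DNA vs RNA per record.

    Record ids are the first whitespace-delimited header token; input order
    is preserved; duplicate ids, empty records, ambiguity codes, and
    records mixing U with T are all errors.
    """
    records: List[Tuple[str, NucSequence]] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FileFormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        letters = str(rec.seq)
        if not letters:
            raise FileFormatError(f"empty FASTA record {rec.id!r}")
        try:
            seq = auto(letters)
        except AlphabetError as err:
            raise FileFormatError(f"record {rec.id!r}: {err}") from err
        records.append((rec.id, seq))
    return records


def read_fasta_dict(path: PathLike) -> Dict[str, NucSequence]:
    return dict(read_fasta(path))


PSI_TABLE_COLUMNS = ("transcript_id", "position", "label")


def read_psi_table(path: PathLike) -> List[PsiSite]:
    """Read a tab-separated Ψ-site table with 1-based positions.

    Header must name ``transcript_id`` and ``position`` (``label`` is
    optional and defaults to empty).
    """
    sites: List[PsiSite] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or not {
            "transcript_id", "position"
        }.issubset(reader.fieldnames):
            raise FileFormatError(
                "psi table must have a header with columns "
                "'transcript_id' and 'position' (tab-separated)"
            )
        for lineno, row in enumerate(reader, start=2):
            raw = (row.get("position") or "").strip()
            try:
                position = int(raw)
            except ValueError:
                raise FileFormatError(
                    f"line {lineno}: position {raw!r} is not an integer"
                ) from None
            if position < 1:
                raise FileFormatError(
                    f"line {lineno}: position must be >= 1, got {position}"
                )
            sites.append(
                PsiSite(
                    (row.get("transcript_id") or "").strip(),
                    position,
                    (row.get("label") or "").strip(),
                )
            )
    return sites


def write_psi_table(sites: List[PsiSite], path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(PSI_TABLE_COLUMNS)
        for s in sites:
            writer.writerow([s.transcript_id, s.position, s.label])


@dataclass(frozen=True)
class OrderSheetRow:
    """One orderable bridging oligo on the exported sheet."""

    name: str
    transcript_id: str
    psi_position: int
    adaptor_side: str
    rna_side: str
    oligo_to_order: str
    warnings: str = ""


ORDER_SHEET_COLUMNS = (
    "name",
    "transcript_id",
    "psi_position",
    "adaptor_side",
    "rna_side",
    "oligo_to_order",
    "warnings",
)


def order_rows(batch: BatchResult) -> List[OrderSheetRow]:
    """Flatten successful batch designs into order-sheet rows."""
    return [
        OrderSheetRow(
            name=row.design.oligo.name,
            transcript_id=row.psi.transcript_id,
            psi_position=row.psi.position,
            adaptor_side=row.design.adaptor_side.letters,
            rna_side=row.design.rna_side.letters,
            oligo_to_order=row.design.order_string,
            warnings="; ".join(row.design.warnings),
        )
        for row in batch.rows
    ]


def write_order_csv(rows: List[OrderSheetRow], path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(ORDER_SHEET_COLUMNS)
        for r in rows:
            writer.writerow(
                [r.name, r.transcript_id, r.psi_position, r.adaptor_side,
                 r.rna_side, r.oligo_to_order, r.warnings]
            )


def read_order_csv(path: PathLike) -> List[OrderSheetRow]:
    rows: List[OrderSheetRow] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if tuple(reader.fieldnames or ()) != ORDER_SHEET_COLUMNS:
            raise FileFormatError(
                f"order sheet header must be {','.join(ORDER_SHEET_COLUMNS)}"
            )
        for row in reader:
            rows.append(
                OrderSheetRow(
                    name=row["name"],
                    transcript_id=row["transcript_id"],
                    psi_position=int(row["psi_position"]),
                    adaptor_side=row["adaptor_side"],
                    rna_side=row["rna_side"],
                    oligo_to_order=row["oligo_to_order"],
                    warnings=row["warnings"],
                )
            )
    return rows


def write_fasta(records: List[Tuple[str, NucSequence]], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for rec_id, seq in records:
            handle.write(f">{rec_id}\n")
            letters = seq.letters
            for i in range(0, len(letters), 70):
                handle.write(letters[i : i + 70] + "\n")
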