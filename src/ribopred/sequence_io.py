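"""Reading, validating and assembling gene records.

Coordinate convention used throughout the package: +1 is the first
nucleotide of the start codon, -1 the nucleotide immediately upstream; there
is no position 0, and windows include both endpoints.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio.Seq import Seq

from .tables import START_CODONS, STOP_CODONS

__all__ = [
    "GeneRecord",
    "read_fasta",
    "read_operon_table",
    "filter_protein_coding",
    "translate_cds",
    "assemble_records",
    "write_rejection_report",
]

_IUPAC = set("ACGTRYSWKMBDHVN")


class FastaFormatError(ValueError):
    """Malformed FASTA record (carries the offending line number)."""


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene: 5'-UTR, CDS, derived protein, operon context.

    ``position_in_operon`` is 1-based; ``is_first_gene`` is true exactly for
    position 1 (monocistronic genes count as first genes).
    """

    gene_id: str
    utr5: str
    cds: str
    protein: str
    operon_id: str = ""
    position_in_operon: int = 1

    @property
    def is_first_gene(self) -> bool:
        return self.position_in_operon == 1

    def __post_init__(self) -> None:
        if self.position_in_operon < 1:
            raise ValueError(
                f"{self.gene_id}: position_in_operon must be >= 1"
            )


def _normalize(seq: str) -> str:
    """Uppercase, strip whitespace, map RNA U to DNA T."""
    return "".join(seq.split()).upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly line-wrapped) FASTA file into (id, sequence) pairs.

    The id is the first whitespace-delimited token of the header.  Sequences
    are case-folded, whitespace-stripped and U->T normalized.  Records are
    returned in file order.

    Raises :class:`FastaFormatError` with a line number for a record with an
    empty header or empty sequence, or for sequence letters outside the
    IUPAC nucleotide alphabet.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def _flush(line_no: int) -> None:
        if header is None:
            return
        seq = _normalize("".join(chunks))
        if not header:
            raise FastaFormatError(f"line {header_line}: empty FASTA header")
        if not seq:
            raise FastaFormatError(
                f"line {header_line}: record '{header}' has an empty sequence"
            )
        bad = set(seq) - _IUPAC
        if bad:
            raise FastaFormatError(
                f"line {line_no}: record '{header}' contains non-IUPAC "
                f"letters {sorted(bad)}"
            )
        records.append((header, seq))

    i = 0
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith(">"):
                _flush(i)
                header = line[1:].split()[0] if line[1:].split() else ""
                header_line = i
                chunks = []
            elif line.strip():
                if header is None:
                    raise FastaFormatError(
                        f"line {i}: sequence data before any header"
                    )
                chunks.append(line)
        _flush(i)
    return records


def read_operon_table(path: str | Path) -> dict[str, tuple[str, int, str]]:
    """Read the operon annotation table.

    Expects a tab-separated file with a header row naming the columns
    ``gene_id``, ``operon_id``, ``position`` and ``utr5``.  Returns
    ``gene_id -> (operon_id, position_in_operon, utr5)``; the UTR may be the
    empty string.  Duplicate gene ids and non-positive or non-integer
    positions are errors.
    """
    out: dict[str, tuple[str, int, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene_id", "operon_id", "position", "utr5"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"operon table must have columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            gid = row["gene_id"]
            if gid in out:
                raise ValueError(f"duplicate gene_id {gid!r} in operon table")
            try:
                pos = int(row["position"])
            except (TypeError, ValueError):
                raise ValueError(
                    f"gene {gid!r}: non-integer position {row['position']!r}"
                ) from None
            if pos < 1:
                raise ValueError(f"gene {gid!r}: position must be >= 1")
            out[gid] = (row["operon_id"], pos, _normalize(row["utr5"] or ""))
    return out


# Reason codes for CDS rejection, in the order the checks are applied.
BAD_START = "BAD_START"
BAD_LENGTH = "BAD_LENGTH"
INTERNAL_STOP = "INTERNAL_STOP"
NO_TERMINAL_STOP = "NO_TERMINAL_STOP"


def classify_cds(cds: str) -> str | None:
    """Return the first violated protein-coding rule, or None if valid."""
    if len(cds) < 6 or len(cds) % 3 != 0:
        return BAD_LENGTH
    if cds[:3] not in START_CODONS:
        return BAD_START
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if any(c in STOP_CODONS for c in codons[:-1]):
        return INTERNAL_STOP
    if codons[-1] not in STOP_CODONS:
        return NO_TERMINAL_STOP
    return None


def filter_protein_coding(
    cds_records: Iterable[tuple[str, str]],
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Partition CDSs into protein-coding keepers and rejects.

    A keeper starts with ATG/CTG/GTG/TTG, has length a positive multiple of
    3, ends in a stop codon and has no internal stop.  Rejects carry one
    machine-readable reason code each (BAD_START, BAD_LENGTH, INTERNAL_STOP
    or NO_TERMINAL_STOP); rejection is a result, not an error.
    """
    kept: list[tuple[str, str]] = []
    rejected: list[tuple[str, str]] = []
    for gid, seq in cds_records:
        seq = _normalize(seq)
        reason = classify_cds(seq)
        if reason is None:
            kept.append((gid, seq))
        else:
            rejected.append((gid, reason))
    return kept, rejected


def translate_cds(cds: str) -> str:
    """Translate a filtered CDS with the bacterial genetic code.

    The initiator codon becomes Met whatever its identity (ATG/GTG/TTG/CTG
    all initiate with fMet in bacteria); the terminal stop is dropped, so the
    protein has len(cds)/3 - 1 residues.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    aa = str(Seq(cds).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise ValueError("internal stop codon in CDS")
    return "M" + aa[1:] if aa else aa


def assemble_records(
    cds_records: Iterable[tuple[str, str]],
    operon_table: dict[str, tuple[str, int, str]] | None = None,
) -> tuple[list[GeneRecord], list[tuple[str, str]]]:
    """Filter CDSs and join them with operon/UTR annotation.

    Genes absent from the operon table are retained as single-gene operons
    with an empty UTR; UTR-dependent features are flagged missing downstream
    rather than the gene being discarded here.
    """
    kept, rejected = filter_protein_coding(cds_records)
    operon_table = operon_table or {}
    records = []
    for gid, cds in kept:
        operon_id, pos, utr5 = operon_table.get(gid, (gid, 1, ""))
        records.append(
            GeneRecord(
                gene_id=gid,
                utr5=utr5,
                cds=cds,
                protein=translate_cds(cds),
                operon_id=operon_id,
                position_in_operon=pos,
            )
        )
    return records, rejected


def write_rejection_report(
    rejected: Iterable[tuple[str, str]], path: str | Path
) -> None:
    """Write the (gene_id, reason) rejection report as TSV."""
    with open(path, "w") as fh:
        fh.write("gene_id\treason\n")
        for gid, reason in rejected:
            fh.write(f"{gid}\t{reason}\n")
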