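"""Sequence records, FASTA I/O and translation-based pseudogene screening.

COI is a protein-coding mitochondrial gene, so a genuine amplicon translates
without internal stop codons in some reading frame.  Nuclear copies (NUMTs)
and other pseudogenes accumulate frameshifts and premature stops, which makes
the putative translated protein an effective quality filter: a query passes
when at least one examined frame is free of internal stops under the
vertebrate mitochondrial genetic code.

Two FASTA header dialects are understood, matching the synthetic-data writer:

* queries:    ``>queryID|station``
* references: ``>refID|Order|Family|Genus|Species``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .taxonomy import Lineage

#: NCBI translation table of the vertebrate mitochondrial code.
VERTEBRATE_MITO_TABLE = 2

_VALID_NT = set("ACGTN")


@dataclass
class QueryRecord:
    """One query sequence, optionally tagged with its sampling station."""

    id: str
    sequence: str
    station: Optional[str] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_NT
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)}"
            )


@dataclass
class ReferenceRecord:
    """One reference sequence with its full taxonomic lineage."""

    id: str
    sequence: str
    lineage: Lineage

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")


Record = Union[QueryRecord, ReferenceRecord]


def _first_content_line(path: Path) -> tuple[int, str]:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.strip():
                return i, line
    return 0, ""


def read_fasta(path, dialect: str = "auto") -> list[Record]:
    """Read a FASTA file into query or reference records.

    ``dialect`` is ``"query"``, ``"reference"``, ``"plain"`` or ``"auto"``
    (sniffed from the number of ``|``-separated header fields).  Raises on a
    file whose first content line is not a header (with its line number) and
    on duplicate ids.
    """
    path = Path(path)
    lineno, line = _first_content_line(path)
    if lineno == 0:
        return []
    if not line.startswith(">"):
        raise ValueError(f"{path}:{lineno}: sequence data before first '>' header")
    records: list[Record] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split("|")
        rid = fields[0].strip()
        if rid in seen:
            raise ValueError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        seq = str(rec.seq)
        kind = dialect
        if kind == "auto":
            kind = {5: "reference", 2: "query"}.get(len(fields), "plain")
        if kind == "reference":
            if len(fields) != 5:
                raise ValueError(
                    f"{path}: header {rec.description!r} is not refID|Order|Family|Genus|Species"
                )
            records.append(
                ReferenceRecord(rid, seq, Lineage(*(f.strip() for f in fields[1:])))
            )
        elif kind == "query":
            station = fields[1].strip() if len(fields) > 1 else None
            records.append(QueryRecord(rid, seq, station=station))
        else:
            records.append(QueryRecord(rid, seq))
    return records


def write_fasta(records: Iterable[Record], path) -> None:
    """Write records using the header dialect matching each record type."""
    out = []
    for rec in records:
        if isinstance(rec, ReferenceRecord):
            desc = "|".join((rec.id, *rec.lineage))
        elif rec.station is not None:
            desc = f"{rec.id}|{rec.station}"
        else:
            desc = rec.id
        out.append(SeqRecord(Seq(rec.sequence), id=desc, description=""))
    SeqIO.write(out, str(path), "fasta")


def translate(seq: str, frame: int = 0, code: int = VERTEBRATE_MITO_TABLE) -> str:
    """Translate ``seq`` in reading frame 0, 1 or 2.

    The trailing partial codon is dropped; stop codons render as ``*`` and
    codons containing N render as ``X``.  Default genetic code is the
    vertebrate mitochondrial table (TGA=W, ATA=M, AGA/AGG=stop).
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    sub = seq.upper()[frame:]
    if len(sub) < 3:
        raise ValueError("fewer than 3 nucleotides after the frame offset")
    sub = sub[: len(sub) - len(sub) % 3]
    return str(Seq(sub).translate(table=code))


@dataclass
class PseudogeneReport:
    """Per-frame internal-stop counts and the resulting pass/fail verdict."""

    query_id: str
    #: frame label (+1..+3, -1..-3) -> number of internal stop codons
    stop_counts: dict[str, int] = field(default_factory=dict)
    passing_frame: Optional[str] = None

    @property
    def verdict(self) -> str:
        return "pass" if self.passing_frame is not None else "fail"

    @property
    def passed(self) -> bool:
        return self.passing_frame is not None


def _internal_stops(protein: str) -> int:
    # a stop in the final translated residue is not "internal"
    return protein[:-1].count("*")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def screen_pseudogene(
    record: QueryRecord,
    check_reverse: bool = False,
    code: int = VERTEBRATE_MITO_TABLE,
) -> PseudogeneReport:
    """Screen one query for pseudogene signatures by translation.

    Examines the three forward frames (labelled +1, +2, +3), and the three
    reverse-complement frames (-1, -2, -3) when ``check_reverse`` is set.
    The verdict is pass iff at least one examined frame has zero internal
    stops; ``passing_frame`` is the first such frame in label order.
    Trailing Ns carry no signal and are stripped first, so the verdict does
    not depend on uninformative padding.
    """
    seq = record.sequence.rstrip("N")
    if len(seq) < 6:
        raise ValueError(
            f"record {record.id!r}: sequence of {len(seq)} nt is too short to screen"
        )
    frames = [(f"+{f + 1}", seq, f) for f in range(3)]
    if check_reverse:
        rc = seq.translate(_COMPLEMENT)[::-1]
        frames += [(f"-{f + 1}", rc, f) for f in range(3)]
    report = PseudogeneReport(query_id=record.id)
    for label, s, offset in frames:
        stops = _internal_stops(translate(s, frame=offset, code=code))
        report.stop_counts[label] = stops
        if stops == 0 and report.passing_frame is None:
            report.passing_frame = label
    return report


@dataclass(frozen=True)
class LengthStats:
    n: int
    mean: Optional[float]
    min: Optional[int]
    max: Optional[int]


def length_stats(records: Sequence[Record]) -> LengthStats:
    """Count/mean/min/max of sequence lengths; mean is None for no records."""
    lengths = [len(r.sequence) for r in records]
    if not lengths:
        return LengthStats(0, None, None, None)
    return LengthStats(len(lengths), sum(lengths) / len(lengths), min(lengths), max(lengths))


def qc_report(
    records: Sequence[QueryRecord], check_reverse: bool = False
) -> tuple[pd.DataFrame, list[QueryRecord], list[QueryRecord]]:
    """Screen every query; return (report table, passing, flagged).

    No record is dropped: ``len(records) == len(passing) + len(flagged)``.
    """
    rows = []
    passing: list[QueryRecord] = []
    flagged: list[QueryRecord] = []
    for rec in records:
        rep = screen_pseudogene(rec, check_reverse=check_reverse)
        rows.append(
            {
                "query_id": rec.id,
                "length": len(rec.sequence),
                "frame_stop_counts": ";".join(
                    f"{k}:{v}" for k, v in rep.stop_counts.items()
                ),
                "verdict": rep.verdict,
            }
        )
        (passing if rep.passed else flagged).append(rec)
    table = pd.DataFrame(
        rows, columns=["query_id", "length", "frame_stop_counts", "verdict"]
    )
    return table, passing, flagged
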