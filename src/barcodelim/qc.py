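"""Pseudogene/quality screening of barcode alignments.

COI is a protein-coding mitochondrial gene: a genuine barcode read in the
correct frame contains no stop codons, and the amplicon has a fixed expected
length.  Records failing either check are flagged (and, in the pipeline,
excluded with a warning rather than aborting the run, mirroring survey
practice of dropping poor-quality sequences).

Translation uses the vertebrate mitochondrial genetic code, under which the
stop codons are TAA, TAG, AGA and AGG (the standard code would miscall
AGA/AGG in fishes).  Codons containing gaps, N or any ambiguity code are
skipped, not counted as stops.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import QCError
from .records import BarcodeAlignment

logger = logging.getLogger(__name__)

#: Stop codons of the vertebrate mitochondrial genetic code.
MITO_STOP_CODONS = frozenset({"TAA", "TAG", "AGA", "AGG"})

EXPECTED_AMPLICON_LENGTH = 626


def count_stops(seq: str, frame: int) -> int:
    """Number of stop codons among complete codons of ``seq`` in ``frame``.

    ``seq`` must already be gap-free.  Codons with any non-ACGT character are
    skipped.
    """
    stops = 0
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if any(c not in "ACGT" for c in codon):
            continue
        if codon in MITO_STOP_CODONS:
            stops += 1
    return stops


def best_reading_frame(seq: str) -> tuple[int, int]:
    """Reading frame of the gap-stripped sequence with the fewest stops.

    Returns ``(frame, n_stops)``; ties resolve to the lowest frame index.
    """
    stripped = seq.upper().replace("-", "")
    if len(stripped) < 3:
        raise QCError("sequence shorter than one codon after gap removal")
    stops = [count_stops(stripped, f) for f in range(3)]
    best = min(range(3), key=lambda f: (stops[f], f))
    return best, stops[best]


@dataclass
class QCRecord:
    id: str
    best_frame: int
    n_stop_codons: int
    n_ambiguous: int
    length_ok: bool

    @property
    def passed(self) -> bool:
        return self.n_stop_codons == 0 and self.length_ok


@dataclass
class QCReport:
    records: list[QCRecord]
    expected_length: int

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.records)

    @property
    def failing_ids(self) -> list[str]:
        return [r.id for r in self.records if not r.passed]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "best_frame": [r.best_frame for r in self.records],
                "n_stop_codons": [r.n_stop_codons for r in self.records],
                "n_ambiguous": [r.n_ambiguous for r in self.records],
                "length_ok": [r.length_ok for r in self.records],
                "pass": [r.passed for r in self.records],
            }
        )
        summary = pd.DataFrame(
            [
                {
                    "id": "__dataset__",
                    "best_frame": "",
                    "n_stop_codons": sum(r.n_stop_codons for r in self.records),
                    "n_ambiguous": sum(r.n_ambiguous for r in self.records),
                    "length_ok": all(r.length_ok for r in self.records),
                    "pass": self.passed,
                }
            ]
        )
        return pd.concat([frame, summary], ignore_index=True)


def _count_ambiguous(seq: str) -> int:
    """Ambiguity codes plus internal gaps (leading/trailing gaps are padding)."""
    core = seq.strip("-")
    return sum(1 for c in core if c not in "ACGT")


def qc_alignment(
    aln: BarcodeAlignment, expected_length: int = EXPECTED_AMPLICON_LENGTH
) -> QCReport:
    """Screen every record for stop codons, ambiguity content and length.

    A record passes iff its best reading frame contains no stop codons and
    the alignment length matches ``expected_length``; the dataset passes iff
    every record does.
    """
    length_ok = aln.length == expected_length
    records = []
    for rec in aln:
        frame, n_stops = best_reading_frame(rec.seq)
        entry = QCRecord(
            id=rec.id,
            best_frame=frame,
            n_stop_codons=n_stops,
            n_ambiguous=_count_ambiguous(rec.seq),
            length_ok=length_ok,
        )
        if not entry.passed:
            logger.warning(
                "QC failure for %s: %d stop codon(s), length_ok=%s",
                rec.id,
                n_stops,
                length_ok,
            )
        records.append(entry)
    return QCReport(records=records, expected_length=expected_length)
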