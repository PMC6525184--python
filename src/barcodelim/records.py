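"""Core containers: aligned barcode sequences with taxonomy, and distance matrices.

A dataset is an aligned set of COI barcode sequences in which every record
carries a full Linnean path (species, genus, family, order, class).  Distances
between records are stored as proportions (substitutions per site); rendering
as percent happens only at the reporting edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, DistanceError

# IUPAC nucleotide one-letter codes plus the alignment gap.
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")

#: Encoding used throughout: unambiguous bases get codes 0-3 such that the two
#: purines (A, G) share the high bit pattern 0x, and the two pyrimidines (C, T)
#: share 1x -- a substitution is a transition iff the codes differ but agree
#: after a right shift.  Everything ambiguous maps to 255.
BASE_CODES = {"A": 0, "G": 1, "C": 2, "T": 3}


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned barcode sequence with its taxonomic assignment."""

    id: str
    species: str
    genus: str
    family: str
    order: str
    class_rank: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq.upper()) - IUPAC_CHARS
        if bad:
            raise AlignmentError(
                f"record {self.id!r}: illegal sequence characters {sorted(bad)}"
            )
        object.__setattr__(self, "seq", self.seq.upper())


class BarcodeAlignment:
    """An ordered, uniform-length set of :class:`SequenceRecord`.

    Parameters
    ----------
    records:
        At least one record; all sequences must have identical length.
    """

    def __init__(self, records: list[SequenceRecord]):
        if not records:
            raise AlignmentError("alignment must contain at least one record")
        lengths = {len(r.seq) for r in records}
        if len(lengths) != 1:
            ref = len(records[0].seq)
            offenders = [r.id for r in records if len(r.seq) != ref]
            raise AlignmentError(
                f"unequal sequence lengths (expected {ref}): offending ids {offenders}"
            )
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate record ids: {dupes}")
        self.records: list[SequenceRecord] = list(records)
        self.length: int = lengths.pop()
        self._by_id = {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, rec_id: str) -> SequenceRecord:
        return self._by_id[rec_id]

    def __eq__(self, other) -> bool:
        if not isinstance(other, BarcodeAlignment):
            return NotImplemented
        return self.records == other.records

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def taxonomy_frame(self) -> pd.DataFrame:
        """Taxonomy of all records as a DataFrame indexed by id."""
        return pd.DataFrame(
            {
                "species": [r.species for r in self.records],
                "genus": [r.genus for r in self.records],
                "family": [r.family for r in self.records],
                "order": [r.order for r in self.records],
                "class": [r.class_rank for r in self.records],
            },
            index=pd.Index(self.ids, name="id"),
        )

    def encoded(self) -> np.ndarray:
        """(n, length) uint8 matrix; A/G/C/T -> 0/1/2/3, anything else 255."""
        table = np.full(256, 255, dtype=np.uint8)
        for base, code in BASE_CODES.items():
            table[ord(base)] = code
        raw = np.frombuffer(
            "".join(r.seq for r in self.records).encode("ascii"), dtype=np.uint8
        )
        return table[raw].reshape(len(self.records), self.length)

    def subset(self, keep_ids: list[str]) -> "BarcodeAlignment":
        """New alignment restricted to ``keep_ids`` (original order preserved)."""
        keep = set(keep_ids)
        return BarcodeAlignment([r for r in self.records if r.id in keep])


@dataclass
class DistanceMatrix:
    """Symmetric pairwise genetic distances over a fixed label order.

    ``values`` holds proportions; entries for pairs where the distance formula
    is not evaluable (log-domain violation or no comparable sites) are NaN and
    the pair is listed in ``undefined_pairs``.
    """

    labels: list[str]
    values: np.ndarray
    model: str  # "K2P" or "P_DIST"
    undefined_pairs: set[frozenset] = field(default_factory=set)

    def __post_init__(self) -> None:
        n = len(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise DistanceError(
                f"values shape {self.values.shape} does not match {n} labels"
            )
        if self.model not in ("K2P", "P_DIST"):
            raise DistanceError(f"unknown distance model {self.model!r}")
        finite = ~np.isnan(self.values)
        if not np.allclose(
            self.values[finite], self.values.T[finite], rtol=0, atol=1e-12
        ):
            raise DistanceError("distance matrix is not symmetric")
        if np.any(np.diagonal(self.values) != 0):
            raise DistanceError("distance matrix diagonal must be exactly 0")
        if np.any(self.values[finite] < 0):
            raise DistanceError("negative distances are not allowed")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        """Distance between two labels (NaN if undefined)."""
        return float(self.values[self._index[a], self._index[b]])

    def is_defined(self, a: str, b: str) -> bool:
        return frozenset((a, b)) not in self.undefined_pairs if a != b else True

    @property
    def has_undefined(self) -> bool:
        return bool(self.undefined_pairs)

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self._index[lab] for lab in labels]
        sub = self.values[np.ix_(idx, idx)]
        keep = set(labels)
        undef = {p for p in self.undefined_pairs if p <= keep}
        return DistanceMatrix(list(labels), sub.copy(), self.model, undef)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def pair_distances(self) -> list[tuple[float, str, str]]:
        """All strict upper-triangle entries as (distance, label_a, label_b)."""
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                out.append((float(self.values[i, j]), self.labels[i], self.labels[j]))
        return out
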