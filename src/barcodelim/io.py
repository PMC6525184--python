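"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
* FASTA for sequences (via Biopython), with taxonomy in a separate six-column
  TSV (``id  species  genus  family  order  class``, header required).  BOLD
  exports and museum tables are tabular, so taxonomy is never packed into
  FASTA headers.
* MEGA distance format (``#mega`` header, lower-left triangle, 6 decimals),
  the layout consumed by the ABGD web interface.
* Newick trees with branch lengths and integer bootstrap supports as internal
  node labels.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .errors import FormatError, TaxonomyError
from .records import IUPAC_CHARS, BarcodeAlignment, DistanceMatrix, SequenceRecord

TAXONOMY_COLUMNS = ["id", "species", "genus", "family", "order", "class"]

_NEWICK_RESERVED = set("(),:;")


def _bad_char_line(path, rec_id: str, seq: str) -> int:
    """Line number (1-based) of the first illegal character of a record."""
    bad_pos = next(
        i for i, c in enumerate(seq.upper()) if c not in IUPAC_CHARS
    )
    with open(path) as fh:
        in_rec = False
        seen = 0
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                in_rec = line[1:].split()[0] == rec_id if line[1:].strip() else False
                continue
            if in_rec:
                chunk = len(line.strip())
                if seen + chunk > bad_pos:
                    return lineno
                seen += chunk
    return -1  # pragma: no cover - record always found


def read_taxonomy(path) -> pd.DataFrame:
    """Read the six-column taxonomy TSV, indexed by id."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TAXONOMY_COLUMNS if c not in table.columns]
    if missing:
        raise TaxonomyError(f"taxonomy table {path} lacks columns {missing}")
    if table["id"].duplicated().any():
        dupes = sorted(table.loc[table["id"].duplicated(), "id"])
        raise TaxonomyError(f"duplicate ids in taxonomy table: {dupes}")
    return table.set_index("id")


def write_taxonomy(alignment: BarcodeAlignment, path) -> None:
    frame = alignment.taxonomy_frame().reset_index()
    frame.to_csv(path, sep="\t", index=False)


def read_fasta(path, taxonomy_path) -> BarcodeAlignment:
    """Load an aligned FASTA plus its taxonomy TSV into a BarcodeAlignment.

    Record order follows the FASTA file.  Every FASTA id must be present in
    the taxonomy table; sequences must be of equal length and contain only
    IUPAC nucleotide codes or gaps.
    """
    taxonomy = read_taxonomy(taxonomy_path)
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq)
        bad = set(seq.upper()) - IUPAC_CHARS
        if bad:
            line = _bad_char_line(path, entry.id, seq)
            raise FormatError(
                f"{path}: illegal character(s) {sorted(bad)} in record "
                f"{entry.id!r} at line {line}"
            )
        if entry.id not in taxonomy.index:
            raise TaxonomyError(
                f"record {entry.id!r} missing from taxonomy table {taxonomy_path}"
            )
        row = taxonomy.loc[entry.id]
        records.append(
            SequenceRecord(
                id=entry.id,
                species=row["species"],
                genus=row["genus"],
                family=row["family"],
                order=row["order"],
                class_rank=row["class"],
                seq=seq,
            )
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return BarcodeAlignment(records)


def write_fasta(alignment: BarcodeAlignment, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in alignment:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# MEGA distance dialect
# ---------------------------------------------------------------------------

def write_mega_distance(dmat: DistanceMatrix, path, title: str = "barcodelim distances") -> None:
    """Write a lower-left MEGA distance file at 6-decimal precision.

    The dialect has no missing-value convention, so matrices with undefined
    pairs are refused.
    """
    if dmat.undefined_pairs:
        pairs = sorted(tuple(sorted(p)) for p in dmat.undefined_pairs)
        raise FormatError(
            f"cannot write MEGA file: undefined distance pairs {pairs}"
        )
    with open(path, "w") as fh:
        fh.write("#mega\n")
        fh.write(f"!Title {title};\n")
        fh.write(
            f"!Format DataType=Distance DataFormat=LowerLeft NTaxa={dmat.n};\n\n"
        )
        for label in dmat.labels:
            fh.write(f"#{label}\n")
        fh.write("\n")
        for i in range(1, dmat.n):
            row = " ".join(f"{dmat.values[i, j]:.6f}" for j in range(i))
            fh.write(row + "\n")


def read_mega_distance(path, model: str = "K2P") -> DistanceMatrix:
    """Invert :func:`write_mega_distance` exactly at 6-decimal precision."""
    import numpy as np

    text = Path(path).read_text()
    if not text.lstrip().lower().startswith("#mega"):
        raise FormatError(f"{path}: missing '#mega' header")
    m = re.search(r"NTaxa\s*=\s*(\d+)", text, flags=re.IGNORECASE)
    if not m:
        raise FormatError(f"{path}: missing NTaxa declaration")
    n = int(m.group(1))
    lines = [ln.strip() for ln in text.splitlines()]
    labels = [ln[1:].strip() for ln in lines if ln.startswith("#") and ln.lower() != "#mega"]
    if len(labels) != n:
        raise FormatError(f"{path}: found {len(labels)} taxon labels, expected {n}")
    numeric = []
    for ln in lines:
        if not ln or ln.startswith(("#", "!")):
            continue
        numeric.extend(float(tok) for tok in ln.split())
    expected = n * (n - 1) // 2
    if len(numeric) != expected:
        raise FormatError(
            f"{path}: triangle has {len(numeric)} values, expected {expected}"
        )
    values = np.zeros((n, n))
    k = 0
    for i in range(1, n):
        for j in range(i):
            values[i, j] = values[j, i] = numeric[k]
            k += 1
    return DistanceMatrix(labels, values, model)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def _newick_node(node) -> str:
    if node.is_leaf():
        if any(c in _NEWICK_RESERVED or c.isspace() for c in node.label):
            raise FormatError(
                f"leaf label {node.label!r} contains Newick-reserved characters"
            )
        name = node.label
    else:
        inner = ",".join(_newick_node(c) for c in node.children)
        support = "" if node.support is None else str(int(node.support))
        name = f"({inner}){support}"
    if node.length is None:
        return name
    return f"{name}:{node.length:.6f}"


def write_newick(tree, path) -> None:
    """Serialize a tree to Newick; supports become internal node labels.

    Leaf labels containing any of ``( ) , : ;`` are rejected.
    """
    root = tree.root
    inner = ",".join(_newick_node(c) for c in root.children)
    with open(path, "w") as fh:
        fh.write(f"({inner});\n")
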