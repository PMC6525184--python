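"""Hierarchical synthetic barcode datasets under the K80 substitution model.

The generator emulates the statistical structure a COI barcode survey
assumes: a nested family/genus/species hierarchy in which each level is a
star tree with a fixed stem depth, so intra- and interspecific divergence
bands are under direct analytic control.  Sequences evolve site-wise under
K80 (equal base frequencies, transition/transversion rate ratio ``kappa``),
with codon-aware rejection sampling so that no lineage ever carries an
in-frame stop codon of the vertebrate mitochondrial code -- synthetic
datasets therefore pass the QC screen by construction.

Divergence scale: a stem of depth ``t`` contributes ``t`` expected
substitutions per site, so two individuals of one species are separated by
``2 * intra_depth`` in expectation, two species of one genus by roughly
``2 * (species_depth + intra_depth)``, and so on.

An optional cryptic split plants two lineages inside one nominal species
(the deep-conspecific situation that breaks the barcode gap), separated by
``2 * split_depth`` at the lineage ancestors.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_fasta, write_taxonomy
from .qc import MITO_STOP_CODONS
from .records import BarcodeAlignment, SequenceRecord
from .tree import Node, Tree

_BASES = "AGCT"  # index == internal code
_CODE = {b: i for i, b in enumerate(_BASES)}
_NONSTOP_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in MITO_STOP_CODONS
]


@dataclass(frozen=True)
class CrypticSplit:
    """Plant two lineages inside one nominal species."""

    target_species: int = 0  # index into the generated species list
    split_depth: float = 0.006


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the synthetic barcode generator.

    Depths are expected substitutions per site along the corresponding stem;
    they must increase from individual to genus level.  ``seqs_per_species``
    is either a fixed integer or an inclusive (low, high) range sampled
    uniformly per species (surveys typically hold 1-8 specimens per species).
    """

    n_families: int = 5
    genera_per_family: int = 2
    species_per_genus: int = 2
    seqs_per_species: int | tuple[int, int] = 5
    length: int = 626
    kappa: float = 4.0
    intra_depth: float = 0.003
    species_depth: float = 0.03
    genus_depth: float = 0.08
    family_depth: float = 0.06
    seed: int = 0
    cryptic_split: CrypticSplit | None = None

    def __post_init__(self):
        for name in ("n_families", "genera_per_family", "species_per_genus"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if isinstance(self.seqs_per_species, tuple):
            lo, hi = self.seqs_per_species
            if not (1 <= lo <= hi):
                raise ValueError("seqs_per_species range must satisfy 1 <= lo <= hi")
        elif self.seqs_per_species < 1:
            raise ValueError("seqs_per_species must be >= 1")
        if self.length < 3:
            raise ValueError("length must cover at least one codon")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not (0 <= self.intra_depth < self.species_depth < self.genus_depth):
            raise ValueError(
                "depths must satisfy intra_depth < species_depth < genus_depth"
            )
        if self.cryptic_split is not None:
            n_species = (
                self.n_families * self.genera_per_family * self.species_per_genus
            )
            if not (0 <= self.cryptic_split.target_species < n_species):
                raise ValueError("cryptic_split.target_species out of range")

    @property
    def n_species(self) -> int:
        return self.n_families * self.genera_per_family * self.species_per_genus

    @classmethod
    def survey_scale(cls, seed: int = 0) -> "SimConfig":
        """A survey-sized preset: 100 species, 1-8 specimens each.

        Mirrors the shape of a delta-wide COI inventory (~400 sequences of
        626 bp over a nested hierarchy) including one cryptic split.
        """
        return cls(
            n_families=25,
            genera_per_family=2,
            species_per_genus=2,
            seqs_per_species=(1, 8),
            seed=seed,
            cryptic_split=CrypticSplit(target_species=0),
        )


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset."""

    taxonomy: pd.DataFrame  # indexed by id: species, genus, family, order, class
    tree: Tree  # true tree, branch lengths in expected subs/site
    lineages: dict[str, int] = field(default_factory=dict)  # cryptic-split sides

    @property
    def n_species(self) -> int:
        return self.taxonomy["species"].nunique()

    def species_partition(self) -> dict[str, int]:
        species = sorted(self.taxonomy["species"].unique())
        index = {sp: i for i, sp in enumerate(species)}
        return {rid: index[sp] for rid, sp in self.taxonomy["species"].items()}

    def to_json(self, path) -> None:
        payload = {
            "taxonomy": self.taxonomy.reset_index().to_dict(orient="records"),
            "lineages": self.lineages,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Taxonomy / true-tree skeleton
# ---------------------------------------------------------------------------

def simulate_taxonomy(config: SimConfig, rng: np.random.Generator) -> TruthTable:
    """Balanced nested hierarchy plus its star-shaped true tree.

    Genus stems hang below family roots at depth ``genus_depth``, species at
    ``species_depth`` below their genus, individuals at ``intra_depth`` below
    their species; family roots join the global root at ``family_depth``.
    """
    rows = []
    lineages: dict[str, int] = {}
    root = Node()
    species_counter = 0
    genus_counter = 0
    for fam_i in range(config.n_families):
        family = f"Fam{fam_i + 1:02d}"
        order = f"Ord{fam_i % 4 + 1:02d}"
        fam_node = Node(length=config.family_depth)
        root.children.append(fam_node)
        for _ in range(config.genera_per_family):
            genus_counter += 1
            genus = f"Gen{genus_counter:03d}"
            gen_node = Node(length=config.genus_depth)
            fam_node.children.append(gen_node)
            for _ in range(config.species_per_genus):
                species_counter += 1
                species = f"Sp{species_counter:03d}"
                sp_node = Node(length=config.species_depth)
                gen_node.children.append(sp_node)
                if isinstance(config.seqs_per_species, tuple):
                    lo, hi = config.seqs_per_species
                    n_seqs = int(rng.integers(lo, hi + 1))
                else:
                    n_seqs = config.seqs_per_species
                is_split = (
                    config.cryptic_split is not None
                    and species_counter - 1 == config.cryptic_split.target_species
                    and n_seqs >= 2
                )
                if is_split:
                    sides = [
                        Node(length=config.cryptic_split.split_depth),
                        Node(length=config.cryptic_split.split_depth),
                    ]
                    sp_node.children.extend(sides)
                for k in range(n_seqs):
                    rec_id = f"{species}_{k + 1}"
                    leaf = Node(label=rec_id, length=config.intra_depth)
                    if is_split:
                        side = k % 2
                        sides[side].children.append(leaf)
                        lineages[rec_id] = side
                    else:
                        sp_node.children.append(leaf)
                    rows.append(
                        {
                            "id": rec_id,
                            "species": species,
                            "genus": genus,
                            "family": family,
                            "order": order,
                            "class": "Actinopterygii",
                        }
                    )
    taxonomy = pd.DataFrame(rows).set_index("id")
    return TruthTable(taxonomy=taxonomy, tree=Tree(root), lineages=lineages)


# ---------------------------------------------------------------------------
# K80 sequence evolution
# ---------------------------------------------------------------------------

def k80_transition_matrix(t: float, kappa: float) -> np.ndarray:
    """4x4 substitution probability matrix at divergence ``t`` (A/G/C/T order).

    Rates are normalized so that ``t`` is the expected number of
    substitutions per site.
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e_tv = np.exp(-4.0 * beta * t)
    e_ts = np.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e_tv + 0.5 * e_ts
    p_ts = 0.25 + 0.25 * e_tv - 0.5 * e_ts
    p_tv = 0.25 - 0.25 * e_tv
    m = np.full((4, 4), p_tv)
    for i, j in ((0, 1), (1, 0), (2, 3), (3, 2)):  # A<->G, C<->T
        m[i, j] = p_ts
    np.fill_diagonal(m, p_same)
    return m


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.int64)


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def _stop_codon_positions(codes: np.ndarray) -> np.ndarray:
    """Start indices of complete in-frame (frame 0) stop codons."""
    n_codons = codes.size // 3
    if n_codons == 0:
        return np.empty(0, dtype=np.int64)
    codons = codes[: n_codons * 3].reshape(n_codons, 3)
    strings = ["".join(_BASES[c] for c in row) for row in codons]
    return np.array(
        [3 * i for i, s in enumerate(strings) if s in MITO_STOP_CODONS],
        dtype=np.int64,
    )


def evolve_sequence(
    parent_seq: str, t: float, kappa: float, rng: np.random.Generator
) -> str:
    """Evolve a sequence for ``t`` expected substitutions/site under K80.

    Any draw that would create an in-frame stop codon (frame 0, vertebrate
    mitochondrial code) is redrawn for that codon, preserving the open
    reading frame of the parent.
    """
    if t < 0:
        raise ValueError("branch length t must be non-negative")
    parent = _encode(parent_seq.upper())
    if t == 0:
        return parent_seq.upper()
    cum = np.cumsum(k80_transition_matrix(t, kappa), axis=1)
    child = _draw(parent, cum, rng)
    for _ in range(1000):
        stops = _stop_codon_positions(child)
        if stops.size == 0:
            break
        redo = np.concatenate([stops, stops + 1, stops + 2])
        child[redo] = _draw(parent[redo], cum, rng)
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("codon rejection sampling failed to converge")
    return _decode(child)


def _draw(parent: np.ndarray, cum: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(parent.size)
    return (u[:, None] > cum[parent]).sum(axis=1)


def random_orf_sequence(length: int, rng: np.random.Generator) -> str:
    """Random stop-free sequence (frame 0) of the requested length."""
    n_codons = -(-length // 3)
    picks = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons)
    return "".join(_NONSTOP_CODONS[i] for i in picks)[:length]


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def simulate_dataset(
    config: SimConfig, outdir=None
) -> tuple[BarcodeAlignment, pd.DataFrame, TruthTable]:
    """Simulate a full barcode dataset; optionally write FASTA/TSV/truth JSON.

    Deterministic per ``config.seed``: taxonomy sampling, the root sequence
    and sequence evolution each consume a named substream of one root seed.
    """
    rng_tax = np.random.default_rng([config.seed, 101])
    rng_root = np.random.default_rng([config.seed, 211])
    rng_evol = np.random.default_rng([config.seed, 307])

    truth = simulate_taxonomy(config, rng_tax)
    root_seq = random_orf_sequence(config.length, rng_root)

    seqs: dict[str, str] = {}

    def walk(node: Node, seq: str):
        for child in node.children:
            child_seq = evolve_sequence(seq, child.length, config.kappa, rng_evol)
            if child.is_leaf():
                seqs[child.label] = child_seq
            else:
                walk(child, child_seq)

    walk(truth.tree.root, root_seq)

    records = [
        SequenceRecord(
            id=rec_id,
            species=row["species"],
            genus=row["genus"],
            family=row["family"],
            order=row["order"],
            class_rank=row["class"],
            seq=seqs[rec_id],
        )
        for rec_id, row in truth.taxonomy.iterrows()
    ]
    alignment = BarcodeAlignment(records)
    taxonomy = alignment.taxonomy_frame()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(alignment, outdir / "sequences.fasta")
        write_taxonomy(alignment, outdir / "taxonomy.tsv")
        truth.to_json(outdir / "truth.json")
    return alignment, taxonomy, truth
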