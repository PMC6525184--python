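"""Pairwise genetic distances and divergence summaries.

Implements the two distance models used for barcode delimitation:

* Kimura two-parameter (K2P): ``d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]``
  where P and Q are the observed transition and transversion proportions.
* Uncorrected p-distance: ``p = (ts + tv) / n``.

Sites are compared under pairwise deletion: a site contributes to a pair only
if both sequences carry an unambiguous A/C/G/T there.  Ambiguity codes, N and
gaps are treated as missing at that site.  When the K2P logarithm leaves its
domain (saturation) the pair is recorded as undefined rather than NaN-poisoned.

On top of the matrices sit the rank-wise divergence summary (conspecific /
congeneric / confamilial min-mean-max-SE table) and the barcode-gap report
(per-species maximum intraspecific distance against the nearest-neighbor
interspecific distance).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DistanceError
from .records import BarcodeAlignment, DistanceMatrix

logger = logging.getLogger(__name__)

RANK_LEVELS = ("within_species", "within_genus", "within_family")


@dataclass(frozen=True)
class SitePatternCount:
    """Transition/transversion/comparable-site counts for one sequence pair."""

    n_transitions: int
    n_transversions: int
    n_compared: int

    def __post_init__(self):
        if self.n_transitions + self.n_transversions > self.n_compared:
            raise DistanceError("substitution counts exceed compared sites")


def count_site_patterns(seq_a: str, seq_b: str) -> SitePatternCount:
    """Classify aligned sites of a pair under pairwise deletion.

    Transitions are A<->G and C<->T; every other substitution between
    unambiguous bases is a transversion.
    """
    if len(seq_a) != len(seq_b):
        raise DistanceError("sequences must have equal length")
    ts = tv = n = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if {x, y} in ({"A", "G"}, {"C", "T"}):
            ts += 1
        else:
            tv += 1
    return SitePatternCount(ts, tv, n)


def k2p_distance(counts: SitePatternCount) -> float | None:
    """K2P distance from site-pattern counts; ``None`` when undefined.

    Undefined when no sites are comparable or when the observed proportions
    saturate the logarithm's domain, i.e. ``1 - 2P - Q <= 0`` or
    ``1 - 2Q <= 0``.
    """
    if counts.n_compared == 0:
        return None
    if counts.n_transitions == 0 and counts.n_transversions == 0:
        return 0.0
    p = counts.n_transitions / counts.n_compared
    q = counts.n_transversions / counts.n_compared
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return None
    return -0.5 * math.log(w1 * math.sqrt(w2))


def p_distance(counts: SitePatternCount) -> float | None:
    """Uncorrected proportion of differing sites; ``None`` if no sites compare."""
    if counts.n_compared == 0:
        return None
    return (counts.n_transitions + counts.n_transversions) / counts.n_compared


def _pattern_arrays(encoded: np.ndarray):
    """Vectorized all-pairs (ts, tv, n) over an encoded alignment.

    Codes 0-3 are A/G/C/T with purines and pyrimidines sharing the high bit,
    so a substitution is a transition iff the codes differ but match after a
    right shift; 255 marks a non-comparable state.
    """
    n_rec = encoded.shape[0]
    ts = np.zeros((n_rec, n_rec), dtype=np.int64)
    tv = np.zeros((n_rec, n_rec), dtype=np.int64)
    cmpd = np.zeros((n_rec, n_rec), dtype=np.int64)
    for i in range(n_rec - 1):
        a = encoded[i]
        rest = encoded[i + 1 :]
        valid = (a != 255) & (rest != 255)
        diff = valid & (a != rest)
        trans = diff & ((a >> 1) == (rest >> 1))
        ts_i = trans.sum(axis=1)
        tv_i = diff.sum(axis=1) - ts_i
        n_i = valid.sum(axis=1)
        ts[i, i + 1 :] = ts[i + 1 :, i] = ts_i
        tv[i, i + 1 :] = tv[i + 1 :, i] = tv_i
        cmpd[i, i + 1 :] = cmpd[i + 1 :, i] = n_i
    return ts, tv, cmpd


def distance_matrix(aln: BarcodeAlignment, model: str = "K2P") -> DistanceMatrix:
    """All-pairs distance matrix under the requested model.

    Undefined pairs (saturated K2P or zero comparable sites) are recorded in
    ``undefined_pairs`` with NaN entries, never silently zeroed.
    """
    if len(aln) < 2:
        raise DistanceError("need at least two records for a distance matrix")
    if model not in ("K2P", "P_DIST"):
        raise DistanceError(f"unknown model {model!r}")
    ts, tv, n = _pattern_arrays(aln.encoded())
    with np.errstate(divide="ignore", invalid="ignore"):
        safe_n = np.where(n == 0, 1, n)
        p = ts / safe_n
        q = tv / safe_n
        if model == "P_DIST":
            values = p + q
            bad = n == 0
        else:
            w1 = 1.0 - 2.0 * p - q
            w2 = 1.0 - 2.0 * q
            bad = (n == 0) | (w1 <= 0.0) | (w2 <= 0.0)
            values = np.where(bad, np.nan, -0.5 * np.log(
                np.where(bad, 1.0, w1) * np.sqrt(np.where(bad, 1.0, w2))
            ))
    values = np.where(bad, np.nan, values) + 0.0  # +0.0 normalizes -0.0
    np.fill_diagonal(values, 0.0)
    labels = aln.ids
    undefined = set()
    for i, j in zip(*np.nonzero(np.triu(bad, k=1))):
        undefined.add(frozenset((labels[i], labels[j])))
    if undefined:
        logger.warning("%d undefined %s pairs", len(undefined), model)
    return DistanceMatrix(labels, values, model, undefined)


# ---------------------------------------------------------------------------
# Rank-wise divergence summary (conspecific / congeneric / confamilial)
# ---------------------------------------------------------------------------

@dataclass
class DivergenceSummary:
    """Min/mean/max/SE of pairwise distance (percent) at one taxonomic level."""

    level: str
    n_pairs: int
    min: float | None
    mean: float | None
    max: float | None
    se: float | None


def _level_of(tax_a, tax_b) -> str | None:
    if tax_a["species"] == tax_b["species"]:
        return "within_species"
    if tax_a["genus"] == tax_b["genus"]:
        return "within_genus"
    if tax_a["family"] == tax_b["family"]:
        return "within_family"
    return None


def rank_divergence_summary(
    dmat: DistanceMatrix, taxonomy: pd.DataFrame
) -> list[DivergenceSummary]:
    """Divergence statistics per taxonomic level, in percent.

    Levels form disjoint pair sets: conspecific pairs share the species label;
    congeneric pairs share the genus but not the species; confamilial pairs
    share the family but not the genus.  SE is the sample standard deviation
    of the pair distances divided by sqrt(n_pairs).  Undefined pairs are
    dropped with a logged count.
    """
    buckets: dict[str, list[float]] = {lev: [] for lev in RANK_LEVELS}
    n_undef = 0
    for d, a, b in dmat.pair_distances():
        level = _level_of(taxonomy.loc[a], taxonomy.loc[b])
        if level is None:
            continue
        if math.isnan(d):
            n_undef += 1
            continue
        buckets[level].append(d * 100.0)
    if n_undef:
        logger.warning("%d undefined pairs excluded from divergence summary", n_undef)
    out = []
    for level in RANK_LEVELS:
        vals = np.asarray(buckets[level])
        if vals.size == 0:
            out.append(DivergenceSummary(level, 0, None, None, None, None))
            continue
        se = float(np.std(vals, ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
        out.append(
            DivergenceSummary(
                level,
                int(vals.size),
                float(vals.min()),
                float(vals.mean()),
                float(vals.max()),
                se,
            )
        )
    return out


def summary_frame(summaries: list[DivergenceSummary]) -> pd.DataFrame:
    """Render summaries as the four-column percent table, 2 decimals."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "level": s.level,
                "n_pairs": s.n_pairs,
                "min_divergence_pct": None if s.min is None else round(s.min, 2),
                "mean_divergence_pct": None if s.mean is None else round(s.mean, 2),
                "max_divergence_pct": None if s.max is None else round(s.max, 2),
                "se_divergence_pct": None if s.se is None else round(s.se, 2),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Barcode-gap / nearest-neighbor analysis
# ---------------------------------------------------------------------------

@dataclass
class GapRecord:
    """Per-species barcode-gap entry (distances in percent)."""

    species: str
    n_seqs: int
    max_intra: float | None  # undefined when the species has < 2 sequences
    nn_species: str
    nn_distance: float
    has_gap: bool


def barcode_gap_report(
    dmat: DistanceMatrix, taxonomy: pd.DataFrame
) -> tuple[list[GapRecord], dict]:
    """Maximum intraspecific vs minimum interspecific distance per species.

    The nearest-neighbor distance of a species is the minimum over all
    sequence pairs crossing its boundary; a species has a barcode gap iff its
    maximum intraspecific distance is defined and strictly smaller than its
    nearest-neighbor distance.  The dataset-level summary flags overlap when
    the overall minimum interspecific distance does not exceed the overall
    maximum intraspecific distance.
    """
    species_of = taxonomy["species"]
    species_list = sorted(set(species_of.loc[dmat.labels]))
    if len(species_list) < 2:
        raise DistanceError("barcode-gap analysis needs at least two species")
    intra: dict[str, list[float]] = {sp: [] for sp in species_list}
    nn: dict[str, tuple[float, str]] = {}
    counts: dict[str, int] = {
        sp: int((species_of.loc[dmat.labels] == sp).sum()) for sp in species_list
    }
    for d, a, b in dmat.pair_distances():
        if math.isnan(d):
            continue
        sp_a, sp_b = species_of.loc[a], species_of.loc[b]
        if sp_a == sp_b:
            intra[sp_a].append(d)
            continue
        for sp, other in ((sp_a, sp_b), (sp_b, sp_a)):
            best = nn.get(sp)
            cand = (d, other)
            if best is None or cand < best:
                nn[sp] = cand
    records = []
    for sp in species_list:
        max_intra = max(intra[sp]) * 100.0 if intra[sp] else None
        nn_d, nn_sp = nn[sp]
        assert nn_sp != sp, "nearest neighbor must cross the species boundary"
        nn_pct = nn_d * 100.0
        records.append(
            GapRecord(
                species=sp,
                n_seqs=counts[sp],
                max_intra=max_intra,
                nn_species=nn_sp,
                nn_distance=nn_pct,
                has_gap=max_intra is not None and nn_pct > max_intra,
            )
        )
    intra_values = [r.max_intra for r in records if r.max_intra is not None]
    overall_max_intra = max(intra_values) if intra_values else None
    overall_min_inter = min(r.nn_distance for r in records)
    summary = {
        "overall_max_intra": overall_max_intra,
        "overall_min_inter": overall_min_inter,
        "overlap": (
            overall_max_intra is not None and overall_min_inter <= overall_max_intra
        ),
    }
    return records, summary


def gap_frame(records: list[GapRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [r.species for r in records],
            "n_seqs": [r.n_seqs for r in records],
            "max_intra_pct": [r.max_intra for r in records],
            "nn_species": [r.nn_species for r in records],
            "nn_distance_pct": [r.nn_distance for r in records],
            "has_gap": [r.has_gap for r in records],
        }
    )
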