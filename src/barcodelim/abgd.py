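"""Automatic Barcode Gap Discovery (ABGD)-style partitioning.

The method ranks all pairwise distances, looks for the first statistically
conspicuous gap beyond a prior limit on intraspecific divergence, splits the
data into connected components below the implied threshold, and refines each
group recursively.  A sweep repeats this over a geometric ladder of priors.

Gap-significance rule (this package's documented operationalization; the
band-gap construction in the test suite is the correctness reference):

* Order the ``m`` pairwise distances ascending, ``g_i = d_(i+1) - d_(i)``.
* A gap is *eligible* for prior ``p`` iff its upper end exceeds ``p`` and its
  midpoint (the candidate threshold) is at least ``p`` -- distances below the
  prior are intraspecific by assumption, so a threshold below the prior would
  be meaningless.
* The local slope before gap ``i`` is the mean of the previous ``w`` gaps,
  ``w = max(3, ceil(0.1 m))``; a gap with no predecessors is never
  significant on its own.
* Gap ``i`` is the barcode gap iff ``g_i > X * slope`` and ``g_i > X * G``
  where ``G`` is the largest gap lying entirely inside the prior region and
  ``X`` is the relative gap width.  The returned threshold is the midpoint
  ``(d_(i) + d_(i+1)) / 2``; ``None`` when no gap qualifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DistanceError, PartitionError
from .records import DistanceMatrix

MAX_RECURSION_ROUNDS = 20


@dataclass(frozen=True)
class AbgdConfig:
    """Parameters of the prior sweep.

    ``p_min``/``p_max`` bound the prior maximum intraspecific divergence
    (proportions); ``n_steps`` priors are geometrically spaced between them;
    ``relative_gap_width_x`` is the sensitivity multiplier X.
    """

    p_min: float = 0.001
    p_max: float = 0.1
    n_steps: int = 10
    relative_gap_width_x: float = 1.2
    model: str = "K2P"

    def __post_init__(self):
        if not (0.0 < self.p_min < self.p_max < 1.0):
            raise ValueError(
                f"priors must satisfy 0 < p_min < p_max < 1, "
                f"got ({self.p_min}, {self.p_max})"
            )
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.relative_gap_width_x <= 0:
            raise ValueError("relative gap width X must be positive")
        if self.model not in ("K2P", "P_DIST"):
            raise ValueError(f"unknown model {self.model!r}")

    def priors(self) -> np.ndarray:
        return np.geomspace(self.p_min, self.p_max, self.n_steps)


@dataclass
class Partition:
    """One group assignment of all record ids, with provenance."""

    method: str  # ABGD_INITIAL | ABGD_RECURSIVE | NJ | THRESHOLD
    prior_p: float | None
    threshold_found: float | None
    assignment: dict[str, int]
    n_groups: int

    def __post_init__(self):
        if self.n_groups != len(set(self.assignment.values())):
            raise PartitionError("n_groups does not match distinct group indices")

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for rec_id, gid in self.assignment.items():
            out.setdefault(gid, []).append(rec_id)
        return out

    def refines(self, other: "Partition") -> bool:
        """True iff every group of self is contained in a group of other."""
        for members in self.groups().values():
            targets = {other.assignment[m] for m in members}
            if len(targets) != 1:
                return False
        return True


def relabel_groups(partition: Partition, order: list[str]) -> Partition:
    """Renumber groups consecutively from 0 by first-seen id in ``order``."""
    mapping: dict[int, int] = {}
    for rec_id in order:
        gid = partition.assignment[rec_id]
        if gid not in mapping:
            mapping[gid] = len(mapping)
    new_assignment = {rid: mapping[g] for rid, g in partition.assignment.items()}
    return Partition(
        method=partition.method,
        prior_p=partition.prior_p,
        threshold_found=partition.threshold_found,
        assignment=new_assignment,
        n_groups=len(mapping),
    )


# ---------------------------------------------------------------------------
# Ranked distances and gap detection
# ---------------------------------------------------------------------------

def ranked_distances(dmat: DistanceMatrix) -> list[tuple[float, tuple[str, str]]]:
    """All pairwise distances ascending; ties in stable label-pair order."""
    if dmat.has_undefined:
        pairs = sorted(tuple(sorted(p)) for p in dmat.undefined_pairs)
        raise DistanceError(f"undefined pairs present: {pairs[:5]}...")
    entries = [
        (d, tuple(sorted((a, b)))) for d, a, b in dmat.pair_distances()
    ]
    entries.sort(key=lambda e: (e[0], e[1]))
    return entries


def find_gap(sorted_d, prior_p: float, x: float) -> float | None:
    """First significant gap beyond the prior; returns the midpoint threshold.

    ``sorted_d`` is an ascending sequence of distances (floats, or the
    (distance, pair) tuples produced by :func:`ranked_distances`).
    """
    if len(sorted_d) and isinstance(sorted_d[0], tuple):
        d = np.asarray([e[0] for e in sorted_d], dtype=float)
    else:
        d = np.asarray(sorted_d, dtype=float)
    m = d.size
    if m < 2:
        return None
    gaps = np.diff(d)
    w = max(3, math.ceil(0.1 * m))
    prior_gaps = gaps[d[1:] <= prior_p]
    prior_max = float(prior_gaps.max()) if prior_gaps.size else 0.0
    for i in range(gaps.size):
        if d[i + 1] <= prior_p:
            continue
        midpoint = 0.5 * (d[i] + d[i + 1])
        if midpoint < prior_p:
            continue
        window = gaps[max(0, i - w) : i]
        if window.size == 0:
            continue  # no local slope to compare against
        slope = float(window.mean())
        g = float(gaps[i])
        if g > x * slope and g > x * prior_max:
            return midpoint
    return None


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def partition_at_threshold(dmat: DistanceMatrix, threshold: float) -> Partition:
    """Connected components of the graph joining pairs with d < threshold."""
    if threshold < 0:
        raise PartitionError("threshold must be non-negative")
    n = dmat.n
    uf = _UnionFind(n)
    values = dmat.values
    for i in range(n):
        for j in range(i + 1, n):
            v = values[i, j]
            if not math.isnan(v) and v < threshold:
                uf.union(i, j)
    assignment = {dmat.labels[i]: uf.find(i) for i in range(n)}
    part = Partition(
        method="ABGD_INITIAL",
        prior_p=None,
        threshold_found=threshold,
        assignment=assignment,
        n_groups=len({uf.find(i) for i in range(n)}),
    )
    return relabel_groups(part, list(dmat.labels))


def _single_group(dmat: DistanceMatrix, method: str, prior: float) -> Partition:
    return Partition(
        method=method,
        prior_p=prior,
        threshold_found=None,
        assignment={lab: 0 for lab in dmat.labels},
        n_groups=1,
    )


def abgd_partition(
    dmat: DistanceMatrix, prior_p: float, x: float
) -> tuple[Partition, Partition]:
    """Initial and recursive partition at one prior."""
    ranked = ranked_distances(dmat)
    threshold = find_gap(ranked, prior_p, x)
    if threshold is None:
        initial = _single_group(dmat, "ABGD_INITIAL", prior_p)
    else:
        initial = partition_at_threshold(dmat, threshold)
        initial.method = "ABGD_INITIAL"
        initial.prior_p = prior_p

    # recursive refinement: re-run gap finding inside every group to fixpoint
    order = {lab: i for i, lab in enumerate(dmat.labels)}
    groups = [sorted(g, key=order.__getitem__) for g in initial.groups().values()]
    for _ in range(MAX_RECURSION_ROUNDS):
        new_groups: list[list[str]] = []
        changed = False
        for members in groups:
            if len(members) < 3:
                new_groups.append(members)
                continue
            sub = dmat.submatrix(members)
            thr = find_gap(ranked_distances(sub), prior_p, x)
            if thr is None:
                new_groups.append(members)
                continue
            sub_part = partition_at_threshold(sub, thr)
            if sub_part.n_groups == 1:
                new_groups.append(members)
                continue
            changed = True
            for sub_members in sub_part.groups().values():
                new_groups.append(sorted(sub_members, key=order.__getitem__))
        groups = new_groups
        if not changed:
            break
    else:
        raise PartitionError(
            "recursive ABGD refinement did not reach a fixpoint "
            f"in {MAX_RECURSION_ROUNDS} rounds"
        )
    assignment = {}
    for gid, members in enumerate(groups):
        for rec_id in members:
            assignment[rec_id] = gid
    recursive = relabel_groups(
        Partition(
            method="ABGD_RECURSIVE",
            prior_p=prior_p,
            threshold_found=threshold,
            assignment=assignment,
            n_groups=len(groups),
        ),
        list(dmat.labels),
    )
    return initial, recursive


def abgd_sweep(dmat: DistanceMatrix, config: AbgdConfig) -> list[Partition]:
    """Initial + recursive partition for every prior (2 * n_steps results)."""
    if dmat.model != config.model:
        raise DistanceError(
            f"matrix model {dmat.model} does not match config model {config.model}"
        )
    out: list[Partition] = []
    for prior in config.priors():
        initial, recursive = abgd_partition(
            dmat, float(prior), config.relative_gap_width_x
        )
        out.extend([initial, recursive])
    return out


def sweep_frame(partitions: list[Partition]) -> pd.DataFrame:
    """Per-prior group-count table of a sweep."""
    rows = [
        {
            "method": p.method,
            "prior_p": p.prior_p,
            "threshold": p.threshold_found,
            "n_groups": p.n_groups,
        }
        for p in partitions
    ]
    return pd.DataFrame(rows)


def partitions_frame(partitions: list[Partition]) -> pd.DataFrame:
    """Long-form assignment table (method, prior, threshold, id, group)."""
    rows = []
    for p in partitions:
        for rec_id, gid in sorted(p.assignment.items()):
            rows.append(
                {
                    "method": p.method,
                    "prior_p": p.prior_p,
                    "threshold": p.threshold_found,
                    "id": rec_id,
                    "group": gid,
                }
            )
    return pd.DataFrame(rows)
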