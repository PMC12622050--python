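"""CATH assignment, novelty calls, TM-threshold clustering, and fold census.

A candidate structure is queried against a reference fold library (CATH-style
four-level dotted labels, C.A.T.H). It is *assigned* if its best hit exceeds
the TM-score threshold (strictly), and *novel* if it is compact (burial
fraction strictly above the compactness threshold) yet unassigned. Novel
candidates are de-redundified by greedy clustering at a TM threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable

from .structio import BurialFraction

TM_ASSIGN_THRESHOLD = 0.5
COMPACTNESS_THRESHOLD = 0.5

CATH_LEVELS = ("C", "CA", "CAT", "CATH")


def parse_cath_label(label: str) -> tuple:
    """Validate and split a dotted CATH label of 1–4 integer levels."""
    parts = label.split(".")
    if not 1 <= len(parts) <= 4:
        raise ValueError(f"malformed CATH label {label!r}")
    try:
        return tuple(int(p) for p in parts)
    except ValueError:
        raise ValueError(f"malformed CATH label {label!r}")


def cath_prefix(label: str, level: str) -> str:
    """Truncate a label to a hierarchy level ('C', 'CA', 'CAT', 'CATH')."""
    depth = CATH_LEVELS.index(level) + 1
    parts = label.split(".")
    return ".".join(parts[:depth])


@dataclass(frozen=True)
class StructureSearchHit:
    query_id: str
    target_id: str
    tm_score: float
    cath_label: str

    def __post_init__(self):
        parse_cath_label(self.cath_label)


@dataclass(frozen=True)
class NoveltyCall:
    candidate_id: str
    compact: bool
    assigned_label: str | None
    best_hit: StructureSearchHit | None
    novel: bool


@dataclass(frozen=True)
class FoldCensus:
    """Unique structural-group counts per CATH level, plus optional novel
    cluster count. By hierarchy, n_unique('CATH') ≥ n_unique('CAT') ≥
    n_unique('CA') ≥ n_unique('C')."""

    unique: dict          # level -> count
    novel_clusters: int = 0
    total: int = 0


@dataclass(frozen=True)
class ClusterSet:
    clusters: list        # (representative_id, [member_ids]) — rep included

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def representative_ids(self) -> list:
        return [rep for rep, _ in self.clusters]


def assign_cath(hits, tm_threshold: float = TM_ASSIGN_THRESHOLD):
    """Best-hit CATH assignment.

    Returns (assigned_label | None, best_hit | None). Assigned iff the
    maximum TM-score strictly exceeds the threshold; among equal-TM hits
    the lexicographically smallest target_id wins.
    """
    if not hits:
        return None, None
    best = min(hits, key=lambda h: (-h.tm_score, h.target_id))
    if best.tm_score > tm_threshold:
        return best.cath_label, best
    return None, best


def novelty_call(
    candidate_id: str,
    burial: BurialFraction | float,
    hits,
    tm_threshold: float = TM_ASSIGN_THRESHOLD,
    compactness_threshold: float = COMPACTNESS_THRESHOLD,
) -> NoveltyCall:
    """Novel ⇔ compact (burial strictly > threshold) AND unassigned."""
    b = burial.value if isinstance(burial, BurialFraction) else float(burial)
    compact = b > compactness_threshold
    label, best = assign_cath(hits, tm_threshold)
    return NoveltyCall(
        candidate_id=candidate_id,
        compact=compact,
        assigned_label=label,
        best_hit=best,
        novel=compact and label is None,
    )


def greedy_tm_cluster(
    ids,
    pairwise_tm: Callable[[str, str], float],
    threshold: float = TM_ASSIGN_THRESHOLD,
    burials: dict | None = None,
) -> ClusterSet:
    """Greedy TM-threshold clustering.

    Candidates are visited in order of descending burial (ties:
    lexicographic id; with no burials given, lexicographic id order). The
    first unclustered candidate founds a cluster and absorbs every
    unclustered candidate with TM ≥ threshold to it; repeat until all are
    clustered. Every member therefore has TM ≥ threshold to its
    representative.
    """
    if burials:
        order = sorted(ids, key=lambda i: (-burials.get(i, 0.0), i))
    else:
        order = sorted(ids)
    unclustered = list(order)
    clusters = []
    while unclustered:
        rep = unclustered.pop(0)
        members = [rep]
        remaining = []
        for other in unclustered:
            if pairwise_tm(rep, other) >= threshold:
                members.append(other)
            else:
                remaining.append(other)
        unclustered = remaining
        clusters.append((rep, members))
    return ClusterSet(clusters=clusters)


def build_census(calls, novel_clusters: int = 0) -> FoldCensus:
    """Unique-label census over a set of novelty calls."""
    labels = [c.assigned_label for c in calls if c.assigned_label is not None]
    unique = {
        level: len({cath_prefix(lb, level) for lb in labels})
        for level in CATH_LEVELS
    }
    return FoldCensus(unique=unique, novel_clusters=novel_clusters,
                      total=len(list(calls)))


def _round1(x: Fraction) -> float:
    """Round-half-even to one decimal, in exact rational arithmetic."""
    scaled = x * 10
    floor = scaled.numerator // scaled.denominator
    rem = scaled - floor
    if rem > Fraction(1, 2) or (rem == Fraction(1, 2) and floor % 2 == 1):
        floor += 1
    return floor / 10.0


def census_stats(before: FoldCensus, after: FoldCensus) -> dict:
    """Growth report between two censuses: per-level absolute deltas and
    percentage increases (1-decimal, round-half-even)."""
    report = {}
    for level in CATH_LEVELS:
        b = before.unique.get(level)
        a = after.unique.get(level)
        if b is None or a is None:
            continue
        if b <= 0:
            raise ValueError(f"zero baseline at level {level}")
        report[level] = {
            "before": b,
            "after": a,
            "delta": a - b,
            "pct": _round1(Fraction(100 * (a - b), b)),
        }
    return report


@dataclass(frozen=True)
class DiscoveryRate:
    fraction: float
    per_million: float
    percent: float      # 100·fraction, 1-decimal round-half-even


def discovery_rate(novel: int, total: int) -> DiscoveryRate:
    """Novel-fold discovery rate in fraction, per-million, and rounded
    percent forms."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= novel <= total:
        raise ValueError("need 0 <= novel <= total")
    frac = Fraction(novel, total)
    return DiscoveryRate(
        fraction=float(frac),
        per_million=float(frac * 1_000_000),
        percent=_round1(frac * 100),
    )


def calls_table(calls) -> str:
    """TSV export of novelty calls."""
    lines = ["candidate_id\tcompact\tassigned_label\tbest_hit_target\tbest_hit_tm\tnovel"]
    for c in calls:
        tgt = c.best_hit.target_id if c.best_hit else ""
        tm = f"{c.best_hit.tm_score:.4f}" if c.best_hit else ""
        lines.append(
            f"{c.candidate_id}\t{int(c.compact)}\t{c.assigned_label or ''}\t"
            f"{tgt}\t{tm}\t{int(c.novel)}"
        )
    return "\n".join(lines) + "\n"
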