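"""Pairwise similarity, Kimura two-parameter distances, and panel summaries.

Percent similarity between two aligned sequences is 100 x (identical
compared sites / compared sites); under pairwise deletion a site is compared
only when both sequences carry an unambiguous base (A/C/G/T).  The K2P
distance separates transitions (A<->G, C<->T; proportion P) from
transversions (proportion Q):

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

The marker-selection baseline is the "total average" of a similarity matrix:
mean +/- SD over all t(t-1)/2 off-diagonal values.  A taxon's specificity
signal is its mean similarity to all non-congeneric taxa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core_io import Alignment, SeqRecord, SimilarityMatrix, build_common_sequence

__all__ = [
    "DistanceResult",
    "SummaryStats",
    "SiteClassCounts",
    "SaturationError",
    "pairwise_similarity",
    "k2p_distance",
    "similarity_matrix",
    "matrix_total_average",
    "taxon_vs_others_average",
    "classify_sites",
]

_BASES = frozenset("ACGT")
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


class SaturationError(ValueError):
    """K2P logarithm domain violation: divergence too high for the model."""

    def __init__(self, P: float, Q: float):
        self.P = P
        self.Q = Q
        super().__init__(
            f"distance undefined (saturation): P={P:.4f}, Q={Q:.4f}"
        )


@dataclass(frozen=True)
class DistanceResult:
    """K2P components: transition/transversion proportions and the distance."""

    P: float
    Q: float
    d: float
    compared_sites: int


@dataclass(frozen=True)
class SummaryStats:
    """Mean +/- sample SD over n pairwise percent-similarity values."""

    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class SiteClassCounts:
    conserved: int
    variable: int
    parsimony_informative: int
    singleton: int
    total_columns: int


def _compared_positions(a: str, b: str) -> list[int]:
    return [i for i in range(len(a)) if a[i] in _BASES and b[i] in _BASES]


def _check_pair(a, b) -> tuple[str, str]:
    sa = a.sequence if isinstance(a, SeqRecord) else str(a).upper()
    sb = b.sequence if isinstance(b, SeqRecord) else str(b).upper()
    if len(sa) != len(sb):
        raise ValueError(f"sequences have unequal lengths ({len(sa)} vs {len(sb)})")
    return sa, sb


def pairwise_similarity(a, b, gap_policy: str = "pairwise_deletion") -> float:
    """Percent identity over compared sites of two aligned sequences.

    Sites where either sequence has a gap, N or another ambiguity code are
    excluded.  (For a single pair, complete deletion coincides with pairwise
    deletion; the policies differ only at matrix level.)
    """
    if gap_policy not in ("pairwise_deletion", "complete"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    sa, sb = _check_pair(a, b)
    pos = _compared_positions(sa, sb)
    if not pos:
        raise ValueError("zero comparable sites between sequences")
    same = sum(1 for i in pos if sa[i] == sb[i])
    return 100.0 * same / len(pos)


def k2p_distance(a, b, gap_policy: str = "pairwise_deletion") -> DistanceResult:
    """Kimura two-parameter distance between two aligned sequences."""
    if gap_policy not in ("pairwise_deletion", "complete"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    sa, sb = _check_pair(a, b)
    pos = _compared_positions(sa, sb)
    if not pos:
        raise ValueError("zero comparable sites between sequences")
    ts = tv = 0
    for i in pos:
        if sa[i] == sb[i]:
            continue
        if frozenset((sa[i], sb[i])) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    n = len(pos)
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(P, Q)
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    # identical sequences give exactly 0, not a rounding residue
    if ts == 0 and tv == 0:
        d = 0.0
    return DistanceResult(P=P, Q=Q, d=d, compared_sites=n)


def _complete_deletion_columns(seqs: Sequence[str]) -> list[int]:
    length = len(seqs[0])
    return [i for i in range(length) if all(s[i] in _BASES for s in seqs)]


def similarity_matrix(
    data,
    use_common_sequences: bool = True,
    gap_policy: str = "pairwise_deletion",
    marker: str = "",
) -> SimilarityMatrix:
    """Build the pairwise percent-similarity matrix over taxa.

    ``data`` is an :class:`Alignment` or a sequence of aligned
    :class:`SeqRecord`.  With ``use_common_sequences`` conspecific records
    are first collapsed to one per-species consensus so within-species SNPs
    do not depress between-taxon similarity.
    """
    if isinstance(data, Alignment):
        records = list(data.records)
        marker = marker or data.marker
    else:
        records = list(data)
        if not marker:
            markers = {r.marker for r in records}
            marker = markers.pop() if len(markers) == 1 else ""

    if use_common_sequences:
        by_species: dict[tuple[str, str], list[SeqRecord]] = {}
        for r in records:
            by_species.setdefault(r.taxon, []).append(r)
        records = [build_common_sequence(rs) for rs in by_species.values()]

    if len(records) < 2:
        raise ValueError("need at least 2 taxa after species collapse")

    seqs = [r.sequence for r in records]
    if gap_policy == "complete":
        cols = _complete_deletion_columns(seqs)
        if not cols:
            raise ValueError("complete deletion removed every column")
        seqs = ["".join(s[i] for i in cols) for s in seqs]
        gap_policy = "pairwise_deletion"

    t = len(records)
    values = np.full((t, t), 100.0)
    for i in range(t):
        for j in range(i + 1, t):
            try:
                s = pairwise_similarity(seqs[i], seqs[j], gap_policy)
            except ValueError as e:
                raise ValueError(
                    f"pair ({records[i].id}, {records[j].id}): {e}"
                ) from e
            values[i, j] = values[j, i] = s
    taxa = [r.taxon for r in records]
    if len(set(taxa)) != len(taxa):
        # uncollapsed strains of one species: disambiguate labels by strain
        taxa = [
            (r.genus, f"{r.species} {r.strain}".strip() or str(i))
            for i, r in enumerate(records)
        ]
    length = len(seqs[0])
    return SimilarityMatrix(marker=marker, taxa=taxa, values=values, aligned_length=length)


def _summary(values: np.ndarray) -> SummaryStats:
    n = len(values)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    return SummaryStats(mean=mean, sd=sd, n=n)


def matrix_total_average(m: SimilarityMatrix) -> SummaryStats:
    """Total average similarity: mean +/- SD over all off-diagonal values."""
    if len(m) < 2:
        raise ValueError("need at least 2 taxa")
    return _summary(m.off_diagonal())


def taxon_vs_others_average(
    m: SimilarityMatrix, target, exclude_congeners: bool = True
) -> SummaryStats:
    """Mean similarity of a taxon (or a whole genus) to all other taxa.

    ``target`` is a (genus, species) pair, a "Genus species" string, or a
    bare genus name (pooling every congeneric row).  Congeners of the target
    are excluded from the comparator set by default — the convention under
    which a low value flags a genus-discriminative marker.
    """
    if isinstance(target, str) and " " not in target and (target, "") not in m.taxa:
        rows = [i for i, (g, _) in enumerate(m.taxa) if g == target]
        if not rows:
            raise KeyError(f"genus {target!r} not in matrix")
    else:
        rows = [m.index_of(target)]

    genera = {m.taxa[i][0] for i in rows}
    vals: list[float] = []
    for i in rows:
        for j in range(len(m)):
            if j == i:
                continue
            if exclude_congeners and m.taxa[j][0] in genera:
                continue
            if not exclude_congeners and j in rows:
                continue
            vals.append(m.values[i, j])
    if not vals:
        raise ValueError("no comparator taxa left after exclusion")
    return _summary(np.asarray(vals))


def classify_sites(alignment: Alignment, exclude_ambiguous: bool = True) -> SiteClassCounts:
    """Parsimony site classification of alignment columns.

    Conserved: one base state.  Variable: >=2 states; parsimony-informative
    when >=2 states each occur in >=2 sequences, singleton otherwise.
    Columns containing gaps or ambiguity codes are excluded from
    ``total_columns`` by default.
    """
    if len(alignment.records) < 2:
        raise ValueError("need at least 2 sequences")
    conserved = informative = singleton = total = 0
    for col in zip(*(r.sequence for r in alignment.records)):
        chars = [c for c in col if c in _BASES]
        if exclude_ambiguous and len(chars) != len(col):
            continue
        if not chars:
            continue
        total += 1
        counts: dict[str, int] = {}
        for c in chars:
            counts[c] = counts.get(c, 0) + 1
        if len(counts) == 1:
            conserved += 1
        elif sum(1 for c in counts.values() if c >= 2) >= 2:
            informative += 1
        else:
            singleton += 1
    return SiteClassCounts(
        conserved=conserved,
        variable=informative + singleton,
        parsimony_informative=informative,
        singleton=singleton,
        total_columns=total,
    )
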