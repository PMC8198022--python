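"""Discriminative-window discovery and primer-pair design.

The design substrate is a genus-labeled multiple alignment.  A
*discriminative window* is an alignment interval that is conserved within
the target genus yet differs by at least D bases from the *closest* member
of every other genus — the worst case, so a specificity claim holds against
every panel sequence, not just a consensus.  Primer candidates cut from the
target consensus are screened on length, melting temperature (Wallace
2(A+T)+4(G+C) by default), GC content, hairpin stems and primer-dimer
overlap, and paired under a product-size constraint.  The recommended
annealing temperature is snapped onto the 51-59 degC grid in 2-degree steps
used for annealing optimization.

For genera too similar to yield many-base windows, specificity can still be
engineered by placing the few diagnostic SNPs at the primer's 3' terminus:
a template mismatch at distance k from the 3' end impairs extension with an
empirically measured probability p_k (defaults p_1 = 22.5%, p_4 = 31.7%,
p_5 = 32.9%, from allele-specific PCR mismatch studies).  Assuming
independence, the combined discrimination probability over mismatch
positions K is C = 100 x (1 - prod_k (1 - p_k/100)).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .core_io import Alignment

__all__ = [
    "Window",
    "PrimerCandidate",
    "PrimerPairDesign",
    "MismatchProfile",
    "DesignConstraints",
    "DesignResult",
    "DEFAULT_MISMATCH_PROBABILITIES",
    "revcomp",
    "find_discriminative_windows",
    "melting_temperature",
    "gc_content",
    "hairpin_check",
    "HairpinResult",
    "dimer_score",
    "design_primer_pairs",
    "score_3prime_discrimination",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Extension-failure probability (%) of a single primer-template mismatch at
#: distance k from the 3' terminus (k = 1 is the terminal base).  Positions
#: without a measured value are excluded from the combined score.
DEFAULT_MISMATCH_PROBABILITIES: dict[int, float] = {1: 22.5, 4: 31.7, 5: 32.9}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Window:
    """A discriminative alignment interval [start, end) for one target genus."""

    marker: str
    start: int
    end: int
    target_genus: str
    within_target_conservation: float
    diff_counts: dict[str, int]
    strand_role: Optional[str] = None
    consensus: str = ""

    @property
    def min_diff(self) -> int:
        return min(self.diff_counts.values()) if self.diff_counts else 0

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PrimerCandidate:
    sequence: str
    orientation: str
    window: Optional[Window]
    tm: float
    gc: float
    hairpin: bool
    self_dimer_score: int
    start: int = 0  # alignment column of the candidate's left edge

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PrimerPairDesign:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    product_size: int
    recommended_annealing: int
    cross_dimer_score: int
    target_genus: str = ""
    marker: str = ""

    @property
    def min_diff(self) -> int:
        wins = [w for w in (self.forward.window, self.reverse.window) if w]
        return min((w.min_diff for w in wins), default=0)


@dataclass
class MismatchProfile:
    """Off-target mismatch placement relative to a primer's 3' terminus."""

    positions: list[int]
    per_position_probability: dict[int, float]
    unknown_positions: list[int]
    combined: float


# ---------------------------------------------------------------------------
# Window discovery

def _consensus_base(counts: Counter) -> str:
    # deterministic: most frequent, ties alphabetically
    top = max(counts.values())
    return sorted(b for b, c in counts.items() if c == top)[0]


def find_discriminative_windows(
    alignment: Alignment,
    target_genus: str,
    length_range: tuple[int, int] = (18, 25),
    min_diff_per_genus: int = 1,
    min_conservation: float = 90.0,
    role: Optional[str] = None,
) -> list[Window]:
    """Enumerate all alignment windows usable as genus-specific primer sites.

    A window [s, s+L) with L in ``length_range`` is returned when (i) the
    target-genus rows agree with their own consensus over at least
    ``min_conservation`` percent of cells, (ii) for *every* other genus the
    closest member differs from the target consensus in at least
    ``min_diff_per_genus`` positions, and (iii) the consensus slice is plain
    A/C/G/T (a primer cannot contain gaps or ambiguity).  Sorted by
    worst-case difference count (descending), leftmost first on ties.
    """
    lmin, lmax = length_range
    if alignment.length < lmin:
        raise ValueError(
            f"alignment has {alignment.length} columns, shorter than minimum window {lmin}"
        )
    target_rows = alignment.rows_for_genus(target_genus)
    if not target_rows:
        raise ValueError(f"target genus {target_genus!r} absent from alignment")
    others = [g for g in alignment.genera() if g != target_genus]
    if not others:
        raise ValueError("no non-target genus present")

    arr = alignment.to_array()
    ncols = alignment.length
    tgt = arr[target_rows]

    consensus = np.empty(ncols, dtype="U1")
    for c in range(ncols):
        consensus[c] = _consensus_base(Counter(tgt[:, c]))
    cons_str = "".join(consensus)

    match_frac = (tgt == consensus[None, :]).mean(axis=0)
    # prefix sums for O(1) window sums
    cum_match = np.concatenate([[0.0], np.cumsum(match_frac)])

    diff_rows: dict[str, np.ndarray] = {}
    for g in others:
        rows = alignment.rows_for_genus(g)
        diffs = (arr[rows] != consensus[None, :]).astype(int)
        diff_rows[g] = np.concatenate(
            [np.zeros((len(rows), 1), dtype=int), np.cumsum(diffs, axis=1)], axis=1
        )

    acgt = np.isin(consensus, list("ACGT"))
    cum_acgt = np.concatenate([[0], np.cumsum(~acgt)])

    out: list[Window] = []
    for L in range(lmin, min(lmax, ncols) + 1):
        for s in range(ncols - L + 1):
            e = s + L
            if cum_acgt[e] - cum_acgt[s] > 0:
                continue
            conservation = 100.0 * (cum_match[e] - cum_match[s]) / L
            if conservation < min_conservation:
                continue
            counts: dict[str, int] = {}
            ok = True
            for g in others:
                cs = diff_rows[g]
                D = int((cs[:, e] - cs[:, s]).min())
                counts[g] = D
                if D < min_diff_per_genus:
                    ok = False
                    break
            if not ok:
                continue
            out.append(
                Window(
                    marker=alignment.marker,
                    start=s,
                    end=e,
                    target_genus=target_genus,
                    within_target_conservation=conservation,
                    diff_counts=counts,
                    strand_role=role,
                    consensus=cons_str[s:e],
                )
            )
    out.sort(key=lambda w: (-w.min_diff, w.start, w.end))
    return out


# ---------------------------------------------------------------------------
# Thermodynamic-style screens

def _require_acgt(seq: str) -> str:
    seq = seq.upper()
    if not seq or set(seq) - set("ACGT"):
        raise ValueError(f"sequence must be non-empty A/C/G/T, got {seq!r}")
    return seq


def melting_temperature(sequence: str, method: str = "wallace") -> float:
    """Primer melting temperature in deg C.

    ``wallace``: Tm = 2(A+T) + 4(G+C).
    ``gc``:      Tm = 64.9 + 41 x (nGC - 16.4) / N.
    """
    seq = _require_acgt(sequence)
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    if method == "wallace":
        return 2.0 * at + 4.0 * gc
    if method == "gc":
        return 64.9 + 41.0 * (gc - 16.4) / len(seq)
    raise ValueError(f"unknown Tm method {method!r}")


def gc_content(sequence: str) -> float:
    seq = _require_acgt(sequence)
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class HairpinResult:
    found: bool
    stem_length: int = 0
    stem5: tuple[int, int] = (0, 0)
    stem3: tuple[int, int] = (0, 0)

    def __bool__(self) -> bool:
        return self.found


def hairpin_check(sequence: str, min_stem: int = 4, min_loop: int = 3) -> HairpinResult:
    """Detect a fold-back stem: two reverse-complementary runs of at least
    ``min_stem`` bases separated by a loop of at least ``min_loop`` bases.
    Reports the longest such stem."""
    seq = _require_acgt(sequence)
    n = len(seq)
    best = HairpinResult(found=False)
    for i in range(n):
        for j in range(i + 2 * min_stem + min_loop - 1, n):
            # grow a stem pairing seq[i..] with seq[..j] inward
            k = 0
            while i + k < j - k - min_loop and seq[i + k] == revcomp(seq[j - k]):
                k += 1
            if k >= min_stem and k > best.stem_length:
                best = HairpinResult(
                    found=True,
                    stem_length=k,
                    stem5=(i, i + k),
                    stem3=(j - k + 1, j + 1),
                )
    return best


def dimer_score(a: str, b: Optional[str] = None) -> int:
    """Longest contiguous complementary run between ``a`` and ``b`` in
    antiparallel orientation, over all alignment offsets.  ``b`` defaults to
    ``a`` (self-dimer)."""
    a = _require_acgt(a)
    b = a if b is None else _require_acgt(b)
    rb = b[::-1]
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    best = 0
    for off in range(-len(rb) + 1, len(a)):
        run = 0
        for k in range(len(rb)):
            i = off + k
            if 0 <= i < len(a) and comp[rb[k]] == a[i]:
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best


# ---------------------------------------------------------------------------
# Pair design

@dataclass
class DesignConstraints:
    """Screening thresholds for primer candidates and pairs.

    Caps are deliberately permissive enough to admit wet-lab-validated
    genus-specific primer sets, which include a 5-bp fold-back stem and a
    10-bp palindromic self-overlap in working primers; binary run-length
    screens overcall such motifs.
    """

    length: tuple[int, int] = (18, 25)
    tm_range: tuple[float, float] = (50.0, 72.0)
    tm_method: str = "wallace"
    gc_range: tuple[float, float] = (30.0, 70.0)
    product_size: tuple[int, int] = (150, 600)
    annealing_grid: tuple[int, ...] = (51, 53, 55, 57, 59)
    max_hairpin_stem: int = 5
    hairpin_min_loop: int = 3
    max_self_dimer_run: int = 10
    max_cross_dimer_run: int = 8
    max_tm_difference: float = 6.0
    preferred_product: Optional[int] = None


@dataclass
class DesignResult:
    pairs: list[PrimerPairDesign]
    rejections: Counter

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def _candidates_from_window(
    w: Window, orientation: str, c: DesignConstraints, tally: Counter
) -> list[PrimerCandidate]:
    out = []
    lmin, lmax = c.length
    cons = w.consensus
    for L in range(lmin, min(lmax, len(cons)) + 1):
        for off in range(len(cons) - L + 1):
            sub = cons[off : off + L]
            if set(sub) - set("ACGT"):
                tally["non_acgt"] += 1
                continue
            seq = sub if orientation == "forward" else revcomp(sub)
            tm = melting_temperature(seq, c.tm_method)
            if not (c.tm_range[0] <= tm <= c.tm_range[1]):
                tally["tm"] += 1
                continue
            gc = gc_content(seq)
            if not (c.gc_range[0] <= gc <= c.gc_range[1]):
                tally["gc"] += 1
                continue
            hp = hairpin_check(seq, min_stem=c.max_hairpin_stem + 1, min_loop=c.hairpin_min_loop)
            if hp.found:
                tally["hairpin"] += 1
                continue
            sd = dimer_score(seq)
            if sd > c.max_self_dimer_run:
                tally["self_dimer"] += 1
                continue
            out.append(
                PrimerCandidate(
                    sequence=seq,
                    orientation=orientation,
                    window=w,
                    tm=tm,
                    gc=gc,
                    hairpin=False,
                    self_dimer_score=sd,
                    start=w.start + off,
                )
            )
    return out


def recommend_annealing(tm_f: float, tm_r: float, grid: Sequence[int] = (51, 53, 55, 57, 59)) -> int:
    """Grid point nearest to min(Tm) - 5, clamped into the grid (lower on ties)."""
    ta = min(tm_f, tm_r) - 5.0
    return min(grid, key=lambda g: (abs(g - ta), g))


def design_primer_pairs(
    windows: Sequence[Window],
    target_consensus: str,
    constraints: Optional[DesignConstraints] = None,
) -> DesignResult:
    """Pair forward- and reverse-role windows into screened primer pairs.

    The reverse primer is the reverse complement of its window's consensus.
    Product size is measured on the (degapped) reference consensus from the
    forward primer's start to the reverse primer's end.  Pairs are sorted by
    worst-case window difference count (descending), then closeness to the
    preferred product size, then coordinates.  When nothing passes, the
    result carries per-constraint rejection tallies instead of raising.
    """
    c = constraints or DesignConstraints()
    tally: Counter = Counter()
    fwd_windows = [w for w in windows if w.strand_role in (None, "forward")]
    rev_windows = [w for w in windows if w.strand_role in (None, "reverse")]
    if not fwd_windows or not rev_windows:
        raise ValueError("need at least one forward-role and one reverse-role window")

    # reference coordinates: number of non-gap consensus chars before column c
    gapless = np.array([ch != "-" for ch in target_consensus], dtype=int)
    ref_before = np.concatenate([[0], np.cumsum(gapless)])

    fwd_cands: list[PrimerCandidate] = []
    for w in fwd_windows:
        fwd_cands.extend(_candidates_from_window(w, "forward", c, tally))
    rev_cands: list[PrimerCandidate] = []
    for w in rev_windows:
        rev_cands.extend(_candidates_from_window(w, "reverse", c, tally))

    pairs: list[PrimerPairDesign] = []
    pmin, pmax = c.product_size
    preferred = c.preferred_product if c.preferred_product is not None else (pmin + pmax) // 2
    for f in fwd_cands:
        f_end = f.start + f.length
        for r in rev_cands:
            if r.start < f_end:
                continue
            r_end = r.start + r.length
            product = int(ref_before[r_end] - ref_before[f.start])
            if not (pmin <= product <= pmax):
                tally["product_size"] += 1
                continue
            if abs(f.tm - r.tm) > c.max_tm_difference:
                tally["tm_difference"] += 1
                continue
            cd = dimer_score(f.sequence, r.sequence)
            if cd > c.max_cross_dimer_run:
                tally["cross_dimer"] += 1
                continue
            pairs.append(
                PrimerPairDesign(
                    forward=f,
                    reverse=r,
                    product_size=product,
                    recommended_annealing=recommend_annealing(f.tm, r.tm, c.annealing_grid),
                    cross_dimer_score=cd,
                    target_genus=(f.window.target_genus if f.window else ""),
                    marker=(f.window.marker if f.window else ""),
                )
            )

    pairs.sort(
        key=lambda p: (
            -p.min_diff,
            abs(p.product_size - preferred),
            p.forward.start,
            p.reverse.start,
            p.forward.sequence,
            p.reverse.sequence,
        )
    )
    return DesignResult(pairs=pairs, rejections=tally)


# ---------------------------------------------------------------------------
# 3'-terminal mismatch scoring

def _best_site(primer: str, template: str) -> tuple[int, str, int]:
    """(offset, strand, mismatches) of the best antiparallel-duplex placement
    of ``primer`` on ``template``; + means the primer equals the template
    substring (extension rightward), - means it equals the reverse
    complement (extension leftward, coordinates on the + strand)."""
    L = len(primer)
    best: Optional[tuple[int, int, str]] = None  # (mismatches, offset, strand)
    for strand, probe in (("+", primer), ("-", revcomp(primer))):
        for off in range(len(template) - L + 1):
            mm = sum(1 for a, b in zip(probe, template[off : off + L]) if a != b)
            cand = (mm, off, strand)
            if best is None or cand < best:
                best = cand
    if best is None:
        raise ValueError("primer longer than template")
    mm, off, strand = best
    return off, strand, mm


def _mismatch_positions_from_3prime(primer: str, template: str, off: int, strand: str) -> list[int]:
    L = len(primer)
    site = template[off : off + L]
    ks = []
    if strand == "+":
        for i, (a, b) in enumerate(zip(primer, site)):
            if a != b:
                ks.append(L - i)  # k = 1 is the 3'-terminal base (right edge)
    else:
        probe = revcomp(primer)
        for j, (a, b) in enumerate(zip(probe, site)):
            if a != b:
                ks.append(j + 1)  # 3' terminus sits at the site's left edge
    return sorted(ks)


def combined_mismatch_probability(
    positions: Sequence[int],
    probability_table: Optional[Mapping[int, float]] = None,
) -> MismatchProfile:
    """Fold per-position extension-failure probabilities into one score
    under independence; positions without a tabulated value are reported as
    unknown and excluded."""
    table = DEFAULT_MISMATCH_PROBABILITIES if probability_table is None else dict(probability_table)
    known = {k: table[k] for k in positions if k in table}
    unknown = [k for k in positions if k not in table]
    keep = 1.0
    for p in known.values():
        keep *= 1.0 - p / 100.0
    combined = 100.0 * (1.0 - keep) if known else 0.0
    return MismatchProfile(
        positions=sorted(positions),
        per_position_probability=known,
        unknown_positions=sorted(unknown),
        combined=combined,
    )


def score_3prime_discrimination(
    primer,
    target_template: str,
    offtarget_template: str,
    probability_table: Optional[Mapping[int, float]] = None,
) -> MismatchProfile:
    """Score how strongly 3'-proximal mismatches keep a primer off an
    off-target template.

    The primer must form a perfect duplex somewhere on the target template
    (discrimination is defined relative to a perfect target match); its
    best-matching site on the off-target template (no indels) yields the
    mismatch distances from the 3' terminus, folded into the combined
    probability C.
    """
    seq = primer.sequence if hasattr(primer, "sequence") else str(primer)
    seq = _require_acgt(seq)
    off, strand, mm = _best_site(seq, target_template.upper())
    if mm != 0:
        raise ValueError(
            f"primer does not bind the target template perfectly "
            f"(best site has {mm} mismatches)"
        )
    o_off, o_strand, _ = _best_site(seq, offtarget_template.upper())
    ks = _mismatch_positions_from_3prime(seq, offtarget_template.upper(), o_off, o_strand)
    return combined_mismatch_probability(ks, probability_table)
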