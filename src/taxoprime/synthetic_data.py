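"""Seeded generators for genus-labeled panels and PCR test templates.

``generate_genus_panel`` emulates the structure of a curated marker-gene
panel: a star-of-stars model in which each genus descends from a common
root at a configurable between-genus divergence and each strain from its
genus ancestor at a within-genus divergence, with substitutions drawn under
a transition:transversion bias so transition/transversion-aware statistics
are exercised meaningfully.  *Planted windows* are overwritten after
background mutation, so the ground truth records exact — not expected —
difference counts: inside a planted interval every target-genus row equals
the target ancestor and every other genus differs from it in exactly D
positions.

No indels, rate heterogeneity or recombination are simulated; sequences
stay aligned by construction.

All randomness flows from the explicit seed in the config; there is no
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_io import Alignment, SeqRecord

__all__ = [
    "PlantedWindow",
    "PanelConfig",
    "PanelTruth",
    "generate_genus_panel",
    "generate_template_with_sites",
]

_BASES = np.array(list("ACGT"))
_IDX = {b: i for i, b in enumerate("ACGT")}
#: transition partner of each base (A<->G, C<->T)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


@dataclass(frozen=True)
class PlantedWindow:
    """A window forced to be discriminative for one genus: the target
    consensus differs from every other genus by exactly ``diffs`` bases."""

    start: int
    end: int
    target_genus: str
    diffs: int
    role: Optional[str] = None


@dataclass
class PanelConfig:
    """Study conditions for a synthetic genus panel.

    Defaults mirror a small nostocalean-style marker panel: 5 genera, a few
    strains each, a few hundred aligned columns, ~2% within-genus and ~15%
    between-genus per-site divergence (similarities in the mid-80s, the
    regime in which marker-based genus discrimination operates), and a 2:1
    transition bias.
    """

    seed: int
    n_genera: int = 5
    seqs_per_genus: int = 3
    length: int = 600
    within_genus_divergence: float = 0.02
    between_genus_divergence: float = 0.15
    transition_bias: float = 2.0
    planted_windows: tuple[PlantedWindow, ...] = ()
    marker: str = "synthetic"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for d in (self.within_genus_divergence, self.between_genus_divergence):
            if not (0.0 <= d <= 0.75):
                raise ValueError("divergences must lie in [0, 0.75]")
        spans = sorted((w.start, w.end) for w in self.planted_windows)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("planted windows must be disjoint")
        for w in self.planted_windows:
            if not (0 <= w.start < w.end <= self.length):
                raise ValueError(f"planted window [{w.start}, {w.end}) outside alignment")
            if w.diffs > w.end - w.start:
                raise ValueError(
                    f"cannot plant {w.diffs} differences in a {w.end - w.start}-column window"
                )


@dataclass
class PanelTruth:
    """Ground truth of a generated panel."""

    genus_of: dict[str, str]
    species_of: dict[str, str]
    planted: list[dict]
    divergence: np.ndarray  # realized pairwise p-distance between records
    record_ids: list[str]


def _mutate(seq: np.ndarray, rate: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution at probability ``rate``; a hit is a transition
    with probability kappa/(kappa+2), else one of the two transversions."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        b = out[i]
        if rng.random() < kappa / (kappa + 2.0):
            out[i] = _TRANSITION[b]
        else:
            out[i] = _TRANSVERSIONS[b][rng.integers(2)]
    return out


def generate_genus_panel(config: PanelConfig) -> tuple[Alignment, PanelTruth]:
    """Generate an aligned genus panel plus its ground truth.

    Identical configs (including seed) give byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    kappa = config.transition_bias
    root = rng.choice(_BASES, size=config.length)

    genus_names = [f"Genus{chr(ord('A') + i)}" for i in range(config.n_genera)]
    ancestors: dict[str, np.ndarray] = {}
    rows: list[tuple[str, np.ndarray]] = []
    for g in genus_names:
        anc = _mutate(root, config.between_genus_divergence, kappa, rng)
        ancestors[g] = anc
        for s in range(config.seqs_per_genus):
            rows.append((g, _mutate(anc, config.within_genus_divergence, kappa, rng)))

    seqs = {f"{g}|sp|s{i}": arr for (g, arr), i in zip(rows, _strain_counter(rows))}

    planted_truth: list[dict] = []
    for w in config.planted_windows:
        if w.target_genus not in genus_names:
            raise ValueError(f"planted window targets unknown genus {w.target_genus!r}")
        target_block = ancestors[w.target_genus][w.start : w.end].copy()
        for key in seqs:
            if key.split("|")[0] == w.target_genus:
                seqs[key][w.start : w.end] = target_block
        realized: dict[str, int] = {}
        for g in genus_names:
            if g == w.target_genus:
                continue
            pos = rng.choice(w.end - w.start, size=w.diffs, replace=False)
            block = target_block.copy()
            for p in pos:
                block[p] = _TRANSVERSIONS[block[p]][rng.integers(2)]
            for key in seqs:
                if key.split("|")[0] == g:
                    seqs[key][w.start : w.end] = block
            realized[g] = int((block != target_block).sum())
        planted_truth.append(
            {
                "start": w.start,
                "end": w.end,
                "target_genus": w.target_genus,
                "role": w.role,
                "realized_diffs": realized,
            }
        )

    records = []
    for key, arr in seqs.items():
        g, sp, strain = key.split("|")
        records.append(
            SeqRecord(
                genus=g, species=sp, strain=strain, marker=config.marker,
                sequence="".join(arr),
            )
        )
    aln = Alignment(marker=config.marker, records=records)

    n = len(records)
    div = np.zeros((n, n))
    mats = [np.array(list(r.sequence)) for r in records]
    for i in range(n):
        for j in range(i + 1, n):
            d = float((mats[i] != mats[j]).mean())
            div[i, j] = div[j, i] = d
    truth = PanelTruth(
        genus_of={r.id: r.genus for r in records},
        species_of={r.id: r.species for r in records},
        planted=planted_truth,
        divergence=div,
        record_ids=[r.id for r in records],
    )
    return aln, truth


def _strain_counter(rows):
    counts: dict[str, int] = {}
    for g, _ in rows:
        counts[g] = counts.get(g, 0) + 1
        yield counts[g]


def generate_template_with_sites(
    forward: str,
    reverse: str,
    insert_length: int,
    flank_lengths: tuple[int, int] = (50, 50),
    seed: int = 0,
    mismatches: Sequence[tuple[str, int]] = (),
) -> tuple[str, dict]:
    """Build a template carrying a planted amplicon for one primer pair.

    The template is ``flank5 + forward + insert + revcomp(reverse) +
    flank3``; the amplicon length is len(forward) + insert_length +
    len(reverse).  ``mismatches`` plants template edits at distance k from a
    primer's 3' terminus, given as ("forward"|"reverse", k) pairs — the tool
    for emulating off-target templates that differ only at 3'-proximal
    positions.
    """
    from .primer_design import revcomp

    fwd = forward.upper()
    rev = reverse.upper()
    if insert_length < 0 or min(flank_lengths) < 0:
        raise ValueError("lengths must be non-negative")
    rng = np.random.default_rng(seed)
    flank5 = "".join(rng.choice(_BASES, size=flank_lengths[0]))
    insert = "".join(rng.choice(_BASES, size=insert_length))
    flank3 = "".join(rng.choice(_BASES, size=flank_lengths[1]))
    template = list(flank5 + fwd + insert + revcomp(rev) + flank3)

    f_start = flank_lengths[0]
    f_end = f_start + len(fwd)
    r_start = f_end + insert_length
    r_end = r_start + len(rev)

    for role, k in mismatches:
        if role == "forward":
            if not (1 <= k <= len(fwd)):
                raise ValueError(f"mismatch position {k} outside forward primer")
            pos = f_end - k
        elif role == "reverse":
            if not (1 <= k <= len(rev)):
                raise ValueError(f"mismatch position {k} outside reverse primer")
            pos = r_start + k - 1
        else:
            raise ValueError(f"unknown primer role {role!r}")
        template[pos] = _TRANSVERSIONS[template[pos]][0]

    truth = {
        "forward_site": (f_start, f_end),
        "reverse_site": (r_start, r_end),
        "amplicon": (f_start, r_end),
        "amplicon_length": r_end - f_start,
    }
    return "".join(template), truth
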