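"""In-silico PCR: primer binding prediction and amplification matrices.

A primer binds a template site when the antiparallel duplex satisfies the
binding rules: at most ``max_total_mismatches`` anywhere, no mismatch at the
3'-terminal base (a terminal mismatch stalls polymerase extension), and at
most ``max_3prime_window_mismatches`` within the last ``three_prime_window``
bases.  An ``N`` in the template counts as a mismatch.  Amplicons arise from
a forward site on the plus strand upstream of a reverse site on the minus
strand, with the product length measured from the forward site's start to
the reverse site's end.  The pair x sample presence/absence table
(:class:`AmplificationMatrix`) is the computational analogue of a gel
specificity panel.

Binding is binary; no extension-efficiency or band-intensity model is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from .core_io import GenusPanel, PrimerRecord
from .primer_design import PrimerPairDesign, revcomp

__all__ = [
    "BindingRules",
    "BindingSite",
    "Amplicon",
    "AmplificationMatrix",
    "find_binding_sites",
    "predict_amplicons",
    "amplification_matrix",
]


@dataclass(frozen=True)
class BindingRules:
    """Mismatch tolerances for calling a primer binding site."""

    max_total_mismatches: int = 2
    reject_if_3prime_terminal_mismatch: bool = True
    max_3prime_window_mismatches: int = 1
    three_prime_window: int = 5


@dataclass(frozen=True)
class BindingSite:
    """A tolerated primer placement, in + strand coordinates."""

    template_id: str
    strand: str  # '+' or '-'
    start: int
    end: int
    total_mismatches: int
    three_prime_mismatches: tuple[int, ...]  # distances k from the 3' terminus


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    start: int
    end: int
    forward_site: BindingSite
    reverse_site: BindingSite

    @property
    def length(self) -> int:
        return self.end - self.start


def _primer_seq(primer) -> str:
    if hasattr(primer, "sequence"):
        return primer.sequence.upper()
    return str(primer).upper()


def find_binding_sites(
    primer,
    template: str,
    rules: Optional[BindingRules] = None,
    template_id: str = "",
) -> list[BindingSite]:
    """Scan both strands of ``template`` for tolerated binding sites.

    On the + strand the primer matches the template substring and extends
    rightward (its 3' terminus at the site's right edge); on the - strand it
    matches the reverse complement and extends leftward (3' terminus at the
    left edge).  A primer longer than the template yields no sites.
    """
    rules = rules or BindingRules()
    seq = _primer_seq(primer)
    tmpl = template.upper()
    L = len(seq)
    sites: list[BindingSite] = []
    if L > len(tmpl):
        return sites
    for strand, probe in (("+", seq), ("-", revcomp(seq))):
        for off in range(len(tmpl) - L + 1):
            site = tmpl[off : off + L]
            ks: list[int] = []
            for j in range(L):
                a, b = probe[j], site[j]
                if a != b or b not in "ACGT":
                    # distance from the primer's 3' terminus at this strand
                    ks.append(L - j if strand == "+" else j + 1)
            if len(ks) > rules.max_total_mismatches:
                continue
            if rules.reject_if_3prime_terminal_mismatch and 1 in ks:
                continue
            window_mm = sum(1 for k in ks if k <= rules.three_prime_window)
            if window_mm > rules.max_3prime_window_mismatches:
                continue
            sites.append(
                BindingSite(
                    template_id=template_id,
                    strand=strand,
                    start=off,
                    end=off + L,
                    total_mismatches=len(ks),
                    three_prime_mismatches=tuple(sorted(ks)),
                )
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def predict_amplicons(
    pair,
    template: str,
    size_range: tuple[int, int] = (50, 3000),
    rules: Optional[BindingRules] = None,
    template_id: str = "",
) -> list[Amplicon]:
    """Predict PCR products of a primer pair on one template.

    ``pair`` is a :class:`~taxoprime.primer_design.PrimerPairDesign`, a
    (forward, reverse) tuple of sequences/records, or a 2-list of
    :class:`~taxoprime.core_io.PrimerRecord`.  Every + strand forward site
    upstream of a - strand reverse site with a product length inside
    ``size_range`` yields one amplicon; the mirrored configuration (reverse
    primer on +, forward on -) is the same duplex seen from the other
    strand and is enumerated too, so predictions are strand-symmetric.
    """
    if isinstance(pair, PrimerPairDesign):
        fwd, rev = pair.forward.sequence, pair.reverse.sequence
    else:
        f, r = pair
        fwd, rev = _primer_seq(f), _primer_seq(r)
    f_sites = find_binding_sites(fwd, template, rules, template_id)
    r_sites = find_binding_sites(rev, template, rules, template_id)
    lo, hi = size_range
    out: list[Amplicon] = []
    configs = [
        ([s for s in f_sites if s.strand == "+"], [s for s in r_sites if s.strand == "-"]),
        ([s for s in r_sites if s.strand == "+"], [s for s in f_sites if s.strand == "-"]),
    ]
    for plus_sites, minus_sites in configs:
        for fs in plus_sites:
            for rs in minus_sites:
                if rs.start < fs.start:
                    continue
                L = rs.end - fs.start
                if lo <= L <= hi:
                    out.append(
                        Amplicon(
                            template_id=template_id,
                            start=fs.start,
                            end=rs.end,
                            forward_site=fs,
                            reverse_site=rs,
                        )
                    )
    out.sort(key=lambda a: (a.start, a.end))
    # identical span found via both configurations collapses to one product
    seen = set()
    uniq = []
    for a in out:
        key = (a.start, a.end)
        if key not in seen:
            seen.add(key)
            uniq.append(a)
    return uniq


@dataclass
class AmplificationMatrix:
    """Primer-pair x sample table of predicted products (a gel-panel analogue)."""

    pair_names: list[str]
    sample_names: list[str]
    products: dict[tuple[str, str], list[int]] = field(default_factory=dict)

    def amplified(self, pair: str, sample: str) -> bool:
        return bool(self.products.get((pair, sample)))

    def cell(self, pair: str, sample: str) -> str:
        sizes = self.products.get((pair, sample), [])
        return ",".join(str(s) for s in sizes) if sizes else "-"

    def is_diagonal(self, mapping: Mapping[str, str]) -> bool:
        """True iff each pair amplifies exactly the sample(s) its target
        maps to: ``mapping`` takes pair name -> expected sample name."""
        for p in self.pair_names:
            for s in self.sample_names:
                expect = mapping.get(p) == s
                if self.amplified(p, s) != expect:
                    return False
        return True

    def to_tsv(self) -> str:
        lines = ["pair\t" + "\t".join(self.sample_names)]
        for p in self.pair_names:
            lines.append("\t".join([p] + [self.cell(p, s) for s in self.sample_names]))
        return "\n".join(lines) + "\n"


def _as_templates(panel) -> dict[str, list[str]]:
    """Normalize a panel to sample name -> list of template sequences
    (a multi-template sample models a DNA mixture)."""
    if isinstance(panel, GenusPanel):
        return {
            genus: [r.sequence.replace("-", "") for r in recs]
            for genus, recs in panel.members.items()
        }
    out: dict[str, list[str]] = {}
    for name, value in panel.items():
        if isinstance(value, str):
            out[name] = [value]
        elif hasattr(value, "sequence"):
            out[name] = [value.sequence.replace("-", "")]
        else:
            out[name] = [
                v.sequence.replace("-", "") if hasattr(v, "sequence") else str(v)
                for v in value
            ]
    return out


def _as_pairs(pairs) -> dict[str, tuple[str, str]]:
    out: dict[str, tuple[str, str]] = {}
    for item in pairs:
        if isinstance(item, PrimerPairDesign):
            name = f"{item.target_genus}-{item.marker}" if item.target_genus else "pair"
            base = name
            k = 2
            while name in out:
                name, k = f"{base}.{k}", k + 1
            out[name] = (item.forward.sequence, item.reverse.sequence)
        elif isinstance(item, (tuple, list)) and len(item) == 3:
            name, f, r = item
            out[str(name)] = (_primer_seq(f), _primer_seq(r))
        else:
            raise TypeError(f"cannot interpret primer pair {item!r}")
    return out


def pair_records(primers: Iterable[PrimerRecord]) -> list[tuple[str, str, str]]:
    """Group a flat primer table into (pair name, forward, reverse) triples.

    The pair name is the shared primer-name stem (trailing -F/-R stripped).
    """
    by_stem: dict[str, dict[str, PrimerRecord]] = {}
    order: list[str] = []
    for p in primers:
        stem = p.name
        for suffix in ("-F", "-R", "_F", "_R"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
                break
        if stem not in by_stem:
            by_stem[stem] = {}
            order.append(stem)
        by_stem[stem][p.orientation] = p
    out = []
    for stem in order:
        d = by_stem[stem]
        if "forward" not in d or "reverse" not in d:
            raise ValueError(f"pair {stem!r} is missing a forward or reverse primer")
        out.append((stem, d["forward"].sequence, d["reverse"].sequence))
    return out


def amplification_matrix(
    pairs,
    panel,
    size_range: tuple[int, int] = (50, 3000),
    rules: Optional[BindingRules] = None,
) -> AmplificationMatrix:
    """Run every primer pair against every sample.

    ``pairs``: (name, forward, reverse) triples or
    :class:`~taxoprime.primer_design.PrimerPairDesign` objects.  ``panel``:
    a :class:`~taxoprime.core_io.GenusPanel` or mapping sample name ->
    template(s); a sample with several templates amplifies if any template
    yields a product.  Row and column order follow the input order.
    """
    pair_map = _as_pairs(pairs)
    templates = _as_templates(panel)
    m = AmplificationMatrix(
        pair_names=list(pair_map), sample_names=list(templates), products={}
    )
    for pname, (fwd, rev) in pair_map.items():
        for sname, seqs in templates.items():
            sizes: list[int] = []
            for t in seqs:
                sizes.extend(
                    a.length
                    for a in predict_amplicons((fwd, rev), t, size_range, rules, sname)
                )
            m.products[(pname, sname)] = sorted(sizes)
    return m
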