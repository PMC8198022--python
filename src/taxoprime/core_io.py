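"""Data model and readers/writers for marker-gene sequence panels.

Sequences are genus/species/strain-labeled nucleotide records tied to a
marker gene (16S, rbcLX, rpoB, rpoC1, cpcBA, ...).  Pairwise percent
similarities live in :class:`SimilarityMatrix`, whose on-disk dialect is a
tab-separated lower triangle with a header row of taxon labels — the layout
similarity tables are conventionally printed in.  Per-species consensus
("common sequence") construction collapses conspecific strains so that
within-species SNPs do not leak into between-taxon statistics.

Coordinates are 0-based half-open alignment columns throughout; primers are
always written 5'->3'.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import dendropy

__all__ = [
    "SeqRecord",
    "Alignment",
    "GenusPanel",
    "SimilarityMatrix",
    "PrimerRecord",
    "read_fasta",
    "write_fasta",
    "build_common_sequence",
    "read_newick",
    "read_primer_table",
    "write_primer_table",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "round1",
]

#: Characters allowed in a normalized nucleotide sequence.
ALPHABET = frozenset("ACGTN-RYSWKMBDHV")

#: IUPAC ambiguity code for each set of bases it covers.
IUPAC_CODES: dict[frozenset[str], str] = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


def round1(x: float) -> float:
    """Round to one decimal with half-up ties (printed-table convention)."""
    import decimal

    return float(
        decimal.Decimal(repr(float(x))).quantize(
            decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP
        )
    )


def _normalize_sequence(seq: str) -> str:
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - ALPHABET
    if bad:
        raise ValueError(f"sequence contains invalid characters: {sorted(bad)!r}")
    if not s:
        raise ValueError("sequence is empty")
    return s


@dataclass
class SeqRecord:
    """A genus/species/strain-labeled nucleotide sequence for one marker."""

    genus: str
    species: str
    sequence: str
    strain: str = ""
    marker: str = ""
    id: str = ""

    def __post_init__(self) -> None:
        if not self.genus or not self.species:
            raise ValueError("genus and species labels must be non-empty")
        self.sequence = _normalize_sequence(self.sequence)
        if not self.id:
            self.id = "|".join(
                t for t in (self.genus, self.species, self.strain, self.marker)
            )

    @property
    def taxon(self) -> tuple[str, str]:
        return (self.genus, self.species)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Alignment:
    """An aligned, genus-labeled set of records for one marker gene."""

    marker: str
    records: list[SeqRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("alignment needs at least 2 records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"records have unequal lengths: {sorted(lengths)}")
        if self.length == 0:
            raise ValueError("alignment has zero columns")

    @property
    def length(self) -> int:
        return len(self.records[0])

    def to_array(self) -> np.ndarray:
        """Rows x columns matrix of single characters."""
        return np.array([list(r.sequence) for r in self.records], dtype="U1")

    def genera(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.genus, None)
        return list(seen)

    def rows_for_genus(self, genus: str) -> list[int]:
        return [i for i, r in enumerate(self.records) if r.genus == genus]

    def slice_columns(self, start: int, end: int) -> "Alignment":
        if not (0 <= start < end <= self.length):
            raise ValueError(f"invalid column range [{start}, {end})")
        recs = [replace(r, sequence=r.sequence[start:end]) for r in self.records]
        return Alignment(marker=self.marker, records=recs)


@dataclass
class GenusPanel:
    """Records for one marker grouped by genus."""

    marker: str
    members: dict[str, list[SeqRecord]]

    def __post_init__(self) -> None:
        for genus, recs in self.members.items():
            if not genus:
                raise ValueError("empty genus key")
            for r in recs:
                if r.genus != genus:
                    raise ValueError(
                        f"record {r.id!r} has genus {r.genus!r} under key {genus!r}"
                    )

    @classmethod
    def from_records(cls, records: Iterable[SeqRecord], marker: str = "") -> "GenusPanel":
        members: dict[str, list[SeqRecord]] = {}
        for r in records:
            members.setdefault(r.genus, []).append(r)
        if not marker:
            markers = {r.marker for rs in members.values() for r in rs}
            marker = markers.pop() if len(markers) == 1 else ""
        return cls(marker=marker, members=members)

    def genera(self) -> list[str]:
        return list(self.members)


class SimilarityMatrix:
    """Symmetric matrix of pairwise percent similarities between taxa.

    The diagonal is identically 100 and is excluded from every summary.
    Values are stored at full precision; :meth:`rounded` gives the
    one-decimal reporting view.
    """

    def __init__(
        self,
        marker: str,
        taxa: Sequence[tuple[str, str]],
        values: np.ndarray,
        aligned_length: int = 0,
        *,
        atol: float = 0.05,
    ) -> None:
        values = np.asarray(values, dtype=float)
        t = len(taxa)
        if values.shape != (t, t):
            raise ValueError(f"matrix shape {values.shape} does not match {t} taxa")
        if len(set(taxa)) != t:
            dups = [x for x, c in Counter(taxa).items() if c > 1]
            raise ValueError(f"duplicate taxa: {dups}")
        if np.max(np.abs(values - values.T)) > atol:
            raise ValueError("matrix is asymmetric beyond tolerance 0.05")
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 100.0)
        if np.any(values < 0) or np.any(values > 100):
            raise ValueError("similarities must lie in [0, 100]")
        self.marker = marker
        self.taxa = [tuple(x) for x in taxa]
        self.values = values
        self.aligned_length = int(aligned_length)

    def __len__(self) -> int:
        return len(self.taxa)

    def labels(self) -> list[str]:
        return [f"{g} {s}" if s else g for g, s in self.taxa]

    def index_of(self, taxon) -> int:
        """Locate a taxon given as (genus, species), 'Genus species' or a label."""
        if isinstance(taxon, str):
            try:
                return self.labels().index(taxon)
            except ValueError:
                parts = taxon.split(None, 1)
                taxon = (parts[0], parts[1] if len(parts) > 1 else "")
        taxon = tuple(taxon)
        try:
            return self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in matrix") from None

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(len(self), k=1)
        return self.values[iu]

    def rounded(self) -> np.ndarray:
        out = self.values.copy()
        it = np.nditer(out, flags=["multi_index"], op_flags=["readwrite"])
        for v in it:
            v[...] = round1(float(v))
        return out


@dataclass
class PrimerRecord:
    """One published/designed primer (always written 5'->3')."""

    name: str
    target_genus: str
    marker: str
    sequence: str
    orientation: str
    annealing_temp: float = 0.0
    product_size: int = 0

    def __post_init__(self) -> None:
        self.sequence = self.sequence.strip().upper().replace("U", "T")
        if len(self.sequence) < 10:
            raise ValueError(f"primer {self.name!r} shorter than 10 nt")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"primer {self.name!r} has non-ACGT characters")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")
        if self.product_size and self.product_size <= 0:
            raise ValueError("product_size must be positive when set")


# ---------------------------------------------------------------------------
# FASTA

def _pipe_label_scheme(header: str) -> dict[str, str]:
    """Default 'genus|species|strain|marker' header scheme."""
    parts = header.split("|")
    if len(parts) < 2 or not parts[0] or not parts[1]:
        raise ValueError(
            f"header {header!r} does not match 'genus|species|strain|marker'"
        )
    parts += [""] * (4 - len(parts))
    return {
        "genus": parts[0],
        "species": parts[1],
        "strain": parts[2],
        "marker": parts[3],
    }


def _regex_label_scheme(pattern: str) -> Callable[[str], dict[str, str]]:
    rx = re.compile(pattern)

    def scheme(header: str) -> dict[str, str]:
        m = rx.match(header)
        if not m or "genus" not in m.groupdict() or not m.group("genus"):
            raise ValueError(f"header {header!r} does not match {pattern!r}")
        g = m.groupdict()
        return {
            "genus": g.get("genus", ""),
            "species": g.get("species", "") or "sp",
            "strain": g.get("strain", "") or "",
            "marker": g.get("marker", "") or "",
        }

    return scheme


def read_fasta(path, label_scheme="pipe") -> list[SeqRecord]:
    """Read labeled sequences from FASTA.

    ``label_scheme`` is ``"pipe"`` (genus|species|strain|marker headers), a
    regex with named groups, or a callable header -> field dict.
    """
    if label_scheme == "pipe":
        scheme = _pipe_label_scheme
    elif callable(label_scheme):
        scheme = label_scheme
    else:
        scheme = _regex_label_scheme(label_scheme)

    from Bio import SeqIO

    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty FASTA file")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ValueError(f"{path}:{lineno}: expected '>' header, got {line!r}")
            break

    records: list[SeqRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        fields = scheme(header)
        records.append(SeqRecord(sequence=str(rec.seq), **fields))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for r in records:
            header = "|".join((r.genus, r.species, r.strain, r.marker))
            fh.write(f">{header}\n")
            for i in range(0, len(r.sequence), 70):
                fh.write(r.sequence[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Species consensus ("common sequence")

def build_common_sequence(records: Sequence[SeqRecord], policy: str = "iupac") -> SeqRecord:
    """Collapse conspecific, pre-aligned strains to one consensus record.

    Per column: the majority base wins; a column is emitted as a gap only if
    gaps hold a strict majority.  Base ties are resolved per ``policy``:
    ``"iupac"`` (default) emits the ambiguity code covering the tied bases,
    ``"first"`` picks the alphabetically first tied base.
    """
    if not records:
        raise ValueError("no records given")
    species = {(r.genus, r.species) for r in records}
    if len(species) != 1:
        raise ValueError(f"records span multiple species: {sorted(species)}")
    lengths = {len(r) for r in records}
    if len(lengths) != 1:
        raise ValueError("records must be pre-aligned to equal length")
    if policy not in ("iupac", "first"):
        raise ValueError(f"unknown tie policy {policy!r}")

    n = len(records)
    out = []
    for col in zip(*(r.sequence for r in records)):
        counts = Counter(col)
        gaps = counts.pop("-", 0)
        if gaps > n / 2:
            out.append("-")
            continue
        if not counts:  # all gaps but not strict majority impossible unless n==0
            out.append("-")
            continue
        top = max(counts.values())
        tied = sorted(b for b, c in counts.items() if c == top)
        if len(tied) == 1:
            out.append(tied[0])
        elif policy == "first":
            out.append(tied[0])
        else:
            key = frozenset(tied)
            if key in IUPAC_CODES:
                out.append(IUPAC_CODES[key])
            else:  # ties involving N/ambiguity fall back to N
                out.append("N")

    r0 = records[0]
    strain = r0.strain if n == 1 else "consensus"
    return SeqRecord(
        genus=r0.genus,
        species=r0.species,
        strain=strain,
        marker=r0.marker,
        sequence="".join(out),
    )


# ---------------------------------------------------------------------------
# Trees, primer tables, similarity matrices

def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


_PRIMER_COLUMNS = [
    "name",
    "target_genus",
    "marker",
    "orientation",
    "sequence",
    "annealing_temp",
    "product_size",
]


def read_primer_table(path) -> list[PrimerRecord]:
    """Read a TSV primer table (name, genus, marker, orientation, sequence,
    annealing temperature in deg C, product size in bp)."""
    path = Path(path)
    out: list[PrimerRecord] = []
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_PRIMER_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            out.append(
                PrimerRecord(
                    name=row["name"],
                    target_genus=row["target_genus"],
                    marker=row["marker"],
                    orientation=row["orientation"],
                    sequence=row["sequence"],
                    annealing_temp=float(row["annealing_temp"] or 0),
                    product_size=int(row["product_size"] or 0),
                )
            )
    if not out:
        raise ValueError(f"{path}: no primer rows")
    return out


def write_primer_table(primers: Iterable[PrimerRecord], path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_PRIMER_COLUMNS)
        for p in primers:
            w.writerow(
                [
                    p.name,
                    p.target_genus,
                    p.marker,
                    p.orientation,
                    p.sequence,
                    f"{p.annealing_temp:g}",
                    p.product_size,
                ]
            )


def _parse_taxon_label(label: str) -> tuple[str, str]:
    parts = label.strip().split(None, 1)
    return (parts[0], parts[1] if len(parts) > 1 else "")


def read_similarity_matrix(path) -> SimilarityMatrix:
    """Read a similarity matrix TSV.

    The dialect is a lower triangle: ``# marker:`` / ``# aligned_length:``
    comment lines, a header row of taxon labels, then one row per taxon with
    its label and the similarities to every earlier taxon.  A full square
    matrix is also accepted and checked for symmetry (tolerance 0.05).
    """
    path = Path(path)
    marker = ""
    aligned_length = 0
    rows: list[list[str]] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                m = re.match(r"#\s*(marker|aligned_length)\s*:\s*(\S+)", line)
                if m:
                    if m.group(1) == "marker":
                        marker = m.group(2)
                    else:
                        aligned_length = int(m.group(2))
                continue
            if line.strip():
                rows.append(line.split("\t"))
    if len(rows) < 2:
        raise ValueError(f"{path}: no matrix rows found")
    header = [h for h in rows[0][1:] if h.strip()]
    taxa = [_parse_taxon_label(h) for h in header]
    t = len(taxa)
    body = rows[1:]
    if len(body) != t:
        raise ValueError(f"{path}: {len(body)} data rows for {t} taxa")

    values = np.full((t, t), np.nan)
    np.fill_diagonal(values, 100.0)
    full_square = any(len(r) - 1 > i for i, r in enumerate(body))
    for i, row in enumerate(body):
        label = _parse_taxon_label(row[0])
        if label != taxa[i]:
            raise ValueError(f"{path}: row {i} label {label} != header {taxa[i]}")
        vals = [v for v in row[1:] if v.strip()]
        expect = t if full_square else i
        if full_square and len(vals) not in (t, i):
            raise ValueError(f"{path}: row {i} has {len(vals)} values")
        if not full_square and len(vals) != i:
            raise ValueError(f"{path}: row {i} has {len(vals)} values, expected {i}")
        for j, v in enumerate(vals):
            values[i, j] = float(v)

    if full_square:
        mat = values
        if np.isnan(mat).any():
            # mixed triangle/full rows: mirror what is present
            lower = np.where(np.isnan(mat), 0.0, mat)
            mat = np.where(np.isnan(mat), lower.T, mat)
    else:
        iu = np.triu_indices(t, k=1)
        values[iu] = values.T[iu]
        mat = values
    return SimilarityMatrix(marker=marker, taxa=taxa, values=mat, aligned_length=aligned_length)


def write_similarity_matrix(m: SimilarityMatrix, path) -> None:
    """Write the lower-triangle TSV dialect at one-decimal precision."""
    vals = m.rounded()
    labels = m.labels()
    with Path(path).open("w") as fh:
        fh.write(f"# marker: {m.marker}\n")
        fh.write(f"# aligned_length: {m.aligned_length}\n")
        fh.write("taxon\t" + "\t".join(labels) + "\n")
        for i, lab in enumerate(labels):
            row = [lab] + [f"{vals[i, j]:.1f}" for j in range(i)]
            fh.write("\t".join(row) + "\n")
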