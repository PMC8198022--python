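"""Packaged reference data.

Small plain-text fixtures ship inside the distribution so the full pipeline
is exercisable offline: the published pairwise percent-similarity matrices
of five nostocalean marker genes (16S rRNA, rbcLX, cpcBA, rpoB, rpoC1)
among cultured genera, and the five wet-lab-validated genus-specific primer
pairs those analyses produced.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .core_io import PrimerRecord, SimilarityMatrix, read_primer_table, read_similarity_matrix

__all__ = ["MARKERS", "fixture_path", "load_similarity_matrix", "load_all_matrices", "load_primer_table"]

MARKERS = ("16S", "rbcLX", "cpcBA", "rpoB", "rpoC1")


def fixture_path(name: str) -> Path:
    path = resources.files("taxoprime").joinpath("data", name)
    return Path(str(path))


def load_similarity_matrix(marker: str) -> SimilarityMatrix:
    """Published similarity matrix for one marker gene."""
    if marker not in MARKERS:
        raise KeyError(f"unknown marker {marker!r}; choose from {MARKERS}")
    return read_similarity_matrix(fixture_path(f"similarity_{marker}.tsv"))


def load_all_matrices() -> dict[str, SimilarityMatrix]:
    return {m: load_similarity_matrix(m) for m in MARKERS}


def load_primer_table() -> list[PrimerRecord]:
    """The five published genus-specific primer pairs (10 primers)."""
    return read_primer_table(fixture_path("genus_primers.tsv"))
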