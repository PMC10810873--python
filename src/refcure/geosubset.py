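"""Geographic subsetting by flora checklist and coverage reporting.

A country-level (or any regional) reference dataset is obtained by
keeping only the species listed in a flora checklist CSV. Checklist
names are normalized to bare binomials: case-insensitive, underscores
and spaces interchangeable, authorship stripped, infraspecific ranks
(subsp./var./f.) truncated. The coverage report gives the number of
sequences, the number of checklist species that have at least one
sequence, the checklist size, and their ratio as an integer percentage.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import IO, Iterable

from .curate import _round_half_up
from .taxfasta import Dataset

logger = logging.getLogger(__name__)

_RANK_MARKERS = {
    "subsp.", "subsp", "ssp.", "ssp", "var.", "var", "f.", "forma",
    "subvar.", "subvar", "cv.", "cv",
}
_HEADER_TOKENS = {"species", "species_name", "scientific_name", "scientificname", "name", "taxon"}


def normalize_binomial(name: str) -> str:
    """Reduce a checklist name to a normalized ``genus_epithet`` key.

    Tokens after the epithet (authorship, infraspecific rank + epithet)
    are dropped; hybrid signs are ignored.
    """
    tokens = [t for t in name.replace("_", " ").split() if t not in ("x", "×")]
    return "_".join(tokens[:2]).lower()


@dataclass(frozen=True)
class FloraChecklist:
    species: frozenset[str]  # normalized binomials
    source: str = ""

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("flora checklist must be non-empty")

    def __contains__(self, binomial: str) -> bool:
        return normalize_binomial(binomial) in self.species

    def __len__(self) -> int:
        return len(self.species)


def parse_flora_list(
    stream: IO[str] | Iterable[str],
    column: str | None = None,
    source: str = "",
) -> FloraChecklist:
    """Read a flora checklist CSV into a normalized species set.

    Species names are taken from the first column by default, or from
    the named header column. A leading header row with a recognizable
    title (``species``, ``name`` ...) is skipped automatically.
    """
    rows = [r for r in csv.reader(stream) if r and any(c.strip() for c in r)]
    if not rows:
        raise ValueError("empty flora checklist")
    col = 0
    start = 0
    header = [c.strip().lower() for c in rows[0]]
    if column is not None:
        if column.lower() not in header:
            raise ValueError(f"column {column!r} not found in checklist header")
        col = header.index(column.lower())
        start = 1
    elif header[0] in _HEADER_TOKENS:
        start = 1
    names = {
        normalize_binomial(row[col])
        for row in rows[start:]
        if len(row) > col and row[col].strip()
    }
    names.discard("")
    if not names:
        raise ValueError("flora checklist contains no species names")
    return FloraChecklist(species=frozenset(names), source=source)


def subset_dataset(ds: Dataset, flora: FloraChecklist) -> Dataset:
    """Keep only records whose species binomial is in the checklist."""
    keep = [
        rec
        for rec in ds
        if normalize_binomial(rec.taxonomy.species) in flora.species
    ]
    if not keep:
        logger.warning("flora checklist shares no species with the dataset")
    return Dataset(keep)


@dataclass(frozen=True)
class CoverageReport:
    n_sequences: int
    n_species_with_sequences: int
    n_flora_species: int
    coverage_percent: int


def coverage_report(ds_subset: Dataset, flora: FloraChecklist) -> CoverageReport:
    """Table of checklist coverage by the (already subset) dataset."""
    species = {normalize_binomial(r.taxonomy.species) for r in ds_subset}
    covered = len(species & flora.species)
    return CoverageReport(
        n_sequences=len(ds_subset),
        n_species_with_sequences=covered,
        n_flora_species=len(flora),
        coverage_percent=coverage_percent(covered, len(flora)),
    )


def coverage_percent(n_species_with_sequences: int, n_flora_species: int) -> int:
    """Integer (half-up) percentage of checklist species represented."""
    if n_flora_species <= 0:
        raise ValueError("flora species count must be positive")
    return _round_half_up(100.0 * n_species_with_sequences / n_flora_species)


def write_coverage_tsv(report: CoverageReport, stream: IO[str]) -> None:
    stream.write(
        "n_sequences\tn_species_with_sequences\tn_flora_species\tcoverage_percent\n"
    )
    stream.write(
        f"{report.n_sequences}\t{report.n_species_with_sequences}\t"
        f"{report.n_flora_species}\t{report.coverage_percent}\n"
    )
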