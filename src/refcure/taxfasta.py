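"""Taxonomy-annotated FASTA I/O and the in-memory dataset model.

The header dialect is the SINTAX-compatible one consumed by common
k-mer/direct-hit classifiers::

    >ACC123;tax=k:Viridiplantae,p:Streptophyta,c:Magnoliopsida,o:Rosales,f:Rosaceae,g:Malus,s:Malus_pumila;

A single space is also accepted between the accession and the ``tax=``
annotation on input; output is always canonical (semicolon separator,
spaces in names replaced by underscores, one sequence line per record).
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

logger = logging.getLogger(__name__)

#: rank attribute names in lineage order (kingdom -> species)
RANKS = ("kingdom", "phylum", "class_", "order", "family", "genus", "species")

#: single-letter rank codes; ``d`` (domain) is accepted as an alias of kingdom
RANK_LETTERS = {
    "k": "kingdom",
    "d": "kingdom",
    "p": "phylum",
    "c": "class_",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}

_SERIAL_LETTERS = ("k", "p", "c", "o", "f", "g", "s")

#: species epithets that do not identify a species, hence make a lineage
#: unusable for barcoding even though the field is non-empty
DEFAULT_PLACEHOLDER_EPITHETS = frozenset(
    {"sp", "spp", "cf", "aff", "x", "hybrid", "unclassified", "environmental", "indet"}
)

IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

_TAX_RE = re.compile(r"tax=([^;]*);?")


class TaxfastaError(ValueError):
    """Malformed taxonomy-FASTA input."""


@dataclass(frozen=True)
class TaxonomyString:
    """Ordered seven-rank lineage; empty string marks an unknown rank.

    ``species`` uses the ``Genus_epithet`` convention (underscore, not
    space); :meth:`serialize` enforces it for all ranks.
    """

    kingdom: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def as_tuple(self) -> tuple[str, ...]:
        return tuple(getattr(self, r) for r in RANKS)

    def serialize(self) -> str:
        parts = ",".join(
            f"{letter}:{getattr(self, rank).replace(' ', '_')}"
            for letter, rank in zip(_SERIAL_LETTERS, RANKS)
        )
        return f"tax={parts};"

    def epithet(self) -> str:
        """The part of the species name after the genus, '' if absent."""
        if "_" in self.species:
            return self.species.split("_", 1)[1]
        return ""

    def missing_ranks(
        self, placeholders: frozenset[str] = DEFAULT_PLACEHOLDER_EPITHETS
    ) -> list[str]:
        """Ranks that are empty or carry a placeholder species epithet."""
        missing = [r for r in RANKS if not getattr(self, r)]
        if self.species and "species" not in missing:
            epi = self.epithet().rstrip(".").lower()
            if not epi or epi in placeholders:
                missing.append("species")
        return missing

    def is_complete(
        self, placeholders: frozenset[str] = DEFAULT_PLACEHOLDER_EPITHETS
    ) -> bool:
        return not self.missing_ranks(placeholders)

    def replace(self, **changes: str) -> "TaxonomyString":
        return dataclasses.replace(self, **changes)


def normalize_sequence(seq: str) -> str:
    """Uppercase, map RNA U to T, and validate IUPAC nucleotide codes."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - IUPAC_CODES
    if bad:
        raise TaxfastaError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return s


@dataclass
class SeqRecord:
    """One barcode sequence with its accession, lineage and provenance."""

    accession: str
    taxonomy: TaxonomyString
    sequence: str
    source: str = "imported"  # "imported" | "manual"
    flags: set = field(default_factory=set, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not self.accession:
            raise TaxfastaError("accession must be non-empty")
        if not self.sequence:
            raise TaxfastaError(f"{self.accession}: sequence must be non-empty")
        bad = set(self.sequence) - IUPAC_CODES
        if bad:
            raise TaxfastaError(
                f"{self.accession}: non-IUPAC characters {sorted(bad)}"
            )

    @property
    def species(self) -> str:
        return self.taxonomy.species

    def header(self) -> str:
        return f">{self.accession};{self.taxonomy.serialize()}"


class Dataset:
    """Accession-keyed, insertion-ordered collection of :class:`SeqRecord`."""

    def __init__(self, records: Iterable[SeqRecord] = ()) -> None:
        self._records: list[SeqRecord] = []
        self._by_acc: dict[str, SeqRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: SeqRecord) -> None:
        if rec.accession in self._by_acc:
            raise TaxfastaError(f"duplicate accession {rec.accession!r}")
        self._records.append(rec)
        self._by_acc[rec.accession] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SeqRecord]:
        return iter(self._records)

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_acc

    def __getitem__(self, accession: str) -> SeqRecord:
        return self._by_acc[accession]

    def get(self, accession: str) -> SeqRecord | None:
        return self._by_acc.get(accession)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self._records == other._records

    @property
    def accessions(self) -> list[str]:
        return [r.accession for r in self._records]

    def species_index(self) -> dict[str, list[SeqRecord]]:
        """Map species name -> records, in insertion order."""
        idx: dict[str, list[SeqRecord]] = {}
        for rec in self._records:
            idx.setdefault(rec.species, []).append(rec)
        return idx

    def n_species(self) -> int:
        return len({r.species for r in self._records})

    def without(self, accessions: Iterable[str]) -> "Dataset":
        drop = set(accessions)
        return Dataset(r for r in self._records if r.accession not in drop)

    def only(self, accessions: Iterable[str]) -> "Dataset":
        keep = set(accessions)
        return Dataset(r for r in self._records if r.accession in keep)


def parse_taxonomy(header_tail: str) -> TaxonomyString:
    """Parse the ``tax=k:...,p:...,...;`` span of a header.

    Unknown rank letters are ignored with a warning; ``d:`` is accepted
    as an alias for the kingdom rank.
    """
    m = _TAX_RE.search(header_tail)
    if m is None:
        raise TaxfastaError(f"no 'tax=' annotation in header: {header_tail!r}")
    fields: dict[str, str] = {}
    for item in m.group(1).split(","):
        if not item.strip():
            continue
        letter, _, name = item.partition(":")
        letter = letter.strip().lower()
        rank = RANK_LETTERS.get(letter)
        if rank is None:
            logger.warning("ignoring unknown rank letter %r in %r", letter, header_tail)
            continue
        fields[rank] = name.strip()
    return TaxonomyString(**fields)


def _parse_header(line: str) -> tuple[str, TaxonomyString]:
    body = line[1:].strip()
    # accession terminated by ';' (canonical) or first whitespace
    m = re.match(r"([^;\s]+)[;\s]", body)
    if not m:
        raise TaxfastaError(f"cannot extract accession from header: {line!r}")
    return m.group(1), parse_taxonomy(body)


def parse_taxfasta(
    stream: IO[str] | Iterable[str], source: str = "imported"
) -> tuple[Dataset, list[tuple[str, str]]]:
    """Read taxonomy-FASTA text into a :class:`Dataset`.

    Returns ``(dataset, warnings)`` where warnings is a list of
    ``(accession, issue)`` pairs. Duplicate accessions keep the first
    record; later ones are dropped and reported (curation must never
    silently merge sequences). Input sequence wrapping is accepted.
    """
    ds = Dataset()
    warnings: list[tuple[str, str]] = []
    acc: str | None = None
    tax: TaxonomyString | None = None
    chunks: list[str] = []

    def flush() -> None:
        nonlocal acc, tax, chunks
        if acc is None:
            return
        seq = normalize_sequence("".join(chunks))
        if not seq:
            raise TaxfastaError(f"empty sequence for {acc!r}")
        rec = SeqRecord(acc, tax, seq, source=source)
        if acc in ds:
            warnings.append((acc, "duplicate_accession_dropped"))
            logger.warning("duplicate accession %s: keeping first occurrence", acc)
        else:
            ds.add(rec)
        acc, tax, chunks = None, None, []

    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            flush()
            acc, tax = _parse_header(line)
        else:
            if acc is None:
                raise TaxfastaError(
                    f"line {lineno}: sequence data before any FASTA header"
                )
            chunks.append(line.strip())
    flush()
    return ds, warnings


def write_taxfasta(ds: Dataset, stream: IO[str]) -> None:
    """Write canonical dialect: one header + one sequence line per record."""
    for rec in ds:
        stream.write(rec.header() + "\n")
        stream.write(rec.sequence + "\n")


def load_taxfasta(path: str, source: str = "imported") -> tuple[Dataset, list[tuple[str, str]]]:
    with open(path) as fh:
        return parse_taxfasta(fh, source=source)


def dump_taxfasta(ds: Dataset, path: str) -> None:
    with open(path, "w") as fh:
        write_taxfasta(ds, fh)
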