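"""Community manual-list curation and manual sequence addition.

Curation lists are simple semicolon-delimited text contributed by the
user community, one action per line::

    NCBIAccessionNumber;WrongScientificName;CorrectedScientificName;CuratorName

An empty corrected-name field means the record is removed; otherwise its
genus/species are rewritten from the corrected binomial and, when an
offline taxonomy table resolves the binomial, all higher ranks too.
Manual sequence addition ingests plain FASTA whose headers are species
names and attaches full lineages from the same taxonomy table.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import IO, Iterable

from .taxfasta import RANKS, Dataset, SeqRecord, TaxonomyString, normalize_sequence

logger = logging.getLogger(__name__)


class CurationListError(ValueError):
    """Malformed manual curation list."""


@dataclass(frozen=True)
class CurationEntry:
    accession: str
    wrong_name: str
    corrected_name: str  # empty -> removal semantics
    curator: str

    @property
    def is_removal(self) -> bool:
        return not self.corrected_name.strip()


def parse_curation_list(stream: IO[str] | Iterable[str]) -> list[CurationEntry]:
    """Parse a 4-field semicolon-delimited curation list.

    Lines starting with ``#`` and blank lines are ignored; any other
    line must have exactly four fields or parsing fails with the line
    number.
    """
    entries: list[CurationEntry] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split(";")
        if len(parts) != 4:
            raise CurationListError(
                f"line {lineno}: expected 4 ';'-separated fields, got {len(parts)}"
            )
        acc, wrong, corrected, curator = (p.strip() for p in parts)
        if not acc or not curator:
            raise CurationListError(
                f"line {lineno}: accession and curator must be non-empty"
            )
        entries.append(CurationEntry(acc, wrong, corrected, curator))
    return entries


def _normalize_binomial(name: str) -> str:
    return "_".join(name.replace("_", " ").split()).lower()


class TaxonomySource:
    """Offline species-binomial -> full-lineage lookup from a 7-column TSV.

    The TSV has a header row with the rank names (kingdom ... species).
    Lookups are case-insensitive on normalized binomials; misses are
    reported by returning None, never guessed.
    """

    HEADER = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

    def __init__(self, mapping: dict[str, TaxonomyString]):
        self._map = mapping

    @classmethod
    def from_tsv(cls, stream: IO[str] | Iterable[str]) -> "TaxonomySource":
        reader = csv.reader(stream, delimiter="\t")
        rows = list(reader)
        if not rows:
            raise ValueError("empty taxonomy table")
        header = [h.strip().lower() for h in rows[0]]
        if header[: len(cls.HEADER)] != list(cls.HEADER):
            raise ValueError(
                f"taxonomy table header must be {cls.HEADER}, got {tuple(header)}"
            )
        mapping: dict[str, TaxonomyString] = {}
        for row in rows[1:]:
            if not any(cell.strip() for cell in row):
                continue
            vals = [c.strip().replace(" ", "_") for c in row[:7]]
            tax = TaxonomyString(**dict(zip(RANKS, vals)))
            mapping[_normalize_binomial(tax.species)] = tax
        return cls(mapping)

    @classmethod
    def from_tsv_path(cls, path: str) -> "TaxonomySource":
        with open(path) as fh:
            return cls.from_tsv(fh)

    def lookup(self, binomial: str) -> TaxonomyString | None:
        return self._map.get(_normalize_binomial(binomial))


def _parse_binomial(name: str) -> tuple[str, str]:
    """Split a corrected name into (genus, species).

    First token is the genus, the remainder the epithet. A single-token
    name (genus-level knowledge only) yields species ``Genus_sp``, which
    deliberately fails the completeness check so the record is flagged
    downstream rather than silently kept.
    """
    tokens = name.replace("_", " ").split()
    genus = tokens[0]
    if len(tokens) == 1:
        return genus, f"{genus}_sp"
    return genus, f"{genus}_" + "_".join(tokens[1:])


@dataclass
class CurationActions:
    removed: list[str]
    corrected: list[str]
    unmatched: list[str]
    needs_review: list[str]


def apply_curation_list(
    ds: Dataset,
    entries: list[CurationEntry],
    tax_source: TaxonomySource | None = None,
) -> tuple[Dataset, CurationActions]:
    """Apply removals and taxonomy corrections to a dataset.

    Later entries for the same accession override earlier ones (multiple
    contributor files), with a logged conflict. Accessions absent from
    the dataset are reported as unmatched, never an error.
    """
    effective: dict[str, CurationEntry] = {}
    for e in entries:
        if e.accession in effective:
            logger.warning(
                "conflicting curation entries for %s: keeping the later one (%s)",
                e.accession,
                e.curator,
            )
        effective[e.accession] = e

    actions = CurationActions([], [], [], [])
    out: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in ds:
        e = effective.get(rec.accession)
        if e is None:
            out.append(rec)
            continue
        seen.add(rec.accession)
        if e.is_removal:
            actions.removed.append(rec.accession)
            continue
        genus, species = _parse_binomial(e.corrected_name)
        full = tax_source.lookup(e.corrected_name) if tax_source else None
        if full is not None:
            new_tax = full.replace(genus=genus, species=species)
        else:
            new_tax = rec.taxonomy.replace(genus=genus, species=species)
        new_rec = SeqRecord(
            rec.accession, new_tax, rec.sequence, source=rec.source,
            flags=set(rec.flags),
        )
        if full is None:
            new_rec.flags.add("needs_review")
            actions.needs_review.append(rec.accession)
        actions.corrected.append(rec.accession)
        out.append(new_rec)
    actions.unmatched = sorted(set(effective) - seen)
    return Dataset(out), actions


def parse_species_fasta(stream: IO[str] | Iterable[str]) -> list[tuple[str, str]]:
    """Parse plain FASTA with free-text species names as headers."""
    out: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []

    def flush(lineno: int) -> None:
        nonlocal name, chunks
        if name is None:
            return
        seq = normalize_sequence("".join(chunks))
        if not seq:
            raise ValueError(f"line {lineno}: empty sequence for {name!r}")
        out.append((name, seq))
        name, chunks = None, []

    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            flush(lineno)
            name = line[1:].strip()
        else:
            if name is None:
                raise ValueError(f"line {lineno}: sequence data before any header")
            chunks.append(line.strip())
    flush(-1)
    return out


def add_sequences(
    ds: Dataset,
    new: list[tuple[str, str]],
    tax_source: TaxonomySource,
    id_prefix: str = "MANUAL",
) -> tuple[Dataset, list[str], list[str]]:
    """Append user sequences with taxonomy resolved from the table.

    Each resolvable species gains a record with a generated accession
    ``{id_prefix}_{NNNN}`` that never collides with existing accessions;
    unresolvable species are reported and skipped. Pre-existing records
    are untouched (append-only).
    """
    out = Dataset(ds)
    added: list[str] = []
    unresolved: list[str] = []
    ordinal = 1
    for species_name, seq in new:
        tax = tax_source.lookup(species_name)
        if tax is None:
            unresolved.append(species_name)
            continue
        while f"{id_prefix}_{ordinal:04d}" in out:
            ordinal += 1
        acc = f"{id_prefix}_{ordinal:04d}"
        ordinal += 1
        out.add(SeqRecord(acc, tax, seq, source="manual"))
        added.append(acc)
    return out, added, unresolved


def write_actions_tsv(actions: CurationActions, entries: list[CurationEntry], stream: IO[str]) -> None:
    by_acc = {e.accession: e for e in entries}
    stream.write("accession\taction\tdetail\tcurator\n")
    for acc in actions.removed:
        e = by_acc.get(acc)
        stream.write(f"{acc}\tremoved\twrong_name={e.wrong_name if e else ''}\t{e.curator if e else ''}\n")
    for acc in actions.corrected:
        e = by_acc.get(acc)
        flag = ";needs_review" if acc in actions.needs_review else ""
        stream.write(
            f"{acc}\tcorrected\tnew_name={e.corrected_name if e else ''}{flag}\t{e.curator if e else ''}\n"
        )
    for acc in actions.unmatched:
        e = by_acc.get(acc)
        stream.write(f"{acc}\tunmatched\t\t{e.curator if e else ''}\n")
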