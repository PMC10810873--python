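import io

import pytest

from refcure.manual import (
    CurationListError,
    TaxonomySource,
    add_sequences,
    apply_curation_list,
    parse_curation_list,
    parse_species_fasta,
)
from refcure.taxfasta import Dataset, SeqRecord, TaxonomyString

TAXONOMY_TSV = """kingdom\tphylum\tclass\torder\tfamily\tgenus\tspecies
Viridiplantae\tStreptophyta\tMagnoliopsida\tAsterales\tAsteraceae\tTaraxacum\tTaraxacum officinale
Viridiplantae\tStreptophyta\tMagnoliopsida\tLamiales\tLamiaceae\tLavandula\tLavandula angustifolia
"""


def tax(genus="Typha", species="Typha_angustifolia", family="Typhaceae"):
    return TaxonomyString(
        "Viridiplantae", "Streptophyta", "Magnoliopsida", "Poales",
        family, genus, species,
    )


def dataset(n=10):
    return Dataset(
        SeqRecord(f"KF{i:03d}", tax(species=f"Typha_angustifolia{i}"), "ACGTACGT")
        for i in range(n)
    )


@pytest.fixture
def tax_source():
    return TaxonomySource.from_tsv(io.StringIO(TAXONOMY_TSV))


class TestParseCurationList:
    def test_correction_entry(self):
        entries = parse_curation_list(
            io.StringIO("KF454376;Typha angustifolia;Taraxacum officinale;AQ\n")
        )
        assert len(entries) == 1
        e = entries[0]
        assert e.accession == "KF454376" and not e.is_removal
        assert e.corrected_name == "Taraxacum officinale"

    def test_empty_corrected_field_means_removal(self):
        (e,) = parse_curation_list(io.StringIO("X1;Bad name;;AQ\n"))
        assert e.is_removal

    def test_wrong_field_count_names_line(self):
        with pytest.raises(CurationListError, match="line 2"):
            parse_curation_list(io.StringIO("# comment\nX1;only;three\n"))

    def test_comments_and_blank_lines_skipped(self):
        entries = parse_curation_list(io.StringIO("# c\n\nX1;a;;AQ\n"))
        assert len(entries) == 1


class TestApplyCurationList:
    def test_removals_and_corrections(self, tax_source):
        ds = dataset(10)
        lines = [
            "KF000;x;;AQ",
            "KF001;x;;AQ",
            "KF002;Typha angustifolia;Taraxacum officinale;AQ",
            "KF003;x;Taraxacum officinale;AQ",
            "KF004;x;Taraxacum officinale;AQ",
        ]
        entries = parse_curation_list(io.StringIO("\n".join(lines)))
        ds2, actions = apply_curation_list(ds, entries, tax_source)
        assert len(actions.removed) == 2
        assert len(actions.corrected) == 3
        assert len(ds2) == 8

    def test_correction_rewrites_higher_ranks(self, tax_source):
        ds = dataset(1)
        entries = parse_curation_list(
            io.StringIO("KF000;Typha angustifolia;Taraxacum officinale;AQ\n")
        )
        ds2, actions = apply_curation_list(ds, entries, tax_source)
        rec = ds2["KF000"]
        assert rec.taxonomy.genus == "Taraxacum"
        assert rec.taxonomy.species == "Taraxacum_officinale"
        assert rec.taxonomy.family == "Asteraceae"
        assert actions.needs_review == []

    def test_unresolved_binomial_flags_needs_review(self, tax_source):
        ds = dataset(1)
        entries = parse_curation_list(io.StringIO("KF000;x;Ignotus mysticus;AQ\n"))
        ds2, actions = apply_curation_list(ds, entries, tax_source)
        rec = ds2["KF000"]
        assert rec.taxonomy.genus == "Ignotus"
        assert rec.taxonomy.family == "Typhaceae"  # old higher ranks kept
        assert "needs_review" in rec.flags
        assert actions.needs_review == ["KF000"]

    def test_genus_only_correction_becomes_placeholder(self, tax_source):
        ds = dataset(1)
        entries = parse_curation_list(io.StringIO("KF000;x;Taraxacum;AQ\n"))
        ds2, _ = apply_curation_list(ds, entries, tax_source)
        assert ds2["KF000"].taxonomy.species == "Taraxacum_sp"
        assert not ds2["KF000"].taxonomy.is_complete()

    def test_absent_accession_reported_not_error(self, tax_source):
        ds = dataset(2)
        entries = parse_curation_list(io.StringIO("NOPE;x;;AQ\n"))
        ds2, actions = apply_curation_list(ds, entries, tax_source)
        assert actions.unmatched == ["NOPE"]
        assert ds2 == ds

    def test_empty_list_is_identity(self, tax_source):
        ds = dataset(3)
        ds2, actions = apply_curation_list(ds, [], tax_source)
        assert ds2 == ds
        assert not (actions.removed or actions.corrected or actions.unmatched)

    def test_later_entry_overrides_earlier(self, tax_source):
        ds = dataset(1)
        entries = parse_curation_list(
            io.StringIO("KF000;x;Taraxacum officinale;AQ\nKF000;x;;ZZ\n")
        )
        ds2, actions = apply_curation_list(ds, entries, tax_source)
        assert actions.removed == ["KF000"] and len(ds2) == 0


class TestSpeciesFasta:
    def test_free_text_headers(self):
        out = parse_species_fasta(io.StringIO(">Lavandula angustifolia\nACGT\nACGT\n"))
        assert out == [("Lavandula angustifolia", "ACGTACGT")]

    def test_empty_file(self):
        assert parse_species_fasta(io.StringIO("")) == []

    def test_duplicate_species_kept_as_two_entries(self):
        text = ">Lavandula angustifolia\nAAAA\n>Lavandula angustifolia\nCCCC\n"
        out = parse_species_fasta(io.StringIO(text))
        assert len(out) == 2

    def test_malformed_fasta_is_error(self):
        with pytest.raises(ValueError, match="line 1"):
            parse_species_fasta(io.StringIO("ACGT\n"))


class TestAddSequences:
    def test_all_resolvable(self, tax_source):
        ds = dataset(3)
        new = [("Lavandula angustifolia", "ACGT"), ("Taraxacum officinale", "TTTT")]
        ds2, added, unresolved = add_sequences(ds, new, tax_source)
        assert len(ds2) == 5 and len(added) == 2 and not unresolved
        assert ds2[added[0]].source == "manual"
        assert ds2[added[0]].taxonomy.family == "Lamiaceae"

    def test_unresolvable_skipped(self, tax_source):
        ds = dataset(1)
        ds2, added, unresolved = add_sequences(ds, [("Ignotus mysticus", "ACGT")], tax_source)
        assert len(ds2) == 1 and not added
        assert unresolved == ["Ignotus mysticus"]

    def test_append_only_and_collision_free(self, tax_source):
        ds = Dataset([SeqRecord("MANUAL_0001", tax(), "ACGT")])
        before = list(ds)
        ds2, added, _ = add_sequences(ds, [("Lavandula angustifolia", "GGGG")], tax_source)
        assert added == ["MANUAL_0002"]
        assert [r for r in ds2][: len(before)] == before

    def test_species_count_never_decreases(self, tax_source):
        ds = dataset(4)
        ds2, added, _ = add_sequences(
            ds, [("Lavandula angustifolia", "ACGT")], tax_source
        )
        assert ds2.n_species() >= ds.n_species()
        assert len(ds2) == len(ds) + len(added)
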