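import math

import numpy as np
import pytest

from refcure.curate import (
    STAGES,
    CurationConfig,
    FilterReport,
    filter_chlorophyta,
    filter_fungal,
    filter_incomplete_taxonomy,
    filter_intraspecific,
    filter_nontarget,
    ladder_dropout,
    run_pipeline,
    summarize,
)
from refcure.fixtures import CATEGORY_STAGE
from refcure.taxfasta import Dataset, SeqRecord, TaxonomyString

from _oracles import random_species_matrix, simulate_ladder

CFG = CurationConfig()


def plant_tax(genus="Malus", species="Malus_pumila", **kw):
    base = dict(
        kingdom="Viridiplantae", phylum="Streptophyta", class_="Magnoliopsida",
        order="Rosales", family="Rosaceae", genus=genus, species=species,
    )
    base.update(kw)
    return TaxonomyString(**base)


def star(n, offdiag):
    """Symmetric matrix with constant off-diagonal identity."""
    m = np.full((n, n), offdiag)
    np.fill_diagonal(m, 1.0)
    return m


class TestLadderDropout:
    def test_uniform_high_identity_untouched_all_modes(self):
        for mode in "ABC":
            kept, removed = ladder_dropout(star(5, 0.99), mode, CFG)
            assert kept == [0, 1, 2, 3, 4] and not removed

    def test_single_outlier_removed_in_mode_c(self):
        # four tight members, one distant outlier: dropped on an early rung
        m = star(5, 0.98)
        m[4, :4] = m[:4, 4] = 0.60
        kept, removed = ladder_dropout(m, "C", CFG)
        assert kept == [0, 1, 2, 3]
        assert [i for i, _, _ in removed] == [4]
        assert removed[0][1] <= 0.75  # threshold of the removing step

    def test_borderline_species_wiped_by_a_retained_by_c(self):
        # all-pairs identity exactly 0.90: mode A median 0.90 < 0.97 wipes
        # the species; mode C never removes (0.90 is not strictly below
        # the 0.90 rung, and the 0.925 rung would breach the safeguard)
        m = star(6, 0.90)
        kept_a, _ = ladder_dropout(m, "A", CFG)
        kept_c, _ = ladder_dropout(m, "C", CFG)
        assert kept_a == []
        assert kept_c == [0, 1, 2, 3, 4, 5]

    def test_mode_b_runs_full_ladder_without_safeguard(self):
        m = star(6, 0.90)
        kept_b, _ = ladder_dropout(m, "B", CFG)
        assert kept_b == []  # the 0.925 rung removes everyone, no safeguard

    def test_median_recomputed_after_each_step(self):
        # two outliers at 0.55; after they go, survivors' medians recover
        m = star(6, 0.99)
        for i in (4, 5):
            m[i, :4] = m[:4, i] = 0.55
        m[4, 5] = m[5, 4] = 0.99
        kept, _ = ladder_dropout(m, "C", CFG)
        assert kept == [0, 1, 2, 3]

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(2, 9))
            mat = random_species_matrix(rng, n)
            arr = np.array(mat)
            for mode in "ABC":
                kept, _ = ladder_dropout(arr, mode, CFG)
                assert set(kept) == simulate_ladder(mat, mode), (mode, mat)

    def test_mode_c_retention_floor(self):
        rng = np.random.default_rng(43)
        for _ in range(40):
            n = int(rng.integers(5, 9))
            arr = np.array(random_species_matrix(rng, n))
            kept, _ = ladder_dropout(arr, "C", CFG)
            assert len(kept) >= math.ceil(0.5 * n)

    def test_remaining_basis_stops_on_large_step(self):
        cfg = CurationConfig(safeguard_basis="remaining")
        m = star(6, 0.90)
        kept, _ = ladder_dropout(m, "C", cfg)
        assert kept == [0, 1, 2, 3, 4, 5]


class TestFilterIntraspecific:
    def make_species(self, name, seqs):
        return [
            SeqRecord(f"{name}{i}", plant_tax(species=name), s)
            for i, s in enumerate(seqs)
        ]

    def test_small_species_untouched(self):
        # four members, arbitrarily divergent: below the min-n rule
        seqs = ["ACGTACGTACGT", "TTTTACGTCCCC", "GGGGGGGGGGGG", "ACACACACACAC"]
        ds = Dataset(self.make_species("Small_species", seqs))
        ds2, removed = filter_intraspecific(ds, CFG)
        assert len(ds2) == 4 and not removed

    def test_outlier_removed_detail_names_species(self, small_refs, small_dirty):
        ds, manifest = small_dirty
        _, removed = filter_intraspecific(ds, CurationConfig(seed=7))
        accs = sorted(r.accession for r in removed)
        assert accs == manifest.categories["intraspecific_outlier"]
        assert all("species=" in r.detail for r in removed)


class TestOtherFilters:
    def test_incomplete_taxonomy_variants(self):
        records = [
            SeqRecord("OK", plant_tax(), "ACGT"),
            SeqRecord("NOFAM", plant_tax(family=""), "ACGT"),
            SeqRecord("SP", plant_tax(species="Malus_sp"), "ACGT"),
        ]
        ds2, removed = filter_incomplete_taxonomy(Dataset(records))
        assert ds2.accessions == ["OK"]
        reasons = {r.accession: r.detail for r in removed}
        assert "family" in reasons["NOFAM"] and "species" in reasons["SP"]

    @pytest.mark.parametrize(
        "phylum,removed", [("Chlorophyta", True), ("chlorophyta", True), ("Streptophyta", False)]
    )
    def test_chlorophyta_case_insensitive(self, phylum, removed):
        ds = Dataset([SeqRecord("A1", plant_tax(phylum=phylum), "ACGT")])
        ds2, gone = filter_chlorophyta(ds)
        assert (len(ds2) == 0) is removed
        assert bool(gone) is removed

    def test_fungal_filter_exact_on_fixture(self, small_refs, small_dirty):
        _, fungal_ref = small_refs
        ds, manifest = small_dirty
        ds2, removed = filter_fungal(ds, fungal_ref, CurationConfig(seed=7))
        assert sorted(r.accession for r in removed) == manifest.categories["fungal"]
        assert all("genus=" in r.detail for r in removed)

    def test_nontarget_filter_exact_on_fixture(self, small_refs, small_dirty):
        trusted_ref, _ = small_refs
        ds, manifest = small_dirty
        # planted fungal sequences also lack a trusted-reference hit; the
        # pipeline removes them at stage 1, so test filter 2 without them
        ds = ds.without(manifest.categories["fungal"])
        ds2, removed = filter_nontarget(ds, trusted_ref, CurationConfig(seed=7))
        assert sorted(r.accession for r in removed) == manifest.categories["nontarget"]
        assert all(r.detail.startswith("best_identity=") for r in removed)

    def test_nontarget_requires_reference(self):
        with pytest.raises(ValueError):
            filter_nontarget(Dataset(), Dataset(), CFG)

    def test_filters_1_to_4_idempotent(self, small_refs, small_dirty):
        trusted_ref, fungal_ref = small_refs
        ds, _ = small_dirty
        cfg = CurationConfig(seed=7)
        ds1, _ = filter_fungal(ds, fungal_ref, cfg)
        assert filter_fungal(ds1, fungal_ref, cfg)[1] == []
        ds2, _ = filter_nontarget(ds1, trusted_ref, cfg)
        assert filter_nontarget(ds2, trusted_ref, cfg)[1] == []
        ds3, _ = filter_incomplete_taxonomy(ds2)
        assert filter_incomplete_taxonomy(ds3)[1] == []
        ds4, _ = filter_chlorophyta(ds3)
        assert filter_chlorophyta(ds4)[1] == []


class TestPipeline:
    def test_stagewise_ground_truth(self, small_refs, small_dirty):
        trusted_ref, fungal_ref = small_refs
        ds, manifest = small_dirty
        curated, report = run_pipeline(ds, fungal_ref, trusted_ref, CurationConfig(seed=7))
        by_stage = {s.stage: sorted(r.accession for r in s.removed) for s in report.stages}
        for category, accs in manifest.categories.items():
            assert by_stage[CATEGORY_STAGE[category]] == accs
        assert sorted(curated.accessions) == manifest.clean

    def test_conservation(self, small_refs, small_dirty):
        trusted_ref, fungal_ref = small_refs
        ds, _ = small_dirty
        curated, report = run_pipeline(ds, fungal_ref, trusted_ref, CurationConfig(seed=7))
        assert len(curated) + report.total_removed == len(ds)
        report.validate()

    def test_all_clean_dataset_nothing_removed(self, small_refs):
        from refcure.fixtures import FixtureParams, make_dirty_dataset

        trusted_ref, fungal_ref = small_refs
        params = FixtureParams(
            n_clean_species=6, n_fungal=0, n_nontarget=0, n_incomplete=0,
            n_chlorophyta=0, n_outliers=0, length=240,
        )
        ds, manifest = make_dirty_dataset(3, trusted_ref, fungal_ref, params)
        assert manifest.all_planted() == set()
        curated, report = run_pipeline(ds, fungal_ref, trusted_ref, CurationConfig(seed=3))
        assert report.total_removed == 0
        assert len(curated) == len(ds)

    def test_skip_all_filters_identity(self, small_refs, small_dirty):
        ds, _ = small_dirty
        curated, report = run_pipeline(ds, None, None, CFG, skip=[1, 2, 3, 4, 5])
        assert curated == ds and report.stages == []

    def test_missing_reference_is_error(self, small_dirty):
        ds, _ = small_dirty
        with pytest.raises(ValueError):
            run_pipeline(ds, None, None, CFG)


class TestSummarize:
    def test_zero_removals_zero_loss(self):
        rep = FilterReport.from_counts(100, 40, [0, 0, 0, 0, 0], final_species=40)
        s = summarize(rep)
        assert s["sequence_loss_percent"] == 0
        assert s["species_loss_percent"] == 0
        assert s["retained_sequences"] == 100

    def test_stage_order_fixed(self, small_refs, small_dirty):
        trusted_ref, fungal_ref = small_refs
        ds, _ = small_dirty
        _, report = run_pipeline(ds, fungal_ref, trusted_ref, CurationConfig(seed=7))
        assert tuple(s.stage for s in report.stages) == STAGES
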