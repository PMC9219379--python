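"""Report parsing, cohort assembly, and the two taxon filters."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from tractome.profiles_io import (
    AbundanceTable,
    ReportParseError,
    SampleMetadata,
    TaxonRecord,
    attach_lineages,
    exclude_lineages,
    filter_rare_taxa,
    merge_profiles,
    read_lineage_table,
    read_metadata,
    read_table,
    read_taxonomic_report,
    to_relative_abundance,
    write_lineage_table,
    write_metadata,
    write_table,
)

from conftest import bacterial_taxon, make_table


class TestReadTaxonomicReport:
    def test_empty_file_yields_empty_mapping(self, tmp_path):
        path = tmp_path / "empty.kreport"
        path.write_text("")
        assert read_taxonomic_report(path) == {}

    def test_kraken_species_rows_hand_parsed(self, kraken_report):
        prof = read_taxonomic_report(kraken_report, "species")
        by_name = {rec.name: c for rec, c in prof.items()}
        # hand parse of the fixture: two S rows, clade-read counts
        assert by_name == {"Escherichia coli": 6000, "Escherichia fergusonii": 2000}

    def test_kraken_lineage_reconstructed_from_indentation(self, kraken_report):
        prof = read_taxonomic_report(kraken_report, "species")
        rec = next(r for r in prof if r.name == "Escherichia coli")
        assert rec.lineage == (
            ("genus", "Escherichia"),
            ("phylum", "Proteobacteria"),
            ("domain", "Bacteria"),
        )

    def test_genus_level_selection(self, kraken_report):
        prof = read_taxonomic_report(kraken_report, "genus")
        by_name = {rec.name: c for rec, c in prof.items()}
        assert by_name == {"Escherichia": 8000, "Klebsiella": 1940}

    def test_reread_is_deterministic(self, kraken_report):
        assert read_taxonomic_report(kraken_report) == read_taxonomic_report(
            kraken_report
        )

    def test_bracken_dialect_autodetected(self, bracken_report):
        prof = read_taxonomic_report(bracken_report, "species")
        by_name = {rec.name: c for rec, c in prof.items()}
        assert by_name == {"Escherichia coli": 6100, "Klebsiella pneumoniae": 3900}
        assert all(rec.lineage == () for rec in prof)

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.kreport"
        path.write_text("10.0\t100\t100\tS\t5\tGood sp\nnot-enough-fields\n")
        with pytest.raises(ReportParseError, match="line 2"):
            read_taxonomic_report(path)

    def test_unknown_rank_code_skipped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "odd.kreport"
        path.write_text(
            "10.0\t100\t100\tS\t5\tGood sp\n"
            "10.0\t100\t100\tX9\t6\tWeird clade\n"
        )
        with caplog.at_level("WARNING", logger="tractome"):
            prof = read_taxonomic_report(path, "species")
        assert len(prof) == 1
        assert "unknown rank code" in caplog.text

    def test_duplicate_names_summed_with_warning(self, tmp_path, caplog):
        path = tmp_path / "dup.kreport"
        path.write_text(
            "10.0\t100\t100\tS\t5\tSame sp\n10.0\t40\t40\tS\t6\tSame sp\n"
        )
        with caplog.at_level("WARNING", logger="tractome"):
            prof = read_taxonomic_report(path, "species")
        assert sum(prof.values()) == 140
        assert len(prof) == 1


class TestMergeProfiles:
    def _meta(self, n):
        return [
            SampleMetadata(f"s{i}", f"subj{i}", "CCT", "B") for i in range(n)
        ]

    def test_disjoint_taxa_zero_filled(self):
        a = bacterial_taxon("Alpha sp", 1)
        b = bacterial_taxon("Beta sp", 2)
        table = merge_profiles([{a: 5}, {b: 7}], self._meta(2))
        assert table.taxon_names == ["Alpha sp", "Beta sp"]
        assert table.counts.tolist() == [[5, 0], [0, 7]]

    def test_single_profile_identity(self):
        a = bacterial_taxon("Alpha sp", 1)
        b = bacterial_taxon("Beta sp", 2)
        table = merge_profiles([{b: 3, a: 9}], self._meta(1))
        assert table.counts.tolist() == [[9, 3]]

    def test_sum_conservation(self):
        rng = np.random.default_rng(0)
        taxa = [bacterial_taxon(f"Tax sp{i}", i + 1) for i in range(12)]
        profiles = []
        for _ in range(4):
            chosen = rng.choice(12, size=rng.integers(3, 10), replace=False)
            profiles.append(
                {taxa[j]: int(rng.integers(1, 1000)) for j in chosen}
            )
        table = merge_profiles(profiles, self._meta(4))
        for i, prof in enumerate(profiles):
            assert table.counts[i].sum() == sum(prof.values())

    def test_duplicate_sample_id_rejected(self):
        meta = [
            SampleMetadata("s0", "a", "CCT", "B"),
            SampleMetadata("s0", "b", "CCT", "B"),
        ]
        with pytest.raises(ValueError, match="duplicate sample ids"):
            merge_profiles([{}, {}], meta)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="metadata"):
            merge_profiles([{}], self._meta(2))


class TestExcludeLineages:
    def test_chloroplast_column_removed(self):
        chloro = TaxonRecord(
            9, "Chloroplast sp", "species",
            (("genus", "Chloroplast"), ("domain", "Bacteria")),
        )
        table = make_table([[5, 5]], taxa=[bacterial_taxon("Ok sp", 1), chloro])
        out = exclude_lineages(table)
        assert out.taxon_names == ["Ok sp"]

    def test_all_bacterial_table_unchanged(self):
        table = make_table([[1, 2, 3]])
        assert exclude_lineages(table) is table

    def test_fungi_kept_non_fungal_eukaryotes_dropped(self):
        def euk(name, taxid, kingdom):
            return TaxonRecord(
                taxid, name, "species",
                (("kingdom", kingdom), ("domain", "Eukaryota")),
            )

        taxa = [
            euk("Candida albicans", 1, "Fungi"),
            euk("Saccharomyces cerevisiae", 2, "Fungi"),
            euk("Trypanosoma brucei", 3, "Protista"),
            bacterial_taxon("Bact one", 4),
            bacterial_taxon("Bact two", 5),
            bacterial_taxon("Bact three", 6),
        ]
        table = make_table([[1] * 6], taxa=taxa)
        out = exclude_lineages(table)
        assert out.n_taxa == 5
        assert "Trypanosoma brucei" not in out.taxon_names

    def test_empty_lineage_retained_with_warning(self, caplog):
        naked = TaxonRecord(7, "Mystery sp", "species")
        table = make_table([[4, 4]], taxa=[bacterial_taxon("Ok sp", 1), naked])
        with caplog.at_level("WARNING", logger="tractome"):
            out = exclude_lineages(table)
        assert "Mystery sp" in out.taxon_names
        assert "no lineage" in caplog.text

    def test_never_alters_surviving_counts(self):
        chloro = TaxonRecord(
            9, "Chloroplast sp", "species",
            (("genus", "Chloroplast"), ("domain", "Bacteria")),
        )
        table = make_table(
            [[5, 7], [2, 0]],
            taxa=[bacterial_taxon("Ok sp", 1), chloro],
        )
        out = exclude_lineages(table)
        assert out.counts[:, 0].tolist() == [5, 2]


class TestFilterRareTaxa:
    def test_defaults_encode_global_fraction_and_prevalence(self):
        import inspect

        sig = inspect.signature(filter_rare_taxa)
        assert sig.parameters["min_global_fraction"].default == 1e-7
        assert sig.parameters["min_sample_count"].default == 5

    def test_empty_taxa_table_unchanged(self):
        table = make_table(np.zeros((3, 0), dtype=int))
        assert filter_rare_taxa(table) is table

    def test_hand_evaluated_six_sample_fixture(self):
        # X: abundant but present in only 4 of 6 samples -> removed.
        # Y: present in 5 samples at ~10% -> kept.
        # Z: filler, present everywhere -> kept.
        counts = np.array(
            [
                [500, 100, 900],
                [500, 100, 900],
                [500, 100, 900],
                [500, 100, 900],
                [0, 100, 900],
                [0, 0, 1000],
            ]
        )
        table = make_table(counts, taxon_names=["X sp", "Y sp", "Z sp"])
        out = filter_rare_taxa(table)
        assert out.taxon_names == ["Y sp", "Z sp"]

    def test_global_fraction_rule(self):
        # present in >=5 samples but at ~1e-8 of the grand total -> removed
        counts = np.column_stack(
            [np.full(6, 10_000_000), np.array([1, 1, 1, 1, 1, 0])]
        )
        table = make_table(counts, taxon_names=["Big sp", "Tiny sp"])
        out = filter_rare_taxa(table)
        assert out.taxon_names == ["Big sp"]

    def test_zero_reads_rejected(self):
        table = make_table(np.zeros((2, 2), dtype=int))
        with pytest.raises(ValueError, match="no reads"):
            filter_rare_taxa(table)

    @given(
        arrays(
            np.int64,
            (8, 6),
            elements=st.integers(min_value=0, max_value=500),
        )
    )
    def test_idempotent_on_single_pass(self, counts):
        if counts.sum() == 0:
            return
        table = make_table(counts)
        once = filter_rare_taxa(table)
        if once.n_taxa == 0:
            return
        twice = filter_rare_taxa(once)
        # thresholds re-evaluated on the filtered table's own grand total
        # can only be *less* strict for survivors, so nothing else drops
        assert twice.taxon_names == once.taxon_names
        assert np.array_equal(twice.counts, once.counts)


class TestRelativeAbundance:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ([10, 10, 10, 10], [0.25, 0.25, 0.25, 0.25]),
            ([42], [1.0]),
            ([5, 3, 1, 1], [0.5, 0.3, 0.1, 0.1]),
        ],
    )
    def test_worked_rows(self, row, expected):
        table = make_table([row])
        assert to_relative_abundance(table)[0] == pytest.approx(expected)

    def test_zero_total_sample_named(self):
        table = make_table([[1, 1], [0, 0]])
        with pytest.raises(ValueError, match=table.samples[1].sample_id):
            to_relative_abundance(table)

    @given(
        arrays(
            np.int64,
            (5, 7),
            elements=st.integers(min_value=0, max_value=1000),
        )
    )
    def test_rows_sum_to_one(self, counts):
        counts[:, 0] += 1  # ensure positive totals
        table = make_table(counts)
        ra = to_relative_abundance(table)
        assert np.allclose(ra.sum(axis=1), 1.0, atol=1e-12)
        assert ((counts == 0) == (ra == 0)).all()


class TestTabularRoundTrips:
    def test_table_round_trip_lossless(self, tmp_path):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 50, size=(4, 6))
        table = make_table(
            counts, sites=["CCT", "EMT", "FTT", "OCT"],
            subjects=["S1"] * 4, conditions=["M"] * 4,
        )
        write_table(table, tmp_path / "t.tsv", tmp_path / "m.tsv")
        back = read_table(tmp_path / "t.tsv", tmp_path / "m.tsv")
        assert np.array_equal(back.counts, table.counts)
        assert back.taxa == table.taxa
        assert back.samples == table.samples

    def test_metadata_round_trip_csv_and_tsv(self, tmp_path):
        samples = [
            SampleMetadata("s1", "P1", "CCT", "M", "yes", "resistant"),
            SampleMetadata("s2", "P1", "OCT", "M", "yes", "resistant"),
        ]
        for name in ("meta.csv", "meta.tsv"):
            write_metadata(samples, tmp_path / name)
            assert read_metadata(tmp_path / name) == samples

    def test_lineage_sidecar_round_trip(self, tmp_path):
        taxa = [bacterial_taxon("Alpha sp", 11), bacterial_taxon("Beta sp", 22)]
        write_lineage_table(taxa, tmp_path / "tax.tsv")
        lineages = read_lineage_table(tmp_path / "tax.tsv")
        bare = {TaxonRecord(11, "Alpha sp", "species"): 5}
        attached = attach_lineages(bare, lineages)
        (rec,) = attached
        assert rec.lineage == taxa[0].lineage


class TestInvariants:
    def test_site_and_condition_validated(self):
        with pytest.raises(ValueError, match="site"):
            SampleMetadata("s", "p", "XXX", "B")
        with pytest.raises(ValueError, match="condition"):
            SampleMetadata("s", "p", "CCT", "Z")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            make_table([[-1, 2]])

    def test_duplicate_subject_site_rejected(self):
        with pytest.raises(ValueError, match="subject_id"):
            make_table([[1], [2]], subjects=["S1", "S1"], sites=["CCT", "CCT"])
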