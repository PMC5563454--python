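"""VCF reading, filtering-AF annotation, filter decisions, round trips."""

import logging

import pytest

from fafcalc import (
    DiseaseArchitecture,
    PopulationCounts,
    VariantRecord,
    annotate_filtering_af,
    apply_disease_filter,
    filtering_af,
    max_credible_af,
    read_annotated_vcf,
    read_population_counts,
    records_to_frame,
    write_vcf,
)
from fafcalc.vcf_io import UnannotatedRecordError, VcfParseError

HCM_THRESHOLD = max_credible_af(
    DiseaseArchitecture(1 / 500, "dominant", 0.02, penetrance=0.5)
)


class TestReadPopulationCounts:
    def test_single_alt_line(self, write_vcf_text):
        path = write_vcf_text([("1", 100, "A", "T", "AC_NFE=2;AN_NFE=10000")])
        records = read_population_counts(path)
        assert len(records) == 1
        assert records[0].key == ("1", 100, "A", "T")
        assert records[0].counts == (PopulationCounts("NFE", 2, 10_000),)

    def test_multiallelic_decomposition_aligns_allele_index(self, write_vcf_text):
        path = write_vcf_text([("1", 200, "G", "A,C", "AC_NFE=2,7;AN_NFE=10000")])
        records = read_population_counts(path)
        assert [r.alt for r in records] == ["A", "C"]
        assert [r.counts[0].ac for r in records] == [2, 7]
        # AN is a site-level denominator shared across alts
        assert {r.counts[0].an for r in records} == {10_000}

    def test_line_without_mapped_keys_yields_empty_counts(self, write_vcf_text, caplog):
        path = write_vcf_text([("1", 300, "C", "G", None)])
        with caplog.at_level(logging.WARNING):
            records = read_population_counts(path)
        assert records[0].counts == ()
        assert "no mapped population counts" in caplog.text

    def test_missing_an_omits_population(self, write_vcf_text):
        path = write_vcf_text(
            [("1", 400, "T", "A", "AC_NFE=1;AN_NFE=9000;AC_AFR=2")]
        )
        (record,) = read_population_counts(path)
        assert {c.population for c in record.counts} == {"NFE"}

    def test_ac_above_an_skips_record_with_warning(self, write_vcf_text, caplog):
        path = write_vcf_text(
            [("1", 500, "A", "G", "AC_NFE=50;AN_NFE=10"),
             ("1", 600, "A", "G", "AC_NFE=1;AN_NFE=10000")]
        )
        with caplog.at_level(logging.WARNING):
            records = read_population_counts(path)
        assert [r.pos for r in records] == [600]
        assert "exceeds AN" in caplog.text

    def test_malformed_vcf_raises_parse_error(self, tmp_path):
        bad = tmp_path / "bad.vcf"
        bad.write_text("not a vcf\n")
        with pytest.raises(VcfParseError):
            read_population_counts(bad)

    def test_custom_field_map(self, write_vcf_text):
        path = write_vcf_text([("1", 100, "A", "T", "AC_NFE=4;AN_NFE=8000")])
        records = read_population_counts(path, {"NFE": ("AC_NFE", "AN_NFE")})
        assert records[0].counts[0].ac == 4


class TestAnnotate:
    def test_popmax_matches_direct_computation(self):
        rec = VariantRecord("1", 1, "A", "T", (PopulationCounts("NFE", 2, 10_000),))
        (annotated,) = annotate_filtering_af([rec])
        assert annotated.filtering.popmax_af == pytest.approx(3.5e-5, abs=1e-12)

    def test_all_singletons_get_zero(self):
        counts = tuple(
            PopulationCounts(p, 1, 20_000) for p in ("AFR", "AMR", "EAS", "NFE", "SAS")
        )
        (annotated,) = annotate_filtering_af([VariantRecord("1", 1, "A", "T", counts)])
        assert annotated.filtering.popmax_af == 0.0

    def test_empty_counts_logged_not_annotated(self, caplog):
        with caplog.at_level(logging.WARNING):
            (annotated,) = annotate_filtering_af([VariantRecord("1", 1, "A", "T", ())])
        assert annotated.filtering is None
        assert "no counts" in caplog.text


class TestRoundTrip:
    def test_read_annotate_write_read(self, write_vcf_text, tmp_path):
        path = write_vcf_text(
            [("1", 100, "A", "T", "AC_NFE=2;AN_NFE=10000;AC_AFR=0;AN_AFR=8000"),
             ("2", 50, "GT", "G", "AC_SAS=12;AN_SAS=15000"),
             ("2", 60, "C", "A,G", "AC_EAS=3,1;AN_EAS=9000")]
        )
        records = annotate_filtering_af(read_population_counts(path))
        out = tmp_path / "annotated.vcf"
        write_vcf(records, out)
        back = read_annotated_vcf(out)
        assert [r.key for r in back] == [r.key for r in records]
        assert [r.counts for r in back] == [r.counts for r in records]
        for orig, parsed in zip(records, back):
            assert parsed.filtering.popmax_af == pytest.approx(
                orig.filtering.popmax_af, abs=1e-8
            )
            assert parsed.filtering.popmax_population == orig.filtering.popmax_population

    def test_bgzipped_output(self, write_vcf_text, tmp_path):
        path = write_vcf_text([("1", 100, "A", "T", "AC_NFE=2;AN_NFE=10000")])
        records = annotate_filtering_af(read_population_counts(path))
        out = tmp_path / "annotated.vcf.gz"
        write_vcf(records, out)
        assert read_annotated_vcf(out)[0].counts == records[0].counts

    def test_header_declares_faf_keys(self, write_vcf_text, tmp_path):
        path = write_vcf_text([("1", 100, "A", "T", "AC_NFE=2;AN_NFE=10000")])
        out = tmp_path / "annotated.vcf"
        write_vcf(annotate_filtering_af(read_population_counts(path)), out)
        header = out.read_text()
        assert "##INFO=<ID=FAF95_popmax" in header
        assert "##INFO=<ID=FAF95_NFE" in header


class TestApplyDiseaseFilter:
    def _annotated(self, counts):
        return annotate_filtering_af([VariantRecord("1", 1, "A", "T", tuple(counts))])

    def test_rare_pathogenic_variant_retained(self):
        # the commonest HCM variant is seen 3 times in ~121k reference chromosomes
        records = self._annotated([PopulationCounts("NFE", 3, 121_412)])
        (decision,) = apply_disease_filter(records, HCM_THRESHOLD)
        assert records[0].filtering.popmax_af == pytest.approx(6.7e-6, abs=1e-6)
        assert decision.decision == "retained"

    def test_boundary_is_filtered(self):
        records = self._annotated([PopulationCounts("NFE", 3, 121_412)])
        (decision,) = apply_disease_filter(records, records[0].filtering.popmax_af)
        assert decision.decision == "filtered"

    def test_popmax_zero_retained_under_any_positive_threshold(self):
        records = self._annotated([PopulationCounts("NFE", 1, 121_412)])
        (decision,) = apply_disease_filter(records, 1e-9)
        assert decision.decision == "retained"

    def test_unannotated_record_is_an_error(self):
        with pytest.raises(UnannotatedRecordError):
            apply_disease_filter([VariantRecord("1", 1, "A", "T")], HCM_THRESHOLD)

    def test_decision_consistent_with_recomputed_filtering_af(self):
        records = self._annotated([PopulationCounts("NFE", 25, 121_412)])
        (decision,) = apply_disease_filter(records, HCM_THRESHOLD)
        recomputed = filtering_af(25, 121_412)
        assert (decision.decision == "filtered") == (
            recomputed >= HCM_THRESHOLD.max_credible_af
        )

    def test_filter_is_monotone_in_threshold(self):
        records = annotate_filtering_af([
            VariantRecord("1", i + 1, "A", "T", (PopulationCounts("NFE", ac, 121_412),))
            for i, ac in enumerate([0, 1, 2, 5, 20, 100, 400])
        ])
        loose = {d.variant for d in apply_disease_filter(records, 1e-3)
                 if d.decision == "filtered"}
        tight = {d.variant for d in apply_disease_filter(records, 1e-5)
                 if d.decision == "filtered"}
        assert loose <= tight


def test_records_to_frame_mirrors_annotations(write_vcf_text):
    path = write_vcf_text([("1", 100, "A", "T", "AC_NFE=2;AN_NFE=10000")])
    records = annotate_filtering_af(read_population_counts(path))
    frame = records_to_frame(records)
    assert frame.loc[0, "faf_popmax"] == pytest.approx(3.5e-5, abs=1e-12)
    assert frame.loc[0, "faf_popmax_pop"] == "NFE"
    assert frame.loc[0, "ac_NFE"] == 2
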