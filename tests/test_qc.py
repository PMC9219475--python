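import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpdiv.genotype_io import MISSING
from snpdiv.qc import (
    QcError,
    QcThresholds,
    _levene_probs,
    apply_qc,
    compute_qc_metrics,
    hwe_exact_test,
)
from snpdiv.simdata import SimulationConfig, simulate_dataset

from _util import hwe_conditional_probs, hwe_enumeration_oracle, make_gm


class TestHweExactTest:
    def test_monomorphic_returns_one(self):
        assert hwe_exact_test(5, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 7) == 1.0

    def test_two_het_two_alleles_each(self):
        # alleles 2+2; het counts {0, 2} with conditional probs {1/3, 2/3}
        assert hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3, abs=1e-12)
        assert hwe_exact_test(0, 2, 0) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError, match="no data"):
            hwe_exact_test(0, 0, 0)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 0)

    def test_extreme_cases_against_oracle(self):
        for triple in [(0, 50, 0), (25, 0, 25), (10, 5, 10), (0, 1, 0), (1, 1, 1)]:
            assert hwe_exact_test(*triple) == pytest.approx(
                hwe_enumeration_oracle(*triple), abs=1e-12
            )

    @given(
        st.integers(min_value=0, max_value=20),
        st.integers(min_value=0, max_value=20),
        st.integers(min_value=0, max_value=20),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle(self, n_rr, n_het, n_aa):
        if n_rr + n_het + n_aa == 0:
            return
        assert hwe_exact_test(n_rr, n_het, n_aa) == pytest.approx(
            hwe_enumeration_oracle(n_rr, n_het, n_aa), abs=1e-12
        )

    def test_conditional_distribution_sums_to_one(self):
        for n_ref, n_alt in [(3, 5), (10, 10), (1, 19), (7, 3)]:
            probs = _levene_probs(n_ref, n_alt)
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)
            exact = hwe_conditional_probs(
                *_triple_from_allele_counts(n_ref, n_alt)
            )
            assert np.allclose(probs, [float(p) for p in exact], atol=1e-12)


def _triple_from_allele_counts(n_ref, n_alt):
    # any genotype triple consistent with the allele counts works
    rare = min(n_ref, n_alt)
    h = rare % 2
    hom_r = (rare - h) // 2
    n = (n_ref + n_alt) // 2
    hom_c = n - h - hom_r
    if n_ref >= n_alt:
        return hom_c, h, hom_r
    return hom_r, h, hom_c


class TestComputeQcMetrics:
    def test_fully_observed_marker_has_unit_call_rates(self):
        gm = make_gm([[0, 1], [1, 2], [2, 0], [1, 1]], list("AABB"))
        m = compute_qc_metrics(gm)
        assert (m.snp_pop_call_rate == 1.0).all()
        assert (m.indiv_call_rate == 1.0).all()

    def test_pooled_maf_arithmetic(self):
        gm = make_gm([[0], [0], [1], [1], [2], [2]], list("PPPPPP"))
        m = compute_qc_metrics(gm)
        assert m.maf[0] == pytest.approx(0.5)

    def test_all_missing_in_pop_gives_zero_call_rate(self):
        gm = make_gm([[MISSING], [MISSING], [1], [1]], list("AABB"))
        m = compute_qc_metrics(gm)
        k = m.population_order.index("A")
        assert m.snp_pop_call_rate[k, 0] == 0.0
        assert m.hwe_p[k, 0] == 1.0

    def test_indiv_call_rate_tracks_masking(self):
        config = SimulationConfig(
            n_pops=1, pop_sizes=(20,), n_loci=1000, bn_F=(0.0,), fis=(0.0,),
            missing_rate_snp=0.5, seed=2,
        )
        gm, _ = simulate_dataset(config)
        m = compute_qc_metrics(gm)
        se = np.sqrt(0.25 / 1000)
        assert np.all(np.abs(m.indiv_call_rate - 0.5) < 5 * se)


class TestApplyQc:
    def test_zero_thresholds_are_vacuous(self, three_pop_missing_dataset):
        gm, _ = three_pop_missing_dataset
        thresholds = QcThresholds(
            snp_call_rate_per_pop=0.0, indiv_call_rate=0.0, maf_min=0.0, hwe_p_min=0.0
        )
        out, report = apply_qc(gm, thresholds)
        assert out.n_samples == gm.n_samples
        assert out.n_markers == gm.n_markers
        assert report.removed_individuals == {}
        assert all(not v for v in report.removed_markers_by_stage.values())

    def test_planted_low_call_rate_individual_removed(self):
        calls = np.ones((3, 20), dtype=np.int8)
        calls[1, :10] = MISSING
        gm = make_gm(calls, list("PPP"))
        out, report = apply_qc(
            gm, QcThresholds(indiv_call_rate=0.95, maf_min=0.0, hwe_p_min=0.0,
                             snp_call_rate_per_pop=0.0)
        )
        assert list(report.removed_individuals) == ["S1"]
        assert out.n_samples == 2

    def test_monomorphic_marker_removed_at_maf_stage(self):
        config = SimulationConfig(
            n_pops=2, pop_sizes=(20, 20), n_loci=50, bn_F=(0.0, 0.0), fis=(0.0, 0.0),
            seed=13,
        )
        gm, _ = simulate_dataset(config)
        gm.calls[:, 7] = 2  # force monomorphic
        out, report = apply_qc(gm, QcThresholds(hwe_p_min=0.0))
        assert "SNP000008" in report.removed_markers_by_stage["maf"]
        assert "SNP000008" not in out.marker_ids

    def test_stage_attribution_is_first_stage(self):
        # marker 0 fails call rate in pop A AND has MAF 0: attributed to call rate
        calls = np.array(
            [[MISSING, 1], [MISSING, 1], [0, 1], [0, 1]], dtype=np.int8
        )
        gm = make_gm(calls, list("AABB"))
        out, report = apply_qc(
            gm,
            QcThresholds(snp_call_rate_per_pop=0.75, indiv_call_rate=0.0,
                         maf_min=0.01, hwe_p_min=0.0),
        )
        assert report.removed_markers_by_stage["pop_call_rate"] == ["M0"]
        assert report.removed_markers_by_stage["maf"] == []

    def test_all_markers_removed_raises_with_report(self):
        gm = make_gm([[0], [0], [0], [0]], list("PPPP"))
        with pytest.raises(QcError) as exc:
            apply_qc(gm, QcThresholds(maf_min=0.01))
        assert exc.value.report is not None
        assert exc.value.report.n_markers_out == 0

    def test_idempotent_on_complete_data(self, two_pop_dataset):
        gm, _ = two_pop_dataset
        out1, _ = apply_qc(gm)
        out2, report2 = apply_qc(out1)
        assert np.array_equal(out1.calls, out2.calls)
        assert report2.removed_individuals == {}
        assert all(not v for v in report2.removed_markers_by_stage.values())

    def test_report_counts_consistent(self, three_pop_missing_dataset):
        gm, _ = three_pop_missing_dataset
        out, report = apply_qc(gm, QcThresholds(indiv_call_rate=0.85))
        assert report.n_samples_out == out.n_samples
        assert report.n_markers_out == out.n_markers
        removed = sum(len(v) for v in report.removed_markers_by_stage.values())
        assert report.n_markers_in - removed == report.n_markers_out

    def test_report_tsv_written(self, tmp_path, three_pop_missing_dataset):
        gm, _ = three_pop_missing_dataset
        _, report = apply_qc(gm, QcThresholds(indiv_call_rate=0.85))
        path = tmp_path / "qc.tsv"
        report.to_tsv(path)
        text = path.read_text()
        assert text.startswith("section\tkey\tvalue\n")
        assert "n_markers_out" in text
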