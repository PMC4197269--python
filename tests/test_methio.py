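"""Coverage-file parsing, matrix filtering and region averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methpanel.methio import (
    CpGSite,
    MatrixFilterParams,
    MethylationCall,
    TargetRegion,
    build_matrix,
    cross_platform_correlation,
    methylation_ratio,
    read_coverage_file,
    read_matrix,
    region_mean_methylation,
    write_coverage_file,
    write_matrix,
)
from conftest import random_calls
from oracles import brute_matrix_filter, pearson


class TestCoverageFile:
    def test_one_based_input_becomes_zero_based(self, tmp_path):
        p = tmp_path / "x.cov.tsv"
        p.write_text("chr1\t1001\t1001\t75.0\t3\t1\n")
        (call,) = read_coverage_file(p)
        assert call.site == CpGSite("chr1", 1000)
        assert (call.n_meth, call.n_unmeth) == (3, 1)

    def test_zero_coverage_row_kept_with_undefined_ratio(self, tmp_path):
        p = tmp_path / "x.cov.tsv"
        p.write_text("chr1\t5\t5\t0.0\t0\t0\n")
        (call,) = read_coverage_file(p)
        assert call.coverage == 0
        assert methylation_ratio(call) is None

    @pytest.mark.parametrize(
        "row",
        ["chr1\t10\t10\t50.0\t1", "chr1\tx\t10\t50.0\t1\t1", "chr1\t10\t10\t50.0\t-1\t1"],
    )
    def test_malformed_rows_rejected_with_row_number(self, tmp_path, row):
        p = tmp_path / "bad.cov.tsv"
        p.write_text("chr1\t1\t1\t100.0\t4\t0\n" + row + "\n")
        with pytest.raises(ValueError, match="row 2"):
            read_coverage_file(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_coverage_file(tmp_path / "nope.tsv")

    def test_duplicate_positions_are_summed(self, tmp_path):
        p = tmp_path / "dup.cov.tsv"
        p.write_text("chr1\t10\t10\t50.0\t2\t2\nchr1\t10\t10\t100.0\t3\t0\n")
        (call,) = read_coverage_file(p)
        assert (call.n_meth, call.n_unmeth) == (5, 2)

    def test_round_trip_on_synthetic_sample(self, tmp_path, small_cohort):
        sample = small_cohort.samples[0]
        path = tmp_path / "rt.cov.tsv"
        write_coverage_file(small_cohort.calls[sample], path)
        back = read_coverage_file(path)
        orig = {c.site: (c.n_meth, c.n_unmeth) for c in small_cohort.calls[sample]}
        assert {c.site: (c.n_meth, c.n_unmeth) for c in back} == orig


@pytest.mark.parametrize(
    "n_meth,n_unmeth,expected",
    [(3, 1, 0.75), (0, 10, 0.0), (0, 0, None), (7, 0, 1.0)],
)
def test_methylation_ratio(n_meth, n_unmeth, expected):
    call = MethylationCall(CpGSite("chr1", 0), n_meth, n_unmeth)
    assert methylation_ratio(call) == expected


class TestBuildMatrix:
    def two_sample_site(self, cov_a, cov_b):
        site = CpGSite("chr1", 100)
        return {
            "a": [MethylationCall(site, cov_a, 0)],
            "b": [MethylationCall(site, cov_b, 0)],
        }

    def test_incomplete_coverage_drops_site(self):
        m = build_matrix(self.two_sample_site(12, 9), MatrixFilterParams(min_coverage=10))
        assert m.is_empty and m.n_retained == 0

    def test_complete_coverage_keeps_site(self):
        m = build_matrix(self.two_sample_site(12, 10), MatrixFilterParams(min_coverage=10))
        assert m.n_retained == 1
        assert m.ratio.iloc[0].tolist() == [1.0, 1.0]

    def test_sex_chromosome_dropped_when_autosomes_only(self):
        site = CpGSite("chrX", 100)
        calls = {s: [MethylationCall(site, 20, 0)] for s in ("a", "b")}
        assert build_matrix(calls, MatrixFilterParams()).is_empty
        kept = build_matrix(calls, MatrixFilterParams(autosomes_only=False))
        assert kept.n_retained == 1

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            build_matrix({"a": []})

    def test_ratio_defined_iff_covered_and_in_unit_interval(self, small_cohort):
        m = build_matrix(small_cohort.calls, MatrixFilterParams(min_coverage=1))
        defined = m.ratio.notna()
        assert (defined == (m.coverage > 0)).all().all()
        vals = m.ratio.to_numpy()
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
        assert ok.all()

    @pytest.mark.parametrize("trial", range(30))
    def test_retained_sites_match_brute_force_scan(self, trial):
        rng = np.random.default_rng(100 + trial)
        calls = {f"s{k}": random_calls(rng) for k in range(int(rng.integers(2, 5)))}
        params = MatrixFilterParams(
            min_coverage=int(rng.integers(1, 15)),
            autosomes_only=bool(rng.random() < 0.5),
            require_complete=bool(rng.random() < 0.5),
        )
        m = build_matrix(calls, params)
        expected = brute_matrix_filter(
            calls, params.min_coverage, params.autosomes_only,
            params.require_complete, set(params.autosome_names),
        )
        assert set(m.sites) == expected

    @given(st.integers(1, 30), st.integers(0, 20))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_raising_min_coverage_never_retains_more(self, min_cov, bump):
        rng = np.random.default_rng(min_cov * 31 + bump)
        calls = {f"s{k}": random_calls(rng) for k in range(3)}
        lo = build_matrix(calls, MatrixFilterParams(min_coverage=min_cov))
        hi = build_matrix(calls, MatrixFilterParams(min_coverage=min_cov + bump))
        assert hi.n_retained <= lo.n_retained


class TestRegionMean:
    def test_mean_of_defined_ratios(self):
        calls = {
            "a": [MethylationCall(CpGSite("chr1", 10), 2, 8),
                  MethylationCall(CpGSite("chr1", 20), 4, 6)],
            "b": [MethylationCall(CpGSite("chr1", 10), 5, 5),
                  MethylationCall(CpGSite("chr1", 20), 5, 5)],
        }
        m = build_matrix(calls, MatrixFilterParams(min_coverage=1))
        region = TargetRegion("chr1", 0, 30, "r")
        assert region_mean_methylation(m, region, "a") == pytest.approx(0.3)

    def test_region_without_cpgs_is_missing(self, small_cohort):
        m = build_matrix(small_cohort.calls, MatrixFilterParams(min_coverage=1))
        empty = TargetRegion("chr9", 1, 2, "none")
        assert region_mean_methylation(m, empty, small_cohort.samples[0]) is None

    def test_matches_explicit_site_enumeration(self, small_cohort):
        m = build_matrix(small_cohort.calls, MatrixFilterParams(min_coverage=1))
        sample = small_cohort.samples[3]
        region = small_cohort.regions[7]
        expected = np.mean(
            [
                m.ratio.loc[(c, p), sample]
                for c, p in m.ratio.index
                if c == region.chrom and region.start <= p < region.end
                and not np.isnan(m.ratio.loc[(c, p), sample])
            ]
        )
        assert region_mean_methylation(m, region, sample) == pytest.approx(expected)


class TestCrossPlatform:
    def _single_sample(self, cohort, sample):
        m = build_matrix(cohort.calls, MatrixFilterParams(min_coverage=1))
        return type(m)(ratio=m.ratio[[sample]], coverage=m.coverage[[sample]])

    def test_self_correlation_is_one(self, small_cohort):
        m = self._single_sample(small_cohort, "AML_1")
        r, n = cross_platform_correlation(m, m, min_coverage=10)
        assert r == pytest.approx(1.0)
        assert n > 3

    def test_mirrored_ratios_give_minus_one(self, small_cohort):
        m = self._single_sample(small_cohort, "AML_1")
        flipped = type(m)(ratio=1.0 - m.ratio, coverage=m.coverage)
        r, _ = cross_platform_correlation(m, flipped, min_coverage=10)
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_pearson(self, small_cohort):
        a = self._single_sample(small_cohort, "AML_1")
        b = self._single_sample(small_cohort, "AML_2")
        r, n = cross_platform_correlation(a, b, min_coverage=10)
        shared = a.ratio.index[(a.coverage.iloc[:, 0] >= 10)].intersection(
            b.ratio.index[(b.coverage.iloc[:, 0] >= 10)]
        )
        expected = pearson(a.ratio.loc[shared].iloc[:, 0], b.ratio.loc[shared].iloc[:, 0])
        assert r == pytest.approx(expected, abs=1e-12)

    def test_too_few_shared_sites_error_names_count(self, small_cohort):
        m = self._single_sample(small_cohort, "AML_1")
        with pytest.raises(ValueError, match="0 shared"):
            cross_platform_correlation(m, m, min_coverage=10**6)


def test_matrix_tsv_round_trip(tmp_path, small_cohort):
    m = build_matrix(small_cohort.calls, MatrixFilterParams())
    write_matrix(m, tmp_path / "r.tsv", tmp_path / "c.tsv")
    back = read_matrix(tmp_path / "r.tsv", tmp_path / "c.tsv")
    assert back.ratio.shape == m.ratio.shape
    np.testing.assert_allclose(back.ratio.to_numpy(), m.ratio.to_numpy(), atol=1e-9)
    assert (back.coverage.to_numpy() == m.coverage.to_numpy()).all()
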