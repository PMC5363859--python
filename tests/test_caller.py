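"""Leave-one-out cohort genotyping: profile, modal test, gates, cohort calls."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hpmut.caller import (
    CallerError,
    CallerParams,
    call_cohort,
    call_locus,
    leave_one_out_profile,
    locus_quality,
    mode_agreement_pvalue,
    write_calls,
)
from hpmut.catalog import HomopolymerLocus
from hpmut.filters import MutationRecord
from hpmut.observe import LengthHistogram
from hpmut.simulate import (
    SimConfig,
    simulate_histograms,
    simulate_ma_lines,
    score_recovery,
    synth_genome,
)

from conftest import make_obs


def binom_lower_tail(k: int, n: int, p: float) -> float:
    """Oracle: direct pmf summation P(X <= k), X ~ Binomial(n, p)."""
    return math.fsum(
        math.comb(n, j) * p**j * (1.0 - p) ** (n - j) for j in range(k + 1)
    )


class TestLeaveOneOutProfile:
    def test_point_mass_cohort(self, a12_locus):
        obs = make_obs(
            a12_locus, {f"s{i}": {12: 10 * (i + 1)} for i in range(7)}
        )
        prof = leave_one_out_profile(obs, "s0")
        assert prof.freqs == {12: 1.0}
        assert prof.mode == 12 and prof.p0 == 1.0
        assert prof.n_samples_used == 6

    def test_average_is_unweighted_across_samples(self, a12_locus):
        obs = make_obs(
            a12_locus,
            {"q": {12: 1}, "a": {12: 90, 11: 10}, "b": {12: 50, 11: 50}},
        )
        prof = leave_one_out_profile(obs, "q")
        assert prof.freqs[12] == pytest.approx(0.7)
        assert prof.freqs[11] == pytest.approx(0.3)

    def test_depth_zero_sample_excluded(self, a12_locus):
        obs = make_obs(
            a12_locus, {"q": {12: 5}, "a": {12: 40}, "b": {}, "c": {12: 10}}
        )
        prof = leave_one_out_profile(obs, "q")
        assert prof.n_samples_used == 2

    def test_frequencies_sum_to_one(self, a12_locus):
        obs = make_obs(
            a12_locus,
            {"q": {}, "a": {10: 3, 12: 9}, "b": {11: 7, 13: 2}, "c": {12: 50}},
        )
        prof = leave_one_out_profile(obs, "q")
        assert sum(prof.freqs.values()) == pytest.approx(1.0, abs=1e-9)


class TestModeAgreementPvalue:
    def _profile(self, locus_id, p0, mode=12):
        from hpmut.caller import LocusProfile

        return LocusProfile(locus_id, {mode: p0, mode - 1: 1 - p0}, mode, p0, 7)

    def test_all_mass_at_profile_mode(self):
        h = LengthHistogram("s", "l", {12: 50})
        assert mode_agreement_pvalue(h, self._profile("l", 0.95)) == 1.0

    def test_depleted_sample_matches_summation_oracle(self):
        h = LengthHistogram("s", "l", {11: 48, 12: 2})
        p = mode_agreement_pvalue(h, self._profile("l", 0.95))
        assert p == pytest.approx(binom_lower_tail(2, 50, 0.95), abs=1e-12)
        assert p <= 1e-40

    def test_single_read_cannot_reject(self):
        h = LengthHistogram("s", "l", {12: 1})
        assert mode_agreement_pvalue(h, self._profile("l", 0.5)) == 1.0

    def test_depth_zero_raises(self):
        h = LengthHistogram("s", "l", {})
        with pytest.raises(CallerError):
            mode_agreement_pvalue(h, self._profile("l", 0.9))

    @given(
        n=st.integers(min_value=1, max_value=200),
        k_frac=st.floats(min_value=0.0, max_value=1.0),
        p0=st.floats(min_value=0.01, max_value=0.99),
        other=st.integers(min_value=5, max_value=20),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_exact_summation_for_all_n_to_200(self, n, k_frac, p0, other):
        k = min(n, int(round(k_frac * n)))
        counts = {12: k}
        if n - k:
            counts[11] = n - k
        h = LengthHistogram("s", "l", counts)
        p = mode_agreement_pvalue(h, self._profile("l", p0))
        assert p == pytest.approx(binom_lower_tail(k, n, p0), abs=1e-12)

    def test_monotone_nondecreasing_in_k(self):
        prof = self._profile("l", 0.9)
        n = 60
        last = -1.0
        for k in range(n + 1):
            counts = {12: k} if k else {}
            counts[11] = n - k
            if n - k == 0:
                counts.pop(11)
            p = mode_agreement_pvalue(
                LengthHistogram("s", "l", counts), prof
            )
            assert p >= last
            last = p


class TestLocusQuality:
    def test_point_masses_give_unity(self, a12_locus):
        obs = make_obs(a12_locus, {"a": {12: 30}, "b": {11: 40}})
        assert locus_quality(obs) == 1.0

    def test_mixed_histograms(self, a12_locus):
        obs = make_obs(a12_locus, {"a": {12: 40, 11: 10}, "b": {12: 30, 11: 20}})
        assert locus_quality(obs) == pytest.approx(0.7)

    def test_uniform_histogram(self, a12_locus):
        obs = make_obs(a12_locus, {"a": {10: 5, 11: 5, 12: 5, 13: 5}})
        assert locus_quality(obs) == pytest.approx(0.25)

    def test_no_reads_is_none(self, a12_locus):
        assert locus_quality(make_obs(a12_locus, {"a": {}, "b": {}})) is None


class TestCallLocus:
    def cohort_7v1(self, a12_locus, mutant_depth=50):
        hists = {f"s{i}": {12: 50} for i in range(7)}
        hists["mut"] = {11: mutant_depth}
        return make_obs(a12_locus, hists)

    def test_discriminates_single_mutant_from_seven_reference(self, a12_locus):
        calls = call_locus(self.cohort_7v1(a12_locus))
        by_status = {}
        for c in calls:
            by_status.setdefault(c.status, []).append(c)
        assert len(by_status["reference"]) == 7
        (var,) = by_status["variant"]
        assert var.sample == "mut" and var.delta == -1
        assert var.p_value < 1e-6

    def test_low_depth_sample_is_no_call(self, a12_locus):
        # cohort large enough that one thin sample does not trip the
        # locus-level data-availability gate (15/16 > 44/47)
        hists = {f"s{i}": {12: 50} for i in range(15)}
        hists["mut"] = {11: 4}
        calls = {c.sample: c for c in call_locus(make_obs(a12_locus, hists))}
        assert calls["mut"].status == "no_call"
        assert calls["mut"].reason == "low_depth"
        assert calls["s0"].status == "reference"

    def test_single_thin_sample_gates_small_cohort_locus(self, a12_locus):
        # in an 8-sample cohort the 44/47 data fraction requires all 8
        obs = self.cohort_7v1(a12_locus, mutant_depth=4)
        calls = call_locus(obs)
        assert all(c.reason == "insufficient_data" for c in calls)

    def test_even_split_is_multiallelic_no_call(self, a12_locus):
        hists = {f"a{i}": {12: 50} for i in range(4)}
        hists.update({f"b{i}": {13: 50} for i in range(4)})
        calls = call_locus(make_obs(a12_locus, hists))
        assert all(c.status == "no_call" and c.reason == "multiallelic" for c in calls)

    def test_insufficient_data_fraction_gates_locus(self, a12_locus):
        hists = {f"s{i}": ({12: 50} if i < 5 else {}) for i in range(8)}
        calls = call_locus(make_obs(a12_locus, hists))
        assert all(c.reason == "insufficient_data" for c in calls)

    def test_low_lq_gates_locus(self, a12_locus):
        # every sample maximally dispersed -> LQ well under 0.5
        spread = {length: 10 for length in range(9, 15)}
        hists = {f"s{i}": dict(spread) for i in range(8)}
        calls = call_locus(make_obs(a12_locus, hists))
        assert all(c.reason == "low_lq" for c in calls)

    def test_permutation_equivariance(self, a12_locus):
        obs = self.cohort_7v1(a12_locus)
        base = {c.sample: (c.status, c.delta) for c in call_locus(obs)}
        shuffled = make_obs(
            a12_locus,
            {s: dict(obs.histograms[s].counts) for s in reversed(list(obs.histograms))},
        )
        perm = {c.sample: (c.status, c.delta) for c in call_locus(shuffled)}
        assert base == perm


@pytest.fixture(scope="module")
def loci():
    return synth_genome(SimConfig(), seed=1)[1]


class TestCallCohort:
    def test_no_planted_mutations_yield_zero_variants_over_seeds(self, loci):
        cfg = SimConfig(indel_rate=0.0)
        for seed in range(5):
            truth = simulate_ma_lines(cfg, loci, seed=seed)
            obs = simulate_histograms(cfg, truth, seed=1000 + seed)
            calls = call_cohort(obs)
            assert sum(c.status == "variant" for c in calls) == 0

    def test_planted_mutants_recovered(self, loci):
        cfg = SimConfig(indel_rate=0.0)
        truth = simulate_ma_lines(cfg, loci, seed=7)
        # plant 20 homozygous -1 alleles across distinct loci/lines
        for i in range(20):
            line = truth.lines[i % len(truth.lines)]
            locus = truth.loci[i * 37 % len(truth.loci)]
            truth.alleles[line][locus.locus_id] = locus.ref_length - 1
            truth.records.append(
                MutationRecord(
                    line=line, chrom=locus.chrom, pos=locus.locus_id,
                    kind="hp_indel", delta=-1,
                )
            )
        obs = simulate_histograms(cfg, truth, seed=8)
        calls = call_cohort(obs)
        scores = score_recovery(calls, truth)
        assert scores["n_planted"] == 20
        assert scores["sensitivity"] >= 18 / 20
        assert scores["false_positives"] == 0

    def test_rerun_is_byte_identical(self, loci, tmp_path):
        cfg = SimConfig()
        truth = simulate_ma_lines(cfg, loci, seed=5)
        obs = simulate_histograms(cfg, truth, seed=6)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_calls(call_cohort(obs), p1)
        write_calls(call_cohort(obs), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_mismatched_sample_sets_rejected(self, a12_locus):
        other = HomopolymerLocus("chrI", 2000, 2012, "A")
        obs = [
            make_obs(a12_locus, {"a": {12: 9}, "b": {12: 9}}),
            make_obs(other, {"a": {12: 9}, "c": {12: 9}}),
        ]
        with pytest.raises(CallerError):
            call_cohort(obs)

    def test_variant_and_reference_depths_comparable(self, loci):
        """Planted mutants are not called through a depth artifact: the
        mutant calls' depth distribution sits inside the reference calls'."""
        import numpy as np

        cfg = SimConfig(indel_rate=5e-5)
        truth = simulate_ma_lines(cfg, loci, seed=11)
        obs = simulate_histograms(cfg, truth, seed=12)
        calls = call_cohort(obs)
        var_d = [c.depth for c in calls if c.status == "variant"]
        ref_d = [c.depth for c in calls if c.status == "reference"]
        assert len(var_d) >= 10
        assert abs(np.mean(var_d) - np.mean(ref_d)) < 3 * np.std(ref_d)
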