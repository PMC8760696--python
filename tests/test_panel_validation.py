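"""Reference-standard scoring tests, with brute-force confusion oracles."""

from __future__ import annotations

import numpy as np
import pytest

from mpnpanel.config import PipelineConfig
from mpnpanel.io_formats import (
    CALLER_SMALL,
    FormatError,
    TruthVariant,
    VariantCall,
    VariantKey,
)
from mpnpanel.panel_validation import (
    DetectionMatrix,
    ReplicateCallset,
    build_detection_matrix,
    compute_confusion,
    concordance,
    limit_of_detection,
    match_call_to_truth,
    validate_replicates,
)


def _key(pos, ref="A", alt="T", chrom="chr1"):
    return VariantKey(chrom, pos, ref, alt)


def _tv(std, key, vaf=0.05):
    return TruthVariant(standard_id=std, key=key, expected_vaf=vaf)


def _call(key, sample="R", vaf=0.05):
    return VariantCall(
        sample_id=sample,
        key=key,
        vaf=vaf,
        depth=5000,
        alt_reads=int(round(vaf * 5000)),
        caller=CALLER_SMALL,
    )


class TestMatching:
    def test_exact_key(self):
        key = VariantKey("chr9", 5073770, "G", "T")
        assert match_call_to_truth(key, VariantKey("chr9", 5073770, "G", "T"))

    def test_snv_at_indel_locus_no_match(self):
        assert not match_call_to_truth(
            _key(100, "A", "T"), _key(100, "A", "AGGG")
        )

    def test_shifted_duplication_matches_within_tolerance(self):
        ins = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTAC"  # 42 bases
        truth = VariantKey("chr13", 28608250, "A", "A" + ins)
        for shift in range(0, 11):
            call = VariantKey("chr13", 28608250 - shift, "G", "G" + ins)
            assert match_call_to_truth(call, truth) == (shift <= 5)

    def test_different_insert_length_no_match(self):
        truth = _key(100, "A", "A" + "G" * 10)
        call = _key(100, "A", "A" + "G" * 9)
        assert not match_call_to_truth(call, truth)


class TestDetectionMatrix:
    def test_one_missed_truth_variant(self):
        truth = {"Std": [_tv("Std", _key(100 + 10 * i)) for i in range(20)]}
        calls = tuple(_call(tv.key) for tv in truth["Std"][1:])
        matrix = build_detection_matrix(
            truth, [ReplicateCallset("Std", "rep1", "run1", calls)]
        )
        row = matrix.rows[0]
        assert sum(c.detected for c in row.cells) == 19
        assert len(row.off_truth) == 0

    def test_wildtype_standard_off_truth_call(self):
        truth = {"Neg": []}
        matrix = build_detection_matrix(
            truth, [ReplicateCallset("Neg", "rep1", "run1", (_call(_key(5)),))]
        )
        row = matrix.rows[0]
        assert row.cells == ()
        assert len(row.off_truth) == 1

    def test_empty_callset_all_missed(self):
        truth = {"Std": [_tv("Std", _key(100 + 10 * i)) for i in range(9)]}
        matrix = build_detection_matrix(
            truth, [ReplicateCallset("Std", "rep1", "run1", ())]
        )
        assert sum(not c.detected for c in matrix.rows[0].cells) == 9

    def test_unknown_standard_rejected(self):
        with pytest.raises(FormatError, match="Mystery"):
            build_detection_matrix(
                {"Std": []}, [ReplicateCallset("Mystery", "rep1", "run1", ())]
            )


class TestConfusion:
    def test_simple_counts(self):
        truth = {"Std": [_tv("Std", _key(100 + 10 * i)) for i in range(10)]}
        calls = tuple(_call(tv.key) for tv in truth["Std"][:9])
        matrix = build_detection_matrix(
            truth, [ReplicateCallset("Std", "rep1", "run1", calls)]
        )
        tp, fp, fn, tn = compute_confusion(matrix)
        assert (tp, fn, fp) == (9, 1, 0)

    def test_cross_standard_negative_sites(self):
        # 26 unique truth variants panel-wide; a wild-type replicate with one
        # novel-site FP scores tn=26, fp=1 -> specificity 26/27
        union_keys = [_key(1000 + 10 * i) for i in range(26)]
        truth = {
            "Neg": [],
            "StdA": [_tv("StdA", k) for k in union_keys[:13]],
            "StdB": [_tv("StdB", k) for k in union_keys[13:]],
        }
        fp_call = _call(_key(99, "C", "G"))  # not a truth site anywhere
        matrix = build_detection_matrix(
            truth, [ReplicateCallset("Neg", "rep1", "run1", (fp_call,))]
        )
        tp, fp, fn, tn = compute_confusion(matrix)
        assert (tn, fp) == (26, 1)
        assert tn / (tn + fp) == pytest.approx(26 / 27)
        assert round(100 * tn / (tn + fp), 1) == 96.3

    def test_fp_at_negative_site_consumes_it(self):
        keys = [_key(1000 + 10 * i) for i in range(5)]
        truth = {"Neg": [], "StdA": [_tv("StdA", k) for k in keys]}
        matrix = build_detection_matrix(
            truth, [ReplicateCallset("Neg", "rep1", "run1", (_call(keys[0]),))]
        )
        tp, fp, fn, tn = compute_confusion(matrix)
        assert (tn, fp) == (4, 1)

    def test_oracle_200_random_matrices(self):
        """Confusion counts equal a direct recount over the raw matrix."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n_std = int(rng.integers(1, 4))
            all_keys = [_key(100 + 10 * i) for i in range(int(rng.integers(1, 31)))]
            truth = {}
            for s in range(n_std):
                picks = [k for k in all_keys if rng.random() < 0.6]
                truth[f"Std{s}"] = [_tv(f"Std{s}", k) for k in picks]
            replicates = []
            for s in range(n_std):
                for rep in range(int(rng.integers(1, 3))):
                    detected = [
                        tv.key for tv in truth[f"Std{s}"] if rng.random() < 0.8
                    ]
                    extra = (
                        [_key(9000 + int(rng.integers(100)), "C", "G")]
                        if rng.random() < 0.3
                        else []
                    )
                    replicates.append(
                        ReplicateCallset(
                            f"Std{s}",
                            f"rep{rep}",
                            "run1",
                            tuple(_call(k) for k in detected + extra),
                        )
                    )
            matrix = build_detection_matrix(truth, replicates)
            tp, fp, fn, tn = compute_confusion(matrix)

            # independent recount
            exp_tp = sum(c.detected for row in matrix.rows for c in row.cells)
            exp_fn = sum(not c.detected for row in matrix.rows for c in row.cells)
            exp_fp = sum(len(row.off_truth) for row in matrix.rows)
            union = {tv.key for tvs in truth.values() for tv in tvs}
            exp_tn = 0
            for row in matrix.rows:
                own = {tv.key for tv in truth[row.standard_id]}
                neg = union - own
                hit = sum(
                    1 for c in row.off_truth if any(c.key == k for k in neg)
                )
                exp_tn += len(neg) - hit
            assert (tp, fp, fn, tn) == (exp_tp, exp_fp, exp_fn, exp_tn)
            assert tp + fn == sum(len(row.cells) for row in matrix.rows)


class TestConcordance:
    A = [_tv("S", _key(100 + i * 10)) for i in range(21)]

    def test_identical_sets(self):
        assert concordance(self.A, list(self.A)) == 1.0

    def test_20_of_21(self):
        assert concordance(self.A, self.A[:-1]) == pytest.approx(20 / 21)
        assert round(100 * concordance(self.A, self.A[:-1]), 1) == 95.2

    def test_disjoint(self):
        assert concordance(self.A[:10], self.A[10:]) == 0.0

    def test_both_empty(self):
        assert concordance([], []) == 1.0

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = [tv for tv in self.A if rng.random() < 0.5]
            b = [tv for tv in self.A if rng.random() < 0.5]
            j_ab = concordance(a, b)
            j_ba = concordance(b, a)
            assert j_ab == j_ba
            assert 0.0 <= j_ab <= 1.0
            assert (j_ab == 1.0) == (set(a) == set(b))

    def test_both_detected_mode(self):
        assert concordance(
            self.A[:20], self.A[:19], mode="both_detected", truth_total=21
        ) == pytest.approx(19 / 21)


class TestLimitOfDetection:
    def test_lowest_complete_tier(self):
        truth = {
            "T5": [_tv("T5", _key(100), 0.05)],
            "T13": [_tv("T13", _key(200), 0.013)],
        }
        reps = [
            ReplicateCallset("T5", "rep1", "run1", (_call(_key(100)),)),
            ReplicateCallset("T13", "rep1", "run1", (_call(_key(200)),)),
        ]
        matrix = build_detection_matrix(truth, reps)
        assert limit_of_detection(matrix) == 0.013

    def test_incomplete_low_tier_falls_back(self):
        truth = {
            "T5": [_tv("T5", _key(100), 0.05)],
            "T13": [_tv("T13", _key(200), 0.013)],
        }
        reps = [
            ReplicateCallset("T5", "rep1", "run1", (_call(_key(100)),)),
            ReplicateCallset("T13", "rep1", "run1", ()),  # miss at 1.3%
        ]
        assert limit_of_detection(build_detection_matrix(truth, reps)) == 0.05

    def test_single_tier(self):
        truth = {"T5": [_tv("T5", _key(100), 0.05)]}
        reps = [ReplicateCallset("T5", "rep1", "run1", (_call(_key(100)),))]
        assert limit_of_detection(build_detection_matrix(truth, reps)) == 0.05

    def test_no_tiers_is_error(self):
        truth = {"S": [_tv("S", _key(100), None)]}
        reps = [ReplicateCallset("S", "rep1", "run1", ())]
        with pytest.raises(FormatError):
            limit_of_detection(build_detection_matrix(truth, reps))


class TestEndToEnd:
    def test_perfect_replicates_score_unity(self, truth_sets, sim_config):
        from mpnpanel.synthetic_data import simulate_replicates

        replicates = simulate_replicates(truth_sets, sim_config)
        _, report = validate_replicates(truth_sets, replicates)
        assert report.sensitivity == 1.0
        assert report.specificity == 1.0
        assert report.ppv == 1.0
        assert report.lod_vaf == 0.013

    def test_single_injected_miss(self, truth_sets, sim_config):
        from mpnpanel.synthetic_data import simulate_replicates

        w515l = next(
            tv for tv in truth_sets["SeraseqMyeloid"] if tv.gene == "MPL"
        )
        replicates = simulate_replicates(
            truth_sets,
            sim_config,
            drop=[("SeraseqMyeloid", "rep1", "run2", w515l.key)],
        )
        matrix, report = validate_replicates(truth_sets, replicates)
        total_cells = sum(len(row.cells) for row in matrix.rows)
        assert report.fn == 1
        assert report.sensitivity == pytest.approx(1 - 1 / total_cells)
        # a miss can only lower metrics
        assert report.specificity == 1.0

    def test_removing_detection_lowers_sensitivity_strictly(
        self, truth_sets, sim_config
    ):
        from mpnpanel.synthetic_data import simulate_replicates

        base = validate_replicates(
            truth_sets, simulate_replicates(truth_sets, sim_config)
        )[1]
        key = truth_sets["TruQ1"][0].key
        dropped = validate_replicates(
            truth_sets,
            simulate_replicates(
                truth_sets, sim_config, drop=[("TruQ1", "rep1", "run1", key)]
            ),
        )[1]
        assert dropped.sensitivity < base.sensitivity
        assert dropped.specificity <= base.specificity
        assert dropped.ppv <= base.ppv

    def test_per_app_mode_counts_eligible_cells_twice(self, truth_sets, sim_config):
        from mpnpanel.synthetic_data import simulate_replicates

        cfg = PipelineConfig(counting_mode="per_app")
        replicates = simulate_replicates(truth_sets, sim_config)
        _, report = validate_replicates(truth_sets, replicates, cfg)
        assert report.sensitivity == 1.0
        merged = validate_replicates(truth_sets, replicates)[1]
        assert report.tp > merged.tp
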