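import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, spearmanr

from fitland import (
    SortSeqCounts,
    classify_designs,
    count_exact_matches,
    enrichment_scores,
    filter_min_count,
    fit_hill,
    merge_read_pair,
    population_enrichment,
    simulate_sortseq_counts,
)
from fitland.sortseq import classify_bins, derive_threshold, merge_fastq_pair


def make_counts(rows, wt_id="WT", **kwargs):
    frame = pd.DataFrame(rows).set_index("design_id")
    return SortSeqCounts(frame, wt_id=wt_id, **kwargs)


BASE_ROWS = [
    {"design_id": "WT", "count_u": 100, "count_d": 50, "count_b": 50},
    {"design_id": "A", "count_u": 100, "count_d": 10, "count_b": 90},
]


class TestMergeReadPair:
    def test_zero_overlap_is_concatenation(self):
        merged = merge_read_pair("ACGT", "IIII", "TTAA", "IIII", offset=4)
        assert merged == "ACGTTTAA"

    def test_higher_quality_base_wins(self):
        # overlap at position 3: fwd A (Q30='?') vs rev C (Q20='5')
        merged = merge_read_pair("ACGA", "III?", "CTT", "5II", offset=3)
        assert merged[3] == "A"
        # now give the reverse read the higher quality
        merged = merge_read_pair("ACGA", "III5", "CTT", "?II", offset=3)
        assert merged[3] == "C"

    def test_equal_quality_keeps_forward_base(self):
        merged = merge_read_pair("AAAA", "IIII", "CCCC", "IIII", offset=2)
        assert merged == "AAAACC"

    def test_matches_position_by_position_oracle(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(50):
            lf, lr = int(rng.integers(5, 20)), int(rng.integers(5, 20))
            offset = int(rng.integers(0, lf + 1))
            fwd = "".join(rng.choice(bases, lf))
            rev = "".join(rng.choice(bases, lr))
            fq = rng.integers(2, 40, lf)
            rq = rng.integers(2, 40, lr)
            merged = merge_read_pair(fwd, fq, rev, rq, offset)
            # oracle: walk every merged position explicitly
            expected = []
            for pos in range(max(lf, offset + lr)):
                j = pos - offset
                if pos < lf and 0 <= j < lr:
                    expected.append(rev[j] if rq[j] > fq[pos] else fwd[pos])
                elif pos < lf:
                    expected.append(fwd[pos])
                else:
                    expected.append(rev[j])
            assert merged == "".join(expected)

    def test_gap_beyond_forward_read_rejected(self):
        with pytest.raises(ValueError):
            merge_read_pair("ACGT", "IIII", "AA", "II", offset=6)

    def test_fastq_pair_merging(self, tmp_path):
        fwd = tmp_path / "r1.fastq"
        rev = tmp_path / "r2.fastq"
        # true fragment ACGTACGTCCGG: fwd covers [0,8), rev covers [4,12)
        fwd.write_text("@r1\nACGTACGT\n+\nIIIIIIII\n")
        # reverse read as sequenced: revcomp of the true suffix ACGTCCGG
        rev.write_text("@r1\nCCGGACGT\n+\nIIIIIIII\n")
        merged = merge_fastq_pair(fwd, rev, offset=4)
        assert merged == ["ACGTACGTCCGG"]


class TestCountExactMatches:
    LIB = {"d1": "ACGT", "d2": "ACGA", "d1_syn": "ACGC"}

    def test_exact_match_counts(self):
        counts, unassigned = count_exact_matches(["ACGT", "ACGT", "ACGA"], self.LIB)
        assert counts["d1"] == 2 and counts["d2"] == 1 and counts["d1_syn"] == 0
        assert unassigned == 0

    def test_single_mismatch_is_unassigned(self):
        counts, unassigned = count_exact_matches(["ACGG"], self.LIB)
        assert counts.sum() == 0 and unassigned == 1

    def test_synonymous_controls_counted_separately(self):
        counts, _ = count_exact_matches(["ACGT", "ACGC", "ACGC"], self.LIB)
        assert counts["d1"] == 1 and counts["d1_syn"] == 2

    def test_duplicate_nucleotide_sequences_rejected(self):
        with pytest.raises(ValueError, match="share"):
            count_exact_matches([], {"a": "AC", "b": "AC"})


class TestFilterMinCount:
    def test_below_threshold_removed_boundary_retained(self):
        counts = make_counts(
            BASE_ROWS
            + [
                {"design_id": "low", "count_u": 9, "count_d": 5, "count_b": 5},
                {"design_id": "edge", "count_u": 10, "count_d": 5, "count_b": 5},
            ]
        )
        out = filter_min_count(counts, 10)
        assert "low" not in out.frame.index
        assert "edge" in out.frame.index

    def test_all_above_threshold_is_identity(self):
        counts = make_counts(BASE_ROWS)
        out = filter_min_count(counts, 10)
        assert out.frame.equals(counts.frame)

    def test_wild_type_below_threshold_is_hard_error(self):
        counts = make_counts(
            [{"design_id": "WT", "count_u": 5, "count_d": 5, "count_b": 5}]
        )
        with pytest.raises(ValueError, match="wild type"):
            filter_min_count(counts, 10)


class TestEnrichmentScores:
    def test_wild_type_scores_exactly_zero(self):
        table = enrichment_scores(make_counts(BASE_ROWS))
        assert table.frame.loc["WT", "e_bind"] == 0.0
        assert table.frame.loc["WT", "e_disp"] == 0.0

    def test_design_matching_wild_type_proportions_scores_zero(self):
        rows = BASE_ROWS + [
            {"design_id": "twin", "count_u": 100, "count_d": 50, "count_b": 50}
        ]
        table = enrichment_scores(make_counts(rows))
        assert table.frame.loc["twin", "e_bind"] == pytest.approx(0.0)
        assert table.frame.loc["twin", "e_disp"] == pytest.approx(0.0)

    def test_toy_table_matches_hand_arithmetic(self):
        table = enrichment_scores(make_counts(BASE_ROWS))
        # e_bind(A) = log10(90/10) - log10(50/50) = log10 9
        assert table.frame.loc["A", "e_bind"] == pytest.approx(np.log10(9))
        # hand-evaluated with totals Tu=200, Td=60, Tb=140, weights 0.6/0.4
        assert table.frame.loc["A", "e_disp"] == pytest.approx(-0.0829742, abs=1e-6)

    def test_zero_count_rescued_with_pseudocount_flag(self):
        rows = BASE_ROWS + [
            {"design_id": "dead", "count_u": 50, "count_d": 20, "count_b": 0}
        ]
        table = enrichment_scores(make_counts(rows))
        assert bool(table.frame.loc["dead", "pseudocount"])
        assert np.isfinite(table.frame.loc["dead", "e_bind"])
        assert not table.frame.loc[["WT", "A"], "pseudocount"].any()

    def test_invariant_to_uniform_scaling_of_a_population(self):
        counts = make_counts(BASE_ROWS)
        scaled_rows = [dict(r, count_u=r["count_u"] * 7) for r in BASE_ROWS]
        scaled = make_counts(scaled_rows)
        a = enrichment_scores(counts).frame
        b = enrichment_scores(scaled).frame
        assert np.allclose(a[["e_bind", "e_disp"]], b[["e_bind", "e_disp"]])

    def test_wild_type_zero_counts_rejected(self):
        rows = [{"design_id": "WT", "count_u": 100, "count_d": 0, "count_b": 5}]
        with pytest.raises(ValueError, match="wild type"):
            enrichment_scores(make_counts(rows))


class TestPopulationEnrichment:
    def test_wild_type_scores_zero(self):
        rows = [dict(r, count_l=r["count_u"]) for r in BASE_ROWS]
        counts = make_counts(rows)
        assert population_enrichment(counts, "l")["WT"] == 0.0

    def test_twofold_enrichment_gives_log10_two(self):
        rows = [
            {"design_id": "WT", "count_u": 100, "count_d": 1, "count_b": 1,
             "count_l": 100},
            {"design_id": "A", "count_u": 100, "count_d": 1, "count_b": 1,
             "count_l": 200},
        ]
        e = population_enrichment(make_counts(rows), "l")
        assert e["A"] == pytest.approx(np.log10(2))

    def test_consistent_with_binding_score_when_u_equals_d(self):
        # with the unsorted column equal to the display-only column, the
        # b-vs-u enrichment reduces algebraically to e_bind
        rows = [dict(r, count_u=r["count_d"]) for r in BASE_ROWS]
        counts = make_counts(rows)
        e_b = population_enrichment(counts, "b")
        table = enrichment_scores(counts)
        assert np.allclose(e_b, table.frame["e_bind"])

    def test_missing_population_rejected(self):
        with pytest.raises(ValueError, match="not present"):
            population_enrichment(make_counts(BASE_ROWS), "h")


class TestClassification:
    def _simulated_panel(self, depth=1_000_000, seed=0):
        rng = np.random.default_rng(seed)
        groups = {
            "bind+display": (0.85, 0.75),
            "display-only": (0.85, 0.03),
            "inactive": (0.04, 0.03),
        }
        ids, display, bind, truth = ["WT"], [0.85], [0.75], ["bind+display"]
        for label, (dp, bp) in groups.items():
            for i in range(30):
                ids.append(f"{label}_{i}")
                display.append(np.clip(dp + rng.normal(0, 0.02), 0, 1))
                bind.append(np.clip(bp + rng.normal(0, 0.01), 0, 1))
                truth.append(label)
        counts = simulate_sortseq_counts(
            ids, np.array(display), np.array(bind), depth=depth, seed=seed,
            wt_id="WT",
        )
        return counts, pd.Series(truth, index=pd.Index(ids, name="design_id"))

    def test_threshold_boundary_convention_is_inclusive(self):
        table = enrichment_scores(make_counts(BASE_ROWS))
        calls = classify_designs(table, display_threshold=0.0, bind_threshold=0.0)
        # wild type sits exactly on both thresholds: >= counts as positive
        assert calls.loc["WT", "category"] == "bind+display"

    def test_strongly_negative_scores_fall_in_inactive_quadrant(self):
        rows = BASE_ROWS + [
            {"design_id": "dud", "count_u": 1000, "count_d": 3, "count_b": 1}
        ]
        table = enrichment_scores(make_counts(rows))
        calls = classify_designs(table, display_threshold=-0.3, bind_threshold=-0.3)
        assert calls.loc["dud", "category"] == "inactive"

    def test_quadrant_recovery_from_simulated_counts(self):
        """Calibration-derived thresholds recover the true quadrant for at
        least 95% of designs at sequencing depth 1e6."""
        counts, truth = self._simulated_panel()
        table = enrichment_scores(filter_min_count(counts, 10))
        calibration = pd.DataFrame(
            {
                "design_id": ["bind+display_0", "display-only_0", "inactive_0"],
                "displays": [True, True, False],
                "binds": [True, False, False],
            }
        )
        calls = classify_designs(table, calibration=calibration)
        merged = calls.join(truth.rename("truth"), how="inner")
        accuracy = (merged["category"] == merged["truth"]).mean()
        assert accuracy >= 0.95

    def test_missing_thresholds_and_calibration_rejected(self):
        table = enrichment_scores(make_counts(BASE_ROWS))
        with pytest.raises(ValueError):
            classify_designs(table)

    def test_derive_threshold_is_midpoint_of_group_means(self):
        assert derive_threshold([0.0, 1.0], [3.0, 5.0]) == pytest.approx(2.25)

    def test_bin_classification_uses_midpoint_boundaries(self):
        calibration = {
            "display_only": [-2.0, -2.2],
            "low_bind": [-1.0, -0.8],
            "wt_like": [0.0, 0.1],
            "high_bind": [1.0, 1.2],
        }
        scores = pd.Series({"a": -3.0, "b": -0.9, "c": 0.04, "d": 2.0})
        bins = classify_bins(scores, calibration)
        assert list(bins) == ["display_only", "low_bind", "wt_like", "high_bind"]


class TestSimulationRecovery:
    def test_enrichment_ranks_designs_by_true_binding(self):
        """End-to-end: deep simulated counts -> enrichment scores recover the
        true binding-probability ranking (Spearman > 0.9)."""
        rng = np.random.default_rng(1)
        n = 100
        ids = ["WT"] + [f"d{i}" for i in range(n - 1)]
        display = np.concatenate([[0.8], rng.uniform(0.4, 0.95, n - 1)])
        bind = np.concatenate([[0.6], rng.uniform(0.02, 0.95, n - 1)])
        counts = simulate_sortseq_counts(
            ids, display, bind, depth=1_000_000, seed=2, wt_id="WT"
        )
        table = enrichment_scores(filter_min_count(counts, 10))
        rho = spearmanr(table.frame["e_bind"], bind).statistic
        assert rho > 0.9

    def test_replicate_concordance(self):
        """Two independent count simulations of the same truth give highly
        correlated binding enrichments (Pearson r > 0.9)."""
        rng = np.random.default_rng(3)
        n = 100
        ids = ["WT"] + [f"d{i}" for i in range(n - 1)]
        display = np.concatenate([[0.8], rng.uniform(0.4, 0.95, n - 1)])
        bind = np.concatenate([[0.6], rng.uniform(0.02, 0.95, n - 1)])
        tables = []
        for seed in (10, 11):
            counts = simulate_sortseq_counts(
                ids, display, bind, depth=1_000_000, seed=seed, wt_id="WT"
            )
            tables.append(enrichment_scores(filter_min_count(counts, 10)).frame)
        r = pearsonr(tables[0]["e_bind"], tables[1]["e_bind"]).statistic
        assert r > 0.9

    def test_synonymous_controls_score_within_noise(self):
        """Two designs encoding the same protein (identical phenotype) get
        nearly identical binding enrichments at high depth."""
        ids = ["WT", "ctrl_synA", "ctrl_synB", "other"]
        display = np.array([0.8, 0.6, 0.6, 0.3])
        bind = np.array([0.6, 0.4, 0.4, 0.1])
        counts = simulate_sortseq_counts(ids, display, bind, depth=1_000_000,
                                         seed=4, wt_id="WT")
        table = enrichment_scores(counts).frame
        assert abs(
            table.loc["ctrl_synA", "e_bind"] - table.loc["ctrl_synB", "e_bind"]
        ) < 0.05


class TestHillFit:
    def test_noiseless_parameter_recovery(self):
        kd, bmax = 15.0, 2.0
        c = np.array([0.1, 0.5, 1, 3, 10, 15, 30, 100, 300])
        s = bmax * c / (kd + c)
        fit = fit_hill(c, s)
        assert fit.kd == pytest.approx(kd, rel=1e-6)
        assert fit.bmax == pytest.approx(bmax, rel=1e-6)
        assert fit.kd_defined

    def test_half_saturation_at_kd(self):
        c = np.array([1.0, 5.0, 15.0, 50.0, 500.0])
        s = 2.0 * c / (15.0 + c)
        fit = fit_hill(c, s)
        assert fit.bmax * fit.kd / (fit.kd + fit.kd) == pytest.approx(
            fit.bmax / 2
        )

    def test_all_zero_signals_degenerate(self):
        fit = fit_hill([1, 10, 100], [0.0, 0.0, 0.0])
        assert fit.bmax == 0.0
        assert not fit.kd_defined
        assert np.isnan(fit.kd)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_hill([1, 10], [0.1, 0.2])
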