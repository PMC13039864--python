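"""Trajectory stratification: status calls, ratio bins, the 3x3 truth table,
cross-model intersection and threshold monotonicity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betatraj import (
    ALL_LABELS,
    CATEGORIES,
    ComparisonResult,
    DETable,
    SimulationConfig,
    Thresholds,
    bin_ratio,
    call_status,
    category_sets,
    classify_gene,
    intersect_models,
    run_contrasts,
    simulate,
    stratify,
    stratify_model,
)


class TestCallStatus:
    @pytest.mark.parametrize(
        "fc, p, expected",
        [
            (3.0, 0.01, "UP"),
            (0.4, 0.01, "DOWN"),
            (0.4, 0.2, "NS"),  # fails p
            (1.2, 0.001, "NS"),  # fails FC
            (2.0, 0.01, "NS"),  # strict boundary: FC > 2.0 excludes 2.0
            (0.5, 0.01, "NS"),
        ],
    )
    def test_default_strict_thresholds(self, fc, p, expected):
        assert call_status(fc, p) == expected

    def test_inclusive_fc_flag_flips_the_boundary(self):
        inclusive = Thresholds(strict_fc=False)
        assert call_status(2.0, 0.01, inclusive) == "UP"
        assert call_status(0.5, 0.01, inclusive) == "DOWN"


class TestBinRatio:
    @pytest.mark.parametrize(
        "r, expected",
        [
            (6 / 2, "INCREASING"),  # the worked example: FC 2 then 6
            (1.5, "NEAR_CONSTANT"),  # boundaries belong to near-constant
            (0.5, "NEAR_CONSTANT"),
            (0.4, "DECREASING"),
            (1.51, "INCREASING"),
        ],
    )
    def test_bins(self, r, expected):
        assert bin_ratio(r) == expected

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            bin_ratio(0.0)

    @given(st.floats(1e-6, 1e6))
    @settings(max_examples=200, deadline=None)
    def test_total_on_positive_reals(self, r):
        assert bin_ratio(r) in {"INCREASING", "DECREASING", "NEAR_CONSTANT"}


def truth_table_oracle(s20, s35, r):
    """Hand-enumerated mapping of all 9 status pairs."""
    if (s20, s35) == ("UP", "UP"):
        bin_ = "INCREASING" if r > 1.5 else ("DECREASING" if r < 0.5 else "NEAR_CONSTANT")
        return f"UP_BOTH_{bin_}"
    return {
        ("UP", "NS"): "UP_D20_ONLY",
        ("UP", "DOWN"): "DISCORDANT",
        ("NS", "UP"): "UP_D35_ONLY",
        ("NS", "NS"): "UNCLASSIFIED",
        ("NS", "DOWN"): "DOWN_D35_ONLY",
        ("DOWN", "UP"): "DISCORDANT",
        ("DOWN", "NS"): "DOWN_D20_ONLY",
        ("DOWN", "DOWN"): "DOWN_BOTH",
    }[(s20, s35)]


class TestClassifyGene:
    def test_worked_example_up_both_increasing(self):
        assert classify_gene("UP", "UP", 3.0) == "UP_BOTH_INCREASING"

    @pytest.mark.parametrize("s20", ["UP", "DOWN", "NS"])
    @pytest.mark.parametrize("s35", ["UP", "DOWN", "NS"])
    @pytest.mark.parametrize("r", [0.3, 1.0, 3.0])
    def test_exhaustive_status_pairs_match_hand_enumeration(self, s20, s35, r):
        assert classify_gene(s20, s35, r) == truth_table_oracle(s20, s35, r)


def _random_assignment(rng, genes):
    rows = []
    for g in genes:
        s20, s35 = rng.choice(["UP", "DOWN", "NS"], size=2)
        r = float(rng.uniform(0.1, 5.0))
        rows.append(
            {
                "status_d20": s20,
                "status_d35": s35,
                "r": r,
                "category": classify_gene(s20, s35, r),
            }
        )
    return pd.DataFrame(rows, index=genes)


class TestIntersectModels:
    def test_identical_assignments_intersect_to_themselves(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(50)]
        assignment = _random_assignment(rng, genes)
        sets = category_sets(assignment)
        inter = intersect_models({"m1": sets, "m2": sets})
        for label in ALL_LABELS:
            assert inter[label] == sorted(sets[label])

    def test_disagreeing_ratio_bin_drops_the_gene_everywhere(self):
        a = pd.DataFrame(
            [{"status_d20": "UP", "status_d35": "UP", "r": 3.0, "category": "UP_BOTH_INCREASING"}],
            index=["G1"],
        )
        b = pd.DataFrame(
            [{"status_d20": "UP", "status_d35": "UP", "r": 1.0, "category": "UP_BOTH_NEAR_CONSTANT"}],
            index=["G1"],
        )
        inter = intersect_models({"m1": category_sets(a), "m2": category_sets(b)})
        assert all(not inter[label] for label in ALL_LABELS)

    def test_matches_brute_force_double_loop_on_random_assignments(self):
        rng = np.random.default_rng(7)
        genes = [f"G{i:03d}" for i in range(200)]
        a = _random_assignment(rng, genes)
        b = _random_assignment(rng, genes)
        inter = intersect_models({"m1": category_sets(a), "m2": category_sets(b)})
        for label in ALL_LABELS:
            brute = sorted(
                g
                for g in genes
                if a.loc[g, "category"] == label and b.loc[g, "category"] == label
            )
            assert inter[label] == brute

    def test_single_model_is_an_error(self):
        with pytest.raises(ValueError, match="per-model"):
            intersect_models({"m1": {}})


class TestDiscordantHandling:
    def test_discordant_optionally_counted_in_only_sets(self):
        assignment = pd.DataFrame(
            [
                {"status_d20": "UP", "status_d35": "DOWN", "r": 0.1, "category": "DISCORDANT"},
                {"status_d20": "DOWN", "status_d35": "UP", "r": 9.0, "category": "DISCORDANT"},
            ],
            index=["G1", "G2"],
        )
        plain = category_sets(assignment)
        assert plain["DISCORDANT"] == {"G1", "G2"}
        assert not plain["UP_D20_ONLY"]
        counted = category_sets(assignment, count_discordant_in_only=True)
        assert counted["UP_D20_ONLY"] == {"G1"}
        assert counted["DOWN_D35_ONLY"] == {"G1"}
        assert counted["DOWN_D20_ONLY"] == {"G2"}
        assert counted["UP_D35_ONLY"] == {"G2"}


def _de_tables(fc_p):
    """Build (D20, D35) DE tables from {gene: (fc20, p20, fc35, p35)}."""
    genes = list(fc_p)
    d20 = DETable(
        pd.DataFrame(
            {
                "gene_id": genes,
                "fold_change": [fc_p[g][0] for g in genes],
                "p_value": [fc_p[g][1] for g in genes],
            }
        )
    )
    d35 = DETable(
        pd.DataFrame(
            {
                "gene_id": genes,
                "fold_change": [fc_p[g][2] for g in genes],
                "p_value": [fc_p[g][3] for g in genes],
            }
        )
    )
    return d20, d35


class TestStratify:
    def test_every_gene_gets_exactly_one_label(self):
        rng = np.random.default_rng(5)
        fc_p = {
            f"G{i}": (
                float(rng.lognormal(0, 1.5)),
                float(rng.uniform()),
                float(rng.lognormal(0, 1.5)),
                float(rng.uniform()),
            )
            for i in range(300)
        }
        d20, d35 = _de_tables(fc_p)
        assignment = stratify_model(d20, d35)
        assert len(assignment) == 300
        assert assignment["category"].isin(ALL_LABELS).all()

    def test_zero_noise_synthetic_recovery_is_complete(self):
        matrix, sheet, truth = simulate(SimulationConfig(noise_sd=0.0))
        result = stratify(run_contrasts(matrix, sheet))
        recovered = {g: lab for lab in ALL_LABELS for g in result.intersected[lab]}
        for gene, planted in truth.data["category"].items():
            assert recovered[gene] == planted

    def test_threshold_monotonicity(self):
        """Raising fc_up shrinks UP sets; lowering p_max shrinks UP and DOWN."""
        rng = np.random.default_rng(9)
        fc_p = {
            f"G{i}": (
                float(rng.lognormal(0, 1.5)),
                float(rng.uniform()),
                float(rng.lognormal(0, 1.5)),
                float(rng.uniform()),
            )
            for i in range(400)
        }
        d20, d35 = _de_tables(fc_p)

        def up_down(thresholds):
            assignment = stratify_model(d20, d35, thresholds)
            up = set(assignment.index[assignment["status_d20"] == "UP"])
            down = set(assignment.index[assignment["status_d20"] == "DOWN"])
            return up, down

        up_base, down_base = up_down(Thresholds())
        up_strict, _ = up_down(Thresholds(fc_up=3.0))
        assert up_strict <= up_base
        up_lowp, down_lowp = up_down(Thresholds(p_max=0.01))
        assert up_lowp <= up_base and down_lowp <= down_base

    def test_determinism(self):
        matrix, sheet, _ = simulate(SimulationConfig(seed=2))
        first = stratify(run_contrasts(matrix, sheet))
        second = stratify(run_contrasts(matrix, sheet))
        assert first.intersected == second.intersected
        for model in first.per_model:
            pd.testing.assert_frame_equal(first.per_model[model], second.per_model[model])

    def test_up_both_bins_partition_the_up_both_set(self):
        matrix, sheet, _ = simulate(SimulationConfig(noise_sd=0.25, seed=4))
        result = stratify(run_contrasts(matrix, sheet))
        assignment = result.per_model["hESC"]
        up_both = set(
            assignment.index[
                (assignment["status_d20"] == "UP") & (assignment["status_d35"] == "UP")
            ]
        )
        bins = [
            set(assignment.index[assignment["category"] == f"UP_BOTH_{b}"])
            for b in ("INCREASING", "DECREASING", "NEAR_CONSTANT")
        ]
        assert bins[0] | bins[1] | bins[2] == up_both
        assert not (bins[0] & bins[1] or bins[0] & bins[2] or bins[1] & bins[2])

    def test_missing_contrast_is_an_error(self):
        matrix, sheet, _ = simulate(SimulationConfig(noise_sd=0.0))
        comparisons = [c for c in run_contrasts(matrix, sheet) if c.target == "D20"]
        with pytest.raises(ValueError, match="D35"):
            stratify(comparisons)
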