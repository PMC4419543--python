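import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from slicethick.datasets import (
    FRESH_BRAIN,
    FRESH_LIVER,
    PFA_BRAIN,
    load_reference_summary,
    overall_error_discrepancies,
    reference_study_design,
)
from slicethick.errors import ValidationError
from slicethick.stats import (
    compact_letter_display,
    one_way_anova,
    overall_error,
    summarize_combos,
    thickness_error_pct,
    tukey_grouping,
    two_way_anova,
)
from slicethick.synthetic import generate_study


def records_from_cells(cells):
    """cells: dict {(step, speed): list of thickness values}."""
    rows = []
    for (step, speed), values in cells.items():
        for v in values:
            rows.append({"tissue": "t", "step_size_um": step, "speed_mm_s": speed,
                         "thickness_um": float(v)})
    return pd.DataFrame(rows)


def brute_force_two_way_ss(cells):
    """Textbook balanced two-way ANOVA sums of squares from group sums."""
    a_levels = sorted({k[0] for k in cells})
    b_levels = sorted({k[1] for k in cells})
    n = len(next(iter(cells.values())))
    allv = [v for vs in cells.values() for v in vs]
    grand = sum(allv) / len(allv)
    ss_total = sum((v - grand) ** 2 for v in allv)
    mean_a = {a: np.mean([v for (aa, b) in cells for v in cells[(aa, b)] if aa == a])
              for a in a_levels}
    mean_b = {b: np.mean([v for (a, bb) in cells for v in cells[(a, bb)] if bb == b])
              for b in b_levels}
    ss_a = n * len(b_levels) * sum((mean_a[a] - grand) ** 2 for a in a_levels)
    ss_b = n * len(a_levels) * sum((mean_b[b] - grand) ** 2 for b in b_levels)
    cell_mean = {k: np.mean(v) for k, v in cells.items()}
    ss_err = sum((v - cell_mean[k]) ** 2 for k, vs in cells.items() for v in vs)
    ss_ab = ss_total - ss_a - ss_b - ss_err
    return ss_a, ss_b, ss_ab, ss_err, ss_total


class TestThicknessError:
    def test_reference_cells_match_printed_error_column(self):
        printed = {
            (FRESH_LIVER, 200, 0.1): 130.2,
            (FRESH_LIVER, 200, 0.2): 103.65,
            (FRESH_LIVER, 200, 0.4): 174.9,
            (FRESH_LIVER, 400, 0.1): 43.9,
            (FRESH_LIVER, 400, 0.2): 47.875,
            (FRESH_LIVER, 400, 0.4): 104.8,
            (FRESH_BRAIN, 200, 0.2): 60.15,
            (FRESH_BRAIN, 400, 0.2): 58.35,
            (PFA_BRAIN, 100, 0.05): 48.0,
            (PFA_BRAIN, 100, 0.2): 61.1,
            (PFA_BRAIN, 200, 0.05): 16.6,
            (PFA_BRAIN, 200, 0.2): 33.1,
            (PFA_BRAIN, 400, 0.05): 40.65,
            (PFA_BRAIN, 400, 0.2): 33.375,
        }
        df = load_reference_summary()
        for _, row in df.iterrows():
            key = (row["tissue"], row["step_size_um"], row["speed_mm_s"])
            err = thickness_error_pct(row["mean_um"], row["step_size_um"])
            assert err == pytest.approx(printed[key], abs=5e-4), key

    def test_zero_error_when_mean_equals_step(self):
        assert thickness_error_pct(400.0, 400.0) == 0.0

    def test_unit_invariance(self):
        um = thickness_error_pct(460.4, 200.0)
        mm = thickness_error_pct(0.4604, 0.2)
        assert um == pytest.approx(mm)

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValidationError):
            thickness_error_pct(100.0, 0.0)


class TestSummaries:
    def test_summarize_combos_brute_force(self):
        cells = {(200, 0.1): [180, 220, 260], (400, 0.1): [390, 410]}
        combos = summarize_combos(records_from_cells(cells))
        row = combos[combos["step_size_um"] == 200].iloc[0]
        assert row["n"] == 3
        assert row["mean_um"] == pytest.approx(220.0)
        assert row["sd_um"] == pytest.approx(np.std([180, 220, 260], ddof=1))
        assert row["error_pct"] == pytest.approx((220 - 200) / 200 * 100)
        assert len(combos) == 2  # absent cells yield no row

    def test_empty_records_rejected(self):
        with pytest.raises(ValidationError):
            summarize_combos(pd.DataFrame())

    def test_overall_error_exact_arithmetic(self):
        df = load_reference_summary().rename(columns={"mean_um": "thickness_um"})
        # treat each printed cell mean as a single record: cell means (and
        # hence error%) are then reproduced exactly
        combos = summarize_combos(df[["tissue", "step_size_um", "speed_mm_s",
                                      "thickness_um"]])
        overall = overall_error(combos).set_index("tissue")["overall_error_pct"]
        assert overall[FRESH_LIVER] == pytest.approx(100.8875, abs=1e-10)
        assert overall[FRESH_BRAIN] == pytest.approx(59.25, abs=1e-10)
        assert overall[PFA_BRAIN] == pytest.approx(232.825 / 6, abs=1e-10)

    def test_single_combo_overall_equals_its_error(self):
        combos = summarize_combos(records_from_cells({(200, 0.1): [300.0, 300.0]}))
        overall = overall_error(combos)
        assert overall["overall_error_pct"].iloc[0] == pytest.approx(50.0)

    def test_printed_overalls_flagged_where_rounding_disagrees(self):
        disc = overall_error_discrepancies().set_index("tissue")
        assert bool(disc.loc[FRESH_LIVER, "discrepant"])
        assert bool(disc.loc[FRESH_BRAIN, "discrepant"])
        assert not bool(disc.loc[PFA_BRAIN, "discrepant"])


class TestAnova:
    def test_two_way_matches_textbook_formulas(self, rng):
        cells = {
            (a, b): list(rng.normal(100 + 10 * a + 5 * b, 8, 3))
            for a in (1, 2) for b in (1, 2)
        }
        table = two_way_anova(records_from_cells(cells))
        ss_a, ss_b, ss_ab, ss_err, ss_total = brute_force_two_way_ss(cells)
        assert table.loc["step_size_um", "sum_sq"] == pytest.approx(ss_a)
        assert table.loc["speed_mm_s", "sum_sq"] == pytest.approx(ss_b)
        assert table.loc["step_size_um:speed_mm_s", "sum_sq"] == pytest.approx(ss_ab)
        assert table.loc["residual", "sum_sq"] == pytest.approx(ss_err)
        # balanced decomposition is exact
        assert table["sum_sq"].sum() == pytest.approx(ss_total, rel=1e-12)
        f_expected = (ss_a / 1) / (ss_err / 8)
        assert table.loc["step_size_um", "F"] == pytest.approx(f_expected)
        assert table.loc["step_size_um", "p"] == pytest.approx(
            sps.f.sf(f_expected, 1, 8)
        )

    def test_shifted_cell_detected_with_tiny_p(self, rng):
        cells = {
            (a, b): list(rng.normal(100, 5, 6)) for a in (1, 2, 3) for b in (1, 2)
        }
        cells[(3, 2)] = [v + 50 for v in cells[(3, 2)]]  # +10 x SD shift
        table = two_way_anova(records_from_cells(cells))
        assert (table.drop(index="residual")["p"] < 1e-6).any()

    def test_one_way_f_equals_t_squared_for_two_groups(self, rng):
        g1 = rng.normal(100, 10, 8)
        g2 = rng.normal(120, 10, 9)
        records = records_from_cells({(200, 0.2): g1, (400, 0.2): g2})
        table = one_way_anova(records)
        t, p = sps.ttest_ind(g1, g2, equal_var=True)
        assert table.loc["step_size_um", "F"] == pytest.approx(t**2)
        assert table.loc["step_size_um", "p"] == pytest.approx(p)

    def test_identical_groups_give_zero_between_ss(self):
        records = records_from_cells({(200, 0.2): [1, 2, 3], (400, 0.2): [1, 2, 3]})
        table = one_way_anova(records)
        assert table.loc["step_size_um", "sum_sq"] == pytest.approx(0.0, abs=1e-10)
        assert table.loc["step_size_um", "F"] == pytest.approx(0.0, abs=1e-10)

    def test_one_way_three_groups_brute_force(self, rng):
        groups = {s: list(rng.normal(2 * s, 25, 6)) for s in (100, 200, 400)}
        records = records_from_cells({(s, 0.2): v for s, v in groups.items()})
        table = one_way_anova(records)
        allv = [v for vs in groups.values() for v in vs]
        grand = np.mean(allv)
        ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_within = sum((x - np.mean(v)) ** 2 for v in groups.values() for x in v)
        assert table.loc["step_size_um", "sum_sq"] == pytest.approx(ss_between)
        assert table.loc["residual", "sum_sq"] == pytest.approx(ss_within)

    def test_single_level_factor_rejected(self):
        records = records_from_cells({(200, 0.2): [1, 2], (200, 0.4): [3, 4]})
        with pytest.raises(ValidationError):
            two_way_anova(records)
        with pytest.raises(ValidationError):
            one_way_anova(records)

    def test_singleton_cells_need_interaction_dropped(self):
        records = records_from_cells(
            {(200, 0.1): [1.0], (200, 0.2): [2.0], (400, 0.1): [3.0], (400, 0.2): [4.0]}
        )
        with pytest.raises(ValidationError, match="interaction"):
            two_way_anova(records)
        table = two_way_anova(records, interaction=False)
        assert "step_size_um" in table.index


class TestTukey:
    def test_well_separated_groups_get_distinct_letters(self, rng):
        records = records_from_cells(
            {(s, 0.2): rng.normal(mu, 2, 6) for s, mu in [(100, 100), (200, 200), (400, 300)]}
        )
        grouping = tukey_grouping(records)
        letter_sets = [grouping.letters[g] for g in grouping.groups]
        for s1, s2 in itertools.combinations(letter_sets, 2):
            assert not (s1 & s2)

    def test_identical_groups_share_one_letter(self):
        records = records_from_cells(
            {(s, 0.2): [10, 20, 30, 40] for s in (100, 200, 400)}
        )
        grouping = tukey_grouping(records)
        assert all(grouping.letters[g] == frozenset({"a"}) for g in grouping.groups)

    def test_letters_match_pairwise_p_threshold(self, rng):
        records = generate_study(reference_study_design(PFA_BRAIN), seed=3)
        grouping = tukey_grouping(records, by_cell=True)
        for g1, g2 in itertools.combinations(grouping.groups, 2):
            shares = bool(grouping.letters[g1] & grouping.letters[g2])
            assert shares == (grouping.p_values.loc[g1, g2] >= grouping.alpha)

    def test_fewer_than_two_groups_rejected(self):
        records = records_from_cells({(200, 0.2): [1, 2, 3]})
        with pytest.raises(ValidationError):
            tukey_grouping(records)


class TestCompactLetterDisplay:
    def test_middle_group_bridges_its_neighbours(self):
        # only the pair (g0, g1) is non-significant
        sig = {frozenset({"g0", "g2"}), frozenset({"g1", "g2"})}
        letters = compact_letter_display(
            ["g0", "g1", "g2"], lambda a, b: frozenset({a, b}) in sig
        )
        assert letters["g0"] & letters["g1"]
        assert not (letters["g0"] & letters["g2"])
        assert not (letters["g1"] & letters["g2"])

    def test_iff_property_on_random_significance_patterns(self, rng):
        for _ in range(40):
            k = int(rng.integers(2, 8))
            groups = [f"g{i}" for i in range(k)]
            pmat = {frozenset(p): float(rng.uniform()) for p in itertools.combinations(groups, 2)}
            letters = compact_letter_display(
                groups, lambda a, b: pmat[frozenset({a, b})] < 0.3
            )
            for a, b in itertools.combinations(groups, 2):
                shares = bool(letters[a] & letters[b])
                assert shares == (pmat[frozenset({a, b})] >= 0.3)
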