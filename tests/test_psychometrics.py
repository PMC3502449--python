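"""Instability, reliability and validity statistics against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from emadiary.psychometrics import (
    InstabilitySummary,
    compute_instability_summaries,
    cronbach_alpha,
    instability_table,
    mssd,
    reactivity_mean,
    spearman_rho,
    validity_table,
    within_person_sd,
)
from emadiary.scoring import PersonSummary
from emadiary.session_engine import SessionEntry


# --- pure-python reference implementations (independent of numpy paths) -----

def mssd_oracle(xs):
    diffs = [(b - a) ** 2 for a, b in zip(xs, xs[1:])]
    return sum(diffs) / len(diffs)


def sd_oracle(xs):
    m = sum(xs) / len(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def alpha_oracle(rows):
    k = len(rows[0])
    n = len(rows)

    def var(col):
        m = sum(col) / n
        return sum((v - m) ** 2 for v in col) / (n - 1)

    items = [var([r[j] for r in rows]) for j in range(k)]
    totals = var([sum(r) for r in rows])
    if totals == 0:
        return None
    return k / (k - 1) * (1 - sum(items) / totals)


def rank_oracle(xs):
    order = sorted(range(len(xs)), key=lambda i: xs[i])
    ranks = [0.0] * len(xs)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and xs[order[j + 1]] == xs[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for idx in order[i : j + 1]:
            ranks[idx] = avg
        i = j + 1
    return ranks


def spearman_oracle(xs, ys):
    rx, ry = rank_oracle(xs), rank_oracle(ys)
    n = len(xs)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


class TestMSSD:
    @pytest.mark.parametrize(
        "series,expected", [([1, 1, 1], 0.0), ([1, 3], 4.0), ([2, 4, 2], 4.0)]
    )
    def test_hand_oracles(self, series, expected):
        assert mssd(series) == pytest.approx(expected)

    def test_gaps_dropped_before_differencing(self):
        assert mssd([2, None, 4]) == pytest.approx(4.0)

    def test_undefined_below_two_points(self):
        assert mssd([3]) is None
        assert mssd([]) is None


class TestWithinPersonSD:
    def test_hand_oracles(self):
        assert within_person_sd([1, 1, 1]) == pytest.approx(0.0)
        assert within_person_sd([1, 3]) == pytest.approx(math.sqrt(2))
        assert within_person_sd(list(range(1, 8))) == pytest.approx(math.sqrt(28 / 6))

    def test_undefined_below_two_points(self):
        assert within_person_sd([5]) is None


class TestCronbachAlpha:
    def test_identical_items_give_unity(self):
        assert cronbach_alpha([[1, 1], [2, 2], [3, 3]]) == pytest.approx(1.0)

    def test_opposed_items_are_degenerate(self):
        assert cronbach_alpha([[1, 3], [2, 2], [3, 1]]) is None

    def test_independent_noise_alpha_near_zero(self, rng):
        X = rng.integers(1, 8, size=(10000, 2)).astype(float)
        assert abs(cronbach_alpha(X)) < 0.1

    def test_matches_covariance_form(self, rng):
        """alpha equals the covariance-matrix form k/(k-1)(1 - tr C / sum C)."""
        for _ in range(50):
            X = rng.normal(size=(int(rng.integers(5, 40)), int(rng.integers(2, 6))))
            C = np.cov(X, rowvar=False)
            k = X.shape[1]
            expected = k / (k - 1) * (1 - np.trace(C) / C.sum())
            assert cronbach_alpha(X) == pytest.approx(expected, abs=1e-12)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            cronbach_alpha([[1.0, 2.0]])


class TestSpearman:
    def test_perfect_orderings(self):
        rho, p = spearman_rho([1, 2, 3, 4, 5, 6, 7, 8, 9, 10], list(range(10)))
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_rho(list(range(10)), list(range(10, 0, -1)))
        assert rho == pytest.approx(-1.0)

    def test_tie_aware_rank_oracle(self):
        rho, _ = spearman_rho([1, 2, 2, 4], [2, 3, 3, 5], method="t")
        assert rho == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        assert spearman_rho([1, 1, 1, 1], [1, 2, 3, 4]) == (None, None)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        rho1, p1 = spearman_rho(x, y)
        rho2, p2 = spearman_rho(np.exp(x), y**3)
        assert rho1 == pytest.approx(rho2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_exact_permutation_p_matches_bruteforce(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        rho, p = spearman_rho(x, y, method="exact")
        # brute force: share of permutations with |rho| at least as extreme
        rhos = [spearman_oracle(x, [y[i] for i in perm]) for perm in itertools.permutations(range(5))]
        expected = sum(1 for r in rhos if abs(r) >= abs(rho) - 1e-12) / len(rhos)
        assert p == pytest.approx(expected)

    def test_agrees_with_rank_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 25))
            x = rng.integers(1, 8, size=n).astype(float)
            y = rng.integers(1, 8, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = spearman_rho(x, y, method="t")
            assert rho == pytest.approx(spearman_oracle(list(x), list(y)), abs=1e-10)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [1, 2, 3])


class TestValidityTable:
    def make_inputs(self, rho_sign=1.0, n=12):
        rng = np.random.default_rng(42)
        diary = rng.uniform(1.5, 6.5, size=n)
        ratings = diary * rho_sign + rng.normal(0, 0.2, size=n)
        summaries = [
            PersonSummary(f"P{i}", {"anxiety": diary[i]}, 30, 42, True) for i in range(n)
        ]
        interviews = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(n)],
                "occasion": ["followup"] * n,
                "item_code": ["PANSS_G2"] * n,
                "rating": ratings,
            }
        )
        return summaries, interviews

    def test_high_validity_data_gives_positive_rho(self):
        summaries, interviews = self.make_inputs()
        table = validity_table(summaries, interviews, {"anxiety": "PANSS_G2"})
        assert (table["rho"] > 0).all()

    def test_rarely_endorsed_scale_excluded_and_flagged(self):
        summaries, interviews = self.make_inputs()
        for i, s in enumerate(summaries):
            floor = 1.0 if i >= 2 else 3.0  # only two participants endorse
            summaries[i] = PersonSummary(s.participant_id, {"anxiety": floor}, 30, 42, True)
        table = validity_table(summaries, interviews, {"anxiety": "PANSS_G2"})
        assert table["rho"].isna().all()
        assert "endorsed by 2" in table["flag"].iloc[0]

    def test_constant_interview_column_flagged_undefined(self):
        summaries, interviews = self.make_inputs()
        interviews["rating"] = 3.0
        table = validity_table(summaries, interviews, {"anxiety": "PANSS_G2"})
        assert table["rho"].isna().all()
        assert "zero variance" in table["flag"].iloc[0]

    def test_empty_mapping_rejected(self):
        summaries, interviews = self.make_inputs()
        with pytest.raises(ValueError, match="mapping"):
            validity_table(summaries, interviews, {})

    def test_unmapped_interview_code_rejected(self):
        summaries, interviews = self.make_inputs()
        with pytest.raises(ValueError, match="PANSS_P1"):
            validity_table(summaries, interviews, {"delusions": "PANSS_P1"})

    def test_rows_sorted_by_descending_rho(self):
        rng = np.random.default_rng(5)
        n = 15
        diary = rng.uniform(1.5, 6.5, size=n)
        summaries = [
            PersonSummary(
                f"P{i}",
                {"anxiety": diary[i], "guilt": diary[i], "hostility": diary[i]},
                30, 42, True,
            )
            for i in range(n)
        ]
        frames = []
        for code, noise in [("PANSS_G2", 0.1), ("PANSS_G3", 1.5), ("PANSS_P7", 5.0)]:
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": [f"P{i}" for i in range(n)],
                        "occasion": "followup",
                        "item_code": code,
                        "rating": diary + rng.normal(0, noise, n),
                    }
                )
            )
        interviews = pd.concat(frames)
        table = validity_table(
            summaries, interviews,
            {"anxiety": "PANSS_G2", "guilt": "PANSS_G3", "hostility": "PANSS_P7"},
        )
        rhos = table["rho"].dropna().tolist()
        assert rhos == sorted(rhos, reverse=True)


class TestInstabilityTable:
    def test_constant_responses_give_all_zeros(self):
        scores = pd.DataFrame(
            {
                "participant_id": ["P1"] * 5 + ["P2"] * 5,
                "day": [1, 1, 2, 2, 3] * 2,
                "alarm_index": [1, 3, 7, 9, 13] * 2,
                "scale_id": "anxiety",
                "value": 2.0,
            }
        )
        table = instability_table(compute_instability_summaries(scores))
        assert (table["mssd_mean"] == 0).all()
        assert (table["sd_mean"] == 0).all()

    def test_white_noise_mssd_approaches_twice_variance(self, rng):
        values = rng.normal(3.5, 1.0, size=5000)
        scores = pd.DataFrame(
            {
                "participant_id": "P1",
                "day": 1,
                "alarm_index": np.arange(5000),
                "scale_id": "anxiety",
                "value": values,
            }
        )
        summary = compute_instability_summaries(scores)[0]
        assert summary.mssd == pytest.approx(2 * 1.0, rel=0.1)

    def test_delusion_rows_restricted_to_configured_participants(self):
        summaries = [
            InstabilitySummary("P1", "delusions", 1.0, 0.5, 20),
            InstabilitySummary("P2", "delusions", 9.0, 3.0, 20),
            InstabilitySummary("P1", "anxiety", 1.0, 0.5, 20),
            InstabilitySummary("P2", "anxiety", 2.0, 1.0, 20),
        ]
        table = instability_table(summaries, delusion_participants={"P1"})
        row = table[table["scale_id"] == "delusions"].iloc[0]
        assert row["n_participants"] == 1
        assert row["mssd_mean"] == pytest.approx(1.0)
        assert table[table["scale_id"] == "anxiety"]["n_participants"].iloc[0] == 2


class TestReactivity:
    def make_entry(self, thoughts, mood, alarm=1, status="completed"):
        return SessionEntry(
            "P1", 1, alarm, 1,
            {"reactivity_thoughts": thoughts, "reactivity_mood": mood} if status == "completed" else {},
            status,
        )

    def test_floor_responses(self):
        assert reactivity_mean([self.make_entry(1, 1)]) == pytest.approx(1.0)

    def test_single_entry_mean(self):
        assert reactivity_mean([self.make_entry(3, 4)]) == pytest.approx(3.5)

    def test_across_entries(self):
        entries = [self.make_entry(2, 2, alarm=1), self.make_entry(4, 4, alarm=2)]
        assert reactivity_mean(entries) == pytest.approx(3.0)

    def test_missed_entries_ignored(self):
        entries = [self.make_entry(2, 2), self.make_entry(0, 0, alarm=2, status="missed")]
        assert reactivity_mean(entries) == pytest.approx(2.0)

    def test_no_completed_entries_undefined(self):
        assert reactivity_mean([self.make_entry(0, 0, status="missed")]) is None
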