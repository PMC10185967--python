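"""Association-rule mining: oracle equivalence, identities, ordering."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_rules, random_cohort_frame
from mmnet.cohort import Cohort
from mmnet.panel import DISEASES, StratumSpec
from mmnet.rules import (
    PairCounts,
    format_rules,
    lift_matrix,
    lift_matrix_from_counts,
    mine_rules,
    pair_counts,
    rules_from_counts,
    sort_rules,
    top_rules,
)


def tiny_cohort(patterns: list[tuple[str, ...]]) -> Cohort:
    rows = []
    for i, present in enumerate(patterns):
        row = {d: int(d in present) for d in DISEASES}
        row.update(id=f"p{i}", sex="male", weight=1.0, eq5d_index=0.6, hrqol="poor")
        rows.append(row)
    return Cohort(pd.DataFrame(rows))


class TestPairCounts:
    def test_hand_counted_three_records(self):
        cohort = tiny_cohort(
            [("arthritis", "asthma"), ("arthritis",), ("asthma",)]
        )
        pc = pair_counts(cohort)
        assert pc.n == 3
        assert pc.marginals["arthritis"] == 2
        assert pc.marginals["asthma"] == 2
        assert pc.joint.loc["arthritis", "asthma"] == 1

    def test_disjoint_diseases_zero_joint(self):
        cohort = tiny_cohort([("stroke",)] * 4 + [("cancer",)] * 3)
        pc = pair_counts(cohort)
        assert pc.joint.loc["stroke", "cancer"] == 0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(99)
        cohort = Cohort(random_cohort_frame(rng, 180))
        pc = pair_counts(cohort)
        flags = cohort.disease_matrix()
        oracle = brute_force_rules(flags)
        for i, x in enumerate(DISEASES):
            for j, y in enumerate(DISEASES):
                if i == j:
                    continue
                support, _, _ = oracle[(i, j)]
                assert pc.joint.loc[x, y] == pytest.approx(support * pc.n)

    def test_empty_stratum_errors(self):
        cohort = tiny_cohort([("stroke",)])
        with pytest.raises(ValueError, match="female_good"):
            pair_counts(cohort, StratumSpec("good", "female"))


class TestMineRules:
    @pytest.mark.parametrize("seed,n", [(0, 60), (1, 200), (2, 500)])
    def test_oracle_equivalence_on_random_cohorts(self, seed, n):
        """mine_rules ≡ exhaustive brute-force enumeration, machine precision."""
        rng = np.random.default_rng(seed)
        cohort = Cohort(random_cohort_frame(rng, n))
        rules = mine_rules(cohort)
        oracle = brute_force_rules(cohort.disease_matrix())
        idx = {d: i for i, d in enumerate(DISEASES)}
        assert len(rules) == 15 * 14  # both directions of all 105 pairs
        for r in rules.itertuples(index=False):
            support, conf, lift = oracle[(idx[r.antecedent], idx[r.consequent])]
            assert r.support == support
            assert (np.isnan(conf) and np.isnan(r.confidence)) or r.confidence == conf
            assert (np.isnan(lift) and np.isnan(r.lift)) or r.lift == lift

    def test_statistic_identities(self, demo_cohort):
        """lift·(n_Y/n) = confidence and confidence·(n_X/n) = support, exactly."""
        rules = mine_rules(demo_cohort, StratumSpec("poor", "all"))
        np.testing.assert_allclose(
            rules["lift"] * rules["n_y"] / rules["n"], rules["confidence"], rtol=1e-12
        )
        np.testing.assert_allclose(
            rules["confidence"] * rules["n_x"] / rules["n"], rules["support"], rtol=1e-12
        )

    def test_symmetry_and_bounds(self, demo_cohort):
        rules = mine_rules(demo_cohort)
        grouped = rules.assign(
            pair=[ "|".join(sorted(p)) for p in zip(rules["antecedent"], rules["consequent"])]
        ).groupby("pair")
        for _, g in grouped:
            assert len(g) == 2
            assert g["support"].nunique() == 1
            assert np.allclose(g["lift"].iloc[0], g["lift"].iloc[1], equal_nan=True)
        assert (rules["support"] <= np.minimum(rules["n_x"], rules["n_y"]) / rules["n"] + 1e-15).all()
        ok = rules["lift"].notna()
        assert (rules.loc[ok, "lift"] <= rules.loc[ok, "n"] / np.maximum(rules.loc[ok, "n_x"], rules.loc[ok, "n_y"]) + 1e-12).all()

    def test_subset_case_confidence_one(self):
        cohort = tiny_cohort([("ckd", "hypertension")] * 5 + [("hypertension",)] * 5)
        rules = mine_rules(cohort)
        r = rules[(rules["antecedent"] == "ckd") & (rules["consequent"] == "hypertension")]
        assert r["confidence"].iloc[0] == 1.0

    def test_published_male_poor_diabetes_hypertension_cell(self):
        """Counts n=457, n_HTN=255, n_DM=139, n_joint=95 reproduce the printed
        rule DM→HTN: support 20.8, confidence 68.3, lift 1.2."""
        names = list(DISEASES)
        marg = pd.Series(1, index=names)
        marg["hypertension"], marg["diabetes"] = 255, 139
        joint = pd.DataFrame(0, index=names, columns=names)
        np.fill_diagonal(joint.values, marg)
        joint.loc["diabetes", "hypertension"] = joint.loc["hypertension", "diabetes"] = 95
        pc = PairCounts(n=457, marginals=marg, joint=joint)
        rules = format_rules(rules_from_counts(pc))
        row = rules[(rules["antecedent"] == "diabetes") & (rules["consequent"] == "hypertension")].iloc[0]
        assert (row["support_pct"], row["confidence_pct"], row["lift"]) == (20.8, 68.3, 1.2)

    def test_min_support_bounds_checked(self, demo_cohort):
        with pytest.raises(ValueError):
            mine_rules(demo_cohort, min_support=1.5)


class TestTopRules:
    def test_top_pairs_selected(self, demo_cohort):
        rules = mine_rules(demo_cohort)
        top = top_rules(rules, 4)
        assert len(top) == 4
        assert set(top["support"]) == set(rules["support"].nlargest(4))

    def test_k_larger_than_table_returns_all(self, demo_cohort):
        rules = mine_rules(demo_cohort)
        assert len(top_rules(rules, 10_000)) == len(rules)

    def test_pair_mates_adjacent_and_never_split(self, demo_cohort):
        top = top_rules(mine_rules(demo_cohort), 7)  # odd k: pair kept whole
        assert len(top) == 8
        for i in range(0, len(top), 2):
            a, b = top.iloc[i], top.iloc[i + 1]
            assert {a["antecedent"], a["consequent"]} == {b["antecedent"], b["consequent"]}

    def test_tie_break_deterministic_under_shuffle(self):
        """Equal supports order by (support desc, lift desc, labels asc)."""
        rng = np.random.default_rng(4)
        cohort = Cohort(random_cohort_frame(rng, 40))  # small n → many ties
        rules = mine_rules(cohort)
        shuffled = sort_rules(rules.sample(frac=1.0, random_state=8))
        pd.testing.assert_frame_equal(rules, shuffled)


class TestLiftMatrix:
    def test_independence_fixture_near_one(self):
        rng = np.random.default_rng(12)
        flags = (rng.random((60_000, len(DISEASES))) < 0.3).astype(int)
        df = pd.DataFrame(flags, columns=list(DISEASES))
        df["id"], df["sex"], df["weight"] = "x", "male", 1.0
        df["eq5d_index"], df["hrqol"] = 0.9, "normal"
        m = lift_matrix(Cohort(df))
        off = m.values[~np.eye(len(DISEASES), dtype=bool)]
        assert np.nanmax(np.abs(off - 1.0)) < 0.06

    def test_equals_elementwise_recomputation(self, demo_cohort):
        pc = pair_counts(demo_cohort, StratumSpec("poor", "all"))
        m = lift_matrix_from_counts(pc)
        for x in DISEASES[:5]:
            for y in DISEASES[5:10]:
                expected = pc.joint.loc[x, y] * pc.n / (pc.marginals[x] * pc.marginals[y])
                assert m.loc[x, y] == pytest.approx(expected)
        assert np.isnan(np.diag(m.values)).all()

    def test_zero_marginal_masked_not_zero(self):
        cohort = tiny_cohort([("stroke",), ("stroke", "cancer")])
        m = lift_matrix(cohort)
        assert np.isnan(m.loc["stroke", "thyroid"])
        assert m.loc["stroke", "cancer"] == pytest.approx(1.0)
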