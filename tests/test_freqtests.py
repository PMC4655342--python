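"""Mid-P Fisher tests and the reaction-time ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact, kstest

from riskshift import (
    AgentParams,
    ContingencyTable2x2,
    PsychometricParams,
    SessionDesign,
    TrialRecord,
    fisher_midp,
    generate_session,
    per_level_tests,
    rt_anova,
)
from _oracles import midp_fraction_oracle, type2_anova_oracle


class TestFisherMidP:
    def test_zero_margin_is_degenerate_half(self):
        res = fisher_midp(ContingencyTable2x2(0, 0, 5, 7))
        assert res.pvalue == 0.5
        assert res.degenerate

    def test_known_table_matches_enumeration_oracle(self):
        res = fisher_midp(ContingencyTable2x2(8, 2, 2, 8))
        assert res.pvalue == pytest.approx(
            float(midp_fraction_oracle(8, 2, 2, 8)), abs=1e-12
        )

    def test_hand_built_session_level(self):
        """Counts off 10/54 vs on 30/34 risky/safe at one level."""
        res = fisher_midp(ContingencyTable2x2(10, 54, 30, 34))
        assert res.pvalue == pytest.approx(
            float(midp_fraction_oracle(10, 54, 30, 34)), abs=1e-12
        )
        assert res.pvalue < 0.001

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        a=st.integers(0, 15), b=st.integers(0, 15),
        c=st.integers(0, 15), d=st.integers(0, 15),
    )
    def test_symmetries_and_range(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        base = fisher_midp(ContingencyTable2x2(a, b, c, d))
        assert 0.0 <= base.pvalue <= 1.0
        transposed = fisher_midp(ContingencyTable2x2(a, c, b, d))
        swapped = fisher_midp(ContingencyTable2x2(d, c, b, a))
        assert transposed.pvalue == pytest.approx(base.pvalue, abs=1e-12)
        assert swapped.pvalue == pytest.approx(base.pvalue, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)

    def test_midp_below_conventional_fisher(self):
        """Spot check mid-P <= conventional two-sided exact p (the exhaustive
        sweep over all small tables runs in the acceptance suite)."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 12, size=4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            midp = fisher_midp(ContingencyTable2x2(a, b, c, d)).pvalue
            _, p_conv = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            assert midp <= p_conv + 1e-12

    def test_null_calibration_approximately_uniform(self):
        """Under no effect the mid-P is close to uniform on [0, 1]."""
        rng = np.random.default_rng(12)
        n_off, n_on, n_reps = 126, 63, 1000
        pvals = np.empty(n_reps)
        for i in range(n_reps):
            k_off = rng.binomial(n_off, 0.5)
            k_on = rng.binomial(n_on, 0.5)
            pvals[i] = fisher_midp(
                ContingencyTable2x2(k_off, n_off - k_off, k_on, n_on - k_on)
            ).pvalue
        ks = kstest(pvals, "uniform").statistic
        assert ks < 0.1
        assert 0.03 <= np.mean(pvals < 0.05) <= 0.07


class TestPerLevelTests:
    def test_duplicated_conditions_show_no_effect(self, default_design):
        params = PsychometricParams(0.5, 0.1, 0.05, 0.95)
        agent = AgentParams(params_off=params, params_on=params)
        records = generate_session(default_design, agent, seed=13)
        table = per_level_tests(records)
        assert len(table) == 5
        assert table["testable"].all()
        # no systematic significance under the null
        assert (table["midp"] > 0.001).all()

    def test_strong_shift_reaches_a_tier(self):
        """A large shift at one level is detected in >= 80% of seeded runs."""
        design = SessionDesign()
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            rng = np.random.default_rng(1000 + seed)
            records = []
            for cond, p_risky in (("off", 0.25), ("on", 0.6)):
                block = 1 if cond == "off" else 3
                for i in range(64):
                    risky = rng.random() < p_risky
                    records.append(
                        TrialRecord(block, i + 1, cond, 0.3,
                                    "risky" if risky else "safe",
                                    50 if risky else 10, 500.0)
                    )
                # second level so the table has >= 2 levels
                for i in range(4):
                    records.append(TrialRecord(block, 100 + i, cond, 0.7, "safe", 10, 500.0))
            table = per_level_tests(records)
            if table.loc[0.3, "tier"]:
                hits += 1
        assert hits >= int(0.8 * n_runs)

    def test_level_absent_in_one_condition_flagged(self):
        records = [
            TrialRecord(1, 1, "off", 0.3, "risky", 50, 400.0),
            TrialRecord(1, 2, "off", 0.3, "safe", 10, 400.0),
            TrialRecord(3, 1, "on", 0.7, "risky", 0, 400.0),
            TrialRecord(3, 2, "on", 0.3, "safe", 10, 400.0),
        ]
        table = per_level_tests(records)
        assert not table.loc[0.7, "testable"]
        assert np.isnan(table.loc[0.7, "midp"])
        assert table.loc[0.3, "testable"]

    def test_single_condition_rejected(self):
        records = [TrialRecord(1, 1, "off", 0.3, "safe", 10, 400.0)]
        with pytest.raises(ValueError, match="both conditions"):
            per_level_tests(records)


def balanced_rt_records(effect_ms=30.0, noise_sd=50.0, n_per_cell=48, seed=0):
    """Fully crossed condition x choice x level records with additive RT structure."""
    rng = np.random.default_rng(seed)
    records = []
    trial = {}
    for cond in ("off", "on"):
        for choice in ("risky", "safe"):
            for level in (0.1, 0.3, 0.5, 0.7, 0.9):
                for _ in range(n_per_cell):
                    block = 1 if cond == "off" else 3
                    t = trial.get(block, 0) + 1
                    trial[block] = t
                    rt = 600.0 + (effect_ms if cond == "on" else 0.0)
                    rt += noise_sd * rng.standard_normal()
                    outcome = 10 if choice == "safe" else 50
                    records.append(
                        TrialRecord(block, t, cond, level, choice, outcome, float(rt))
                    )
    return records


class TestRtAnova:
    def test_matches_normal_equations_oracle(self):
        records = balanced_rt_records()
        table = rt_anova(records)
        df = pd.DataFrame(
            {
                "condition": [r.condition for r in records],
                "choice": [r.choice for r in records],
                "cue_prob": [r.cue_probability for r in records],
                "rt_ms": [r.rt_ms for r in records],
            }
        )
        oracle = type2_anova_oracle(df)
        label_map = {
            "stimulation": ("condition",),
            "choice": ("choice",),
            "probability": ("cue_prob",),
            "stimulation:choice": ("condition", "choice"),
            "stimulation:probability": ("condition", "cue_prob"),
            "choice:probability": ("choice", "cue_prob"),
            "stimulation:choice:probability": ("condition", "choice", "cue_prob"),
        }
        for label, term in label_map.items():
            assert table.loc[label, "sum_sq"] == pytest.approx(
                oracle[term]["sum_sq"], rel=1e-8, abs=1e-6
            )
            assert table.loc[label, "F"] == pytest.approx(oracle[term]["F"], rel=1e-8)
        assert table.loc["stimulation", "PR(>F)"] < 0.01

    def test_balanced_ss_decomposition(self):
        records = balanced_rt_records(seed=3)
        table = rt_anova(records)
        rts = np.array([r.rt_ms for r in records])
        total_ss = float(((rts - rts.mean()) ** 2).sum())
        assert table["sum_sq"].sum() == pytest.approx(total_ss, rel=1e-8)

    def test_condition_relabel_invariance(self):
        records = balanced_rt_records(seed=5)
        flipped = [
            TrialRecord(r.block, r.trial_in_block,
                        "on" if r.condition == "off" else "off",
                        r.cue_probability, r.choice, r.outcome_points, r.rt_ms)
            for r in records
        ]
        a = rt_anova(records)
        b = rt_anova(flipped)
        assert np.allclose(a["F"].iloc[:-1], b["F"].iloc[:-1], rtol=1e-10)

    def test_constant_rt_degenerates_cleanly(self):
        records = balanced_rt_records(effect_ms=0.0, noise_sd=0.0, n_per_cell=4)
        table = rt_anova(records)
        effects = table.drop(index="Residual")
        assert (effects["sum_sq"] == 0.0).all()
        assert (effects["PR(>F)"] == 1.0).all()

    def test_missing_factor_level_rejected(self):
        records = [r for r in balanced_rt_records(n_per_cell=2) if r.choice == "risky"]
        with pytest.raises(ValueError, match="choice"):
            rt_anova(records)

    def test_omissions_excluded(self, default_session):
        table = rt_anova(default_session)
        n_resp = sum(1 for r in default_session if r.choice != "omit")
        assert table["df"].sum() == n_resp - 1
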