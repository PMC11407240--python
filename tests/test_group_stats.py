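import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as ss

from fnirsevents.group_stats import (correlate_brain_behaviour, fdr_bh,
                                     ks_normality, paired_t, paired_tests)
from fnirsevents.summary_metrics import PARAMETERS


class TestKSNormality:
    def test_normal_samples_usually_flagged_normal(self):
        hits = 0
        for seed in range(100):
            v = np.random.default_rng(seed).normal(size=500)
            *_, normal = ks_normality(v)
            hits += normal
        assert hits >= 95

    def test_statistic_matches_ecdf_oracle(self):
        v = np.random.default_rng(1).uniform(size=500) * 7 - 3
        stat, _p, _ = ks_normality(v)
        x = np.sort(v)
        cdf = ss.norm.cdf(x, v.mean(), v.std(ddof=1))
        n = len(v)
        d_plus = (np.arange(1, n + 1) / n - cdf).max()
        d_minus = (cdf - np.arange(0, n) / n).max()
        assert stat == pytest.approx(max(d_plus, d_minus), abs=1e-10)

    def test_constant_sample_degenerate(self):
        stat, p, normal = ks_normality(np.full(10, 3.0))
        assert not normal and np.isnan(stat)


class TestPairedT:
    def test_closed_form_fixture(self):
        # d = f - u = [-1, -2, 0, -2]: mean -1.25, sd 0.9574
        f = np.array([1.0, 2, 3, 4])
        u = np.array([2.0, 4, 3, 6])
        t, df, p = paired_t(f, u)
        d = f - u
        expected = d.mean() / (d.std(ddof=1) / 2)
        assert t == pytest.approx(expected, abs=1e-12)
        assert t == pytest.approx(-2.6112, abs=1e-3)
        assert df == 3
        t_sp, p_sp = ss.ttest_rel(f, u)
        assert t == pytest.approx(t_sp, abs=1e-10)
        assert p == pytest.approx(p_sp, abs=1e-10)

    def test_identical_samples_degenerate(self):
        t, df, p = paired_t(np.arange(4.0), np.arange(4.0))
        assert np.isnan(t) and df == 3

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 500))
    def test_antisymmetry(self, seed):
        gen = np.random.default_rng(seed)
        f = gen.normal(size=8)
        u = gen.normal(size=8)
        t_fu, _, p_fu = paired_t(f, u)
        t_uf, _, p_uf = paired_t(u, f)
        assert t_fu == pytest.approx(-t_uf, rel=1e-12)
        assert p_fu == pytest.approx(p_uf, rel=1e-12)


class TestFDR:
    def test_step_up_hand_example(self):
        flags = fdr_bh([0.001, 0.2, 0.3], q=0.05)
        assert flags.tolist() == [True, False, False]

    def test_all_zero_p_all_flagged(self):
        assert fdr_bh([0.0, 0.0, 0.0]).all()

    def test_single_p_threshold(self):
        assert fdr_bh([0.04]).tolist() == [True]
        assert fdr_bh([0.06]).tolist() == [False]

    def test_flags_monotone_in_p(self, rng):
        p = rng.uniform(size=40)
        flags = fdr_bh(p, q=0.2)
        if flags.any():
            assert p[flags].max() <= p[~flags].min() or not (~flags).any()


def _param_table(n_participants=8, effect_channel=1, delta=2.0, seed=0):
    """Synthetic ParamTable with a planted Fragranced>Unfragranced shift
    of ``delta`` on mean_t in one channel of the dynamic wash cell."""
    gen = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        pid = f"P{i+1:02d}"
        for channel in range(3):
            for cond in ("fragranced", "unfragranced"):
                base = gen.normal(4.0, 1.0)
                if channel == effect_channel and cond == "fragranced":
                    base += delta
                rows.append({
                    "participant": pid, "channel": channel,
                    "phase": "dynamic", "task": "wash", "condition": cond,
                    "cell_duration_s": 300.0,
                    "n_events": int(gen.integers(1, 5)),
                    "mean_dur": float(gen.uniform(10, 50)),
                    "mean_t": float(base),
                    "max_t": float(base + gen.uniform(0, 2)),
                })
    df = pd.DataFrame(rows)
    for p in PARAMETERS:
        df[f"{p}_norm"] = df[p] / df.cell_duration_s
    return df


class TestPairedTests:
    def test_planted_effect_detected_in_right_channel(self):
        table = _param_table(delta=3.0)
        res = paired_tests(table)
        wash_meant = res[(res.parameter == "mean_t")
                         & (res.task == "wash")]
        assert len(wash_meant) == 3
        hit = wash_meant[wash_meant.channel == 1].iloc[0]
        assert hit.t > 0 and hit.significant_unc
        assert hit.n_pairs == 8 and hit.df == 7

    def test_fdr_family_is_channels_within_parameter(self):
        res = paired_tests(_param_table(delta=0.0, seed=5))
        fam = res[(res.parameter == "max_t") & (res.task == "wash")]
        # uncorrected and corrected flags are both present and consistent
        assert (~fam.significant_fdr | fam.significant_unc).all()

    def test_missing_condition_rows_reduce_pairs(self):
        table = _param_table()
        table = table[~((table.participant == "P01")
                        & (table.condition == "unfragranced"))]
        res = paired_tests(table)
        assert (res.n_pairs == 7).all()


class TestCorrelations:
    def _scores(self, values, attr="intensity"):
        rows = []
        for i, v in enumerate(values):
            row = {"participant": f"P{i+1:02d}", "condition": "fragranced",
                   "form": "liquid", "liking": 5, "intensity": 5,
                   "invigorating": 5, "relaxing": 5, "just_about_right": 3}
            row[attr] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def test_perfect_linear_pairing(self):
        table = _param_table(n_participants=6)
        table = table[table.condition == "fragranced"]
        # make mean_t in channel 0 exactly the participant index
        vals = {f"P{i+1:02d}": float(i) for i in range(6)}
        table.loc[table.channel == 0, "mean_t"] = \
            table.loc[table.channel == 0, "participant"].map(vals)
        scores = self._scores([1 + 0.5 * i for i in range(6)])
        res = correlate_brain_behaviour(table, scores,
                                        pool_conditions=True)
        hit = res[(res.channel == 0) & (res.parameter == "mean_t")
                  & (res.attribute == "intensity") & (res.task == "wash")]
        assert hit.iloc[0].r == pytest.approx(1.0, abs=1e-9)

    def test_matches_covariance_oracle(self):
        gen = np.random.default_rng(42)
        x = gen.normal(size=12)
        y = 0.6 * x + 0.8 * gen.normal(size=12)
        table = _param_table(n_participants=12)
        table = table[table.condition == "fragranced"]
        table.loc[table.channel == 0, "mean_t"] = np.repeat(x, 1)[
            table.loc[table.channel == 0].reset_index().index]
        # simpler: assign by participant order
        sub = table[table.channel == 0].copy()
        for i, pid in enumerate(sorted(sub.participant.unique())):
            table.loc[(table.channel == 0)
                      & (table.participant == pid), "mean_t"] = x[i]
        scores = self._scores(np.clip(np.round(5 + y), 1, 9))
        res = correlate_brain_behaviour(table, scores)
        hit = res[(res.channel == 0) & (res.parameter == "mean_t")
                  & (res.attribute == "intensity") & (res.task == "wash")]
        xs = x
        ys = np.clip(np.round(5 + y), 1, 9)
        oracle = (np.mean(xs * ys) - xs.mean() * ys.mean()) / \
            (xs.std() * ys.std())
        assert hit.iloc[0].r == pytest.approx(oracle, abs=1e-12)

    def test_anti_linear_pairing(self):
        table = _param_table(n_participants=5)
        table = table[table.condition == "fragranced"]
        for i, pid in enumerate(sorted(table.participant.unique())):
            table.loc[(table.channel == 0)
                      & (table.participant == pid), "max_t"] = float(i)
        scores = self._scores([9 - i for i in range(5)])
        res = correlate_brain_behaviour(table, scores)
        hit = res[(res.channel == 0) & (res.parameter == "max_t")
                  & (res.attribute == "intensity") & (res.task == "wash")]
        assert hit.iloc[0].r == pytest.approx(-1.0, abs=1e-9)

    def test_stage_form_pairing_restricted(self):
        res = correlate_brain_behaviour(_param_table(),
                                        self._scores(list(range(1, 9))))
        assert len(res)
        assert set(zip(res.task, res.form)) <= {("wash", "liquid")}
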