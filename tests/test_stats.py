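"""Group statistics: split-plot ANOVA, planned comparisons, two-sample tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from froa.stats import (
    independent_ttest,
    mann_whitney,
    mixed_anova,
    paired_ttest,
    planned_comparisons,
    two_sample_tests,
)


def make_table(values):
    """values[g][s][m] -> long table with groups g, subjects s, models m."""
    rows = []
    for g, subjects in values.items():
        for s, models in enumerate(subjects):
            for m, v in enumerate(models):
                rows.append((f"{g}{s}", g, f"m{m}", v))
    return pd.DataFrame(rows, columns=["participant", "group", "model", "mmc"])


def brute_force_split_plot(df):
    """Independent sums-of-squares oracle via explicit cell-mean loops."""
    groups = sorted(df["group"].unique())
    models = sorted(df["model"].unique())
    subjects = {g: sorted(df[df["group"] == g]["participant"].unique()) for g in groups}
    a, b, n = len(groups), len(models), len(subjects[groups[0]])

    def mean(sel):
        return sel["mmc"].mean()

    grand = mean(df)
    ss = dict.fromkeys(["group", "subj", "model", "inter", "err"], 0.0)
    for g in groups:
        ss["group"] += n * b * (mean(df[df["group"] == g]) - grand) ** 2
        for s in subjects[g]:
            ss["subj"] += b * (mean(df[df["participant"] == s]) - mean(df[df["group"] == g])) ** 2
    for m in models:
        ss["model"] += a * n * (mean(df[df["model"] == m]) - grand) ** 2
    for g in groups:
        for m in models:
            cell = mean(df[(df["group"] == g) & (df["model"] == m)])
            ss["inter"] += n * (cell - mean(df[df["group"] == g]) - mean(df[df["model"] == m]) + grand) ** 2
    for g in groups:
        for s in subjects[g]:
            for m in models:
                y = mean(df[(df["participant"] == s) & (df["model"] == m)])
                dev = (
                    y
                    - mean(df[df["participant"] == s])
                    - mean(df[(df["group"] == g) & (df["model"] == m)])
                    + mean(df[df["group"] == g])
                )
                ss["err"] += dev**2
    return ss


@pytest.fixture(scope="module")
def fixed_2x3x4():
    rng = np.random.default_rng(77)
    return make_table(
        {
            "basic": rng.normal([0, 2, 4], 1.0, size=(4, 3)).tolist(),
            "subordinate": rng.normal([1, 2, 5], 1.0, size=(4, 3)).tolist(),
        }
    )


class TestMixedAnova:
    def test_matches_brute_force_oracle(self, fixed_2x3x4):
        tab = mixed_anova(fixed_2x3x4).set_index("effect")
        oracle = brute_force_split_plot(fixed_2x3x4)
        pairs = [
            ("group", "group"), ("subjects(group)", "subj"), ("model", "model"),
            ("group x model", "inter"), ("model x subjects(group)", "err"),
        ]
        for effect, key in pairs:
            assert tab.loc[effect, "SS"] == pytest.approx(oracle[key], rel=1e-8)
        f_model = (oracle["model"] / 2) / (oracle["err"] / 12)
        assert tab.loc["model", "F"] == pytest.approx(f_model, rel=1e-8)

    def test_matches_pingouin(self, fixed_2x3x4):
        pg = pytest.importorskip("pingouin")
        ours = mixed_anova(fixed_2x3x4).set_index("effect")
        theirs = pg.mixed_anova(
            fixed_2x3x4, dv="mmc", within="model", between="group", subject="participant"
        ).set_index("Source")
        for mine, other in [("group", "group"), ("model", "model"), ("group x model", "Interaction")]:
            assert ours.loc[mine, "F"] == pytest.approx(theirs.loc[other, "F"], rel=1e-9)
            assert ours.loc[mine, "pes"] == pytest.approx(theirs.loc[other, "np2"], rel=1e-9)

    def test_total_ss_decomposition(self, fixed_2x3x4):
        tab = mixed_anova(fixed_2x3x4)
        total = ((fixed_2x3x4["mmc"] - fixed_2x3x4["mmc"].mean()) ** 2).sum()
        assert tab["SS"].sum() == pytest.approx(total, rel=1e-8)

    def test_zero_variance_reported_as_null_result(self):
        df = make_table({"a": [[1.0, 1.0, 1.0]] * 3, "b": [[1.0, 1.0, 1.0]] * 3})
        tab = mixed_anova(df).set_index("effect")
        for effect in ("group", "model", "group x model"):
            assert tab.loc[effect, "F"] == 0.0
            assert tab.loc[effect, "p"] == 1.0

    def test_pure_group_shift_loads_on_task_only(self):
        rng = np.random.default_rng(3)
        subj = rng.normal(0, 1, size=4)
        base = np.repeat(subj[:, None], 3, axis=1)  # no model effect at all
        df = make_table({"a": base.tolist(), "b": (base + 5).tolist()})
        tab = mixed_anova(df).set_index("effect")
        assert tab.loc["group", "F"] > 0
        assert tab.loc["model", "F"] == pytest.approx(0.0, abs=1e-9)
        assert tab.loc["group x model", "F"] == pytest.approx(0.0, abs=1e-9)

    def test_invariance_to_relabeling_and_shift(self, fixed_2x3x4):
        base = mixed_anova(fixed_2x3x4)
        shifted = fixed_2x3x4.copy()
        shifted["mmc"] += 123.0
        shifted["participant"] = shifted["participant"].map(lambda s: "zz" + s[::-1])
        out = mixed_anova(shifted)
        assert np.allclose(base["F"].fillna(-1), out["F"].fillna(-1), rtol=1e-9)

    def test_unbalanced_or_incomplete_rejected(self, fixed_2x3x4):
        with pytest.raises(ValueError, match="complete"):
            mixed_anova(fixed_2x3x4.iloc[1:])
        extra = make_table({"a": [[1, 2, 3]] * 3, "b": [[1, 2, 3]] * 4})
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_anova(extra)


class TestPairwiseTests:
    def test_identical_paired_vectors(self):
        r = paired_ttest(np.arange(5.0), np.arange(5.0))
        assert (r.statistic, r.p) == (0.0, 1.0)

    def test_constant_difference_is_degenerate(self):
        r = paired_ttest(np.arange(5.0) + 2.0, np.arange(5.0))
        assert math.isinf(r.statistic) and r.statistic > 0
        assert r.p == 0.0
        assert "zero-variance" in r.note

    def test_paired_t_matches_hand_formula(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(1.0, 2.0, 12), rng.normal(0.0, 2.0, 12)
        d = x - y
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        r = paired_ttest(x, y)
        assert r.statistic == pytest.approx(expected, rel=1e-10)
        assert r.p == pytest.approx(2 * sps.t.sf(abs(expected), 11), rel=1e-10)

    def test_independent_t_matches_pooled_formula(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0, 1, 10), rng.normal(0.7, 1, 12)
        sp2 = ((9 * x.var(ddof=1)) + (11 * y.var(ddof=1))) / 20
        expected = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 10 + 1 / 12))
        r = independent_ttest(x, y)
        assert r.statistic == pytest.approx(expected, rel=1e-10)
        assert r.df == 20

    def test_identical_groups_give_t_zero(self):
        x = np.arange(6.0)
        r = independent_ttest(x, x.copy())
        assert (r.statistic, r.p) == (0.0, 1.0)

    def test_planned_comparisons_cover_all_contrasts(self, fixed_2x3x4):
        out = planned_comparisons(fixed_2x3x4)
        # 3 within-task pairs per group + 3 between-task contrasts
        assert len(out) == 2 * 3 + 3
        assert all(0 <= c.p <= 1 for c in out)


class TestMannWhitney:
    def test_separated_groups_exact_tail(self):
        r = mann_whitney(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]), alternative="less")
        assert r.statistic == 0.0
        assert r.p == pytest.approx(1 / 20)

    def test_exact_p_matches_full_enumeration(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 6), rng.normal(0.8, 1, 7)
        r = mann_whitney(x, y)
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        u_obs = ranks[:6].sum() - 6 * 7 / 2
        mu = 6 * 7 / 2
        count = total = 0
        for idx in itertools.combinations(range(13), 6):
            u = ranks[list(idx)].sum() - 6 * 7 / 2
            total += 1
            count += abs(u - mu) >= abs(u_obs - mu) - 1e-12
        assert r.p == pytest.approx(count / total, abs=1e-12)

    def test_tied_data_uses_enumeration(self):
        x = np.array([1.0, 1, 2, 3])
        y = np.array([2.0, 3, 3, 4])
        r = mann_whitney(x, y)
        assert r.note == "exact enumeration with ties"
        res = sps.permutation_test(
            (x, y),
            lambda a, b, axis=-1: sps.mannwhitneyu(a, b, axis=axis).statistic,
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=np.inf,
        )
        assert r.p == pytest.approx(res.pvalue, abs=1e-12)

    def test_two_sample_driver_mixes_test_kinds(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            {
                "group": ["a"] * 6 + ["b"] * 6,
                "mean_amplitude_deg": np.r_[rng.normal(2.3, 0.2, 6), rng.normal(3.6, 0.2, 6)],
                "mean_dwell_ms": rng.normal(198, 20, 12),
                "accuracy": np.r_[rng.choice([0.94, 0.95, 0.96], 6), rng.choice([0.95, 0.96], 6)],
            }
        )
        out = two_sample_tests(
            df, metric_cols=("mean_amplitude_deg", "mean_dwell_ms", "accuracy"),
            nonparametric=("accuracy",),
        )
        kinds = {c.label.split(":")[0]: c.kind for c in out}
        assert kinds["mean_amplitude_deg"] == "t"
        assert kinds["accuracy"] == "U"
        amp = next(c for c in out if c.label.startswith("mean_amplitude"))
        assert amp.p < 0.05 and amp.statistic < 0
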