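"""Stay tables, arcsine transform and the mixed-design ANOVA.

The ANOVA is verified against three independent references: an explicit
sums-of-squares decomposition written from the textbook formulas, a
subject-label permutation test for the between-group effect, and
pingouin's mixed ANOVA for the one-within/one-between design.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from twostep import (
    MixedAnova,
    arcsine_transform,
    classify_signature,
    compute_stay_table,
    cumulative_outcome,
    stay_long_table,
)
from conftest import make_dataset


class TestStayTable:
    def test_always_repeat_agent_has_all_ones(self):
        n = 40
        rng = np.random.default_rng(0)
        ds = make_dataset(choice1=np.zeros(n, dtype=int),
                          transition=rng.integers(2, size=n),
                          outcome=rng.integers(2, size=n).astype(float))
        tab = compute_stay_table(ds)
        assert np.all(tab.p_stay[tab.n_pairs > 0] == 1.0)

    def test_hand_counted_cells(self, hand_dataset):
        tab = compute_stay_table(hand_dataset)
        # rows: (better, worse); cols: (common, rare)
        assert tab.n_pairs.tolist() == [[1, 1], [1, 1]]
        assert tab.p_stay.tolist() == [[1.0, 0.0], [1.0, 0.0]]

    def test_punishment_outcome_categories(self):
        # no-loss counts as the better outcome under punishment
        ds = make_dataset(choice1=[0, 0, 1], transition=[0, 0, 0],
                          outcome=[0.0, -1.0, -1.0], valence="punishment")
        tab = compute_stay_table(ds)
        assert tab.n_pairs[0, 0] == 1  # t0 no-loss/common -> stay
        assert tab.p_stay[0, 0] == 1.0
        assert tab.n_pairs[1, 0] == 1  # t1 loss/common -> shift
        assert tab.p_stay[1, 0] == 0.0

    def test_pairs_spanning_omissions_are_skipped(self):
        ds = make_dataset(choice1=[0, 0, 0, 0, 0], transition=[0] * 5,
                          outcome=[1, 1, 1, 1, 1],
                          omitted=[False, False, True, False, False])
        tab = compute_stay_table(ds)
        assert tab.n_pairs.sum() == 2  # (0,1) and (3,4) only

    def test_too_few_usable_trials_rejected(self):
        ds = make_dataset(choice1=[0, 0], transition=[0, 0], outcome=[1, 1],
                          omitted=[False, True])
        with pytest.raises(ValueError):
            compute_stay_table(ds)

    def test_incomplete_subjects_excluded_listwise(self):
        good = make_dataset(choice1=[0, 1] * 10,
                            transition=[0, 1, 0, 1] * 5,
                            outcome=[1, 1, 0, 0] * 5, subject_id="good")
        bad = make_dataset(choice1=[0] * 6, transition=[0] * 6,
                           outcome=[1] * 6, subject_id="bad")  # empty cells
        long = stay_long_table([good, bad])
        assert set(long["subject_id"]) == {"good"}


class TestArcsine:
    @pytest.mark.parametrize("p,expected", [
        (0.0, 0.0), (1.0, np.pi / 2), (0.5, np.pi / 4),
    ])
    def test_closed_forms(self, p, expected):
        assert arcsine_transform(p) == pytest.approx(expected)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=100, derandomize=True)
    def test_strictly_increasing(self, a, b):
        lo, hi = sorted((a, b))
        if lo < hi:
            assert arcsine_transform(lo) < arcsine_transform(hi)

    @pytest.mark.parametrize("p", [-0.01, 1.01])
    def test_domain_enforced(self, p):
        with pytest.raises(ValueError):
            arcsine_transform(p)


class TestCumulativeOutcome:
    def test_hand_sums(self, hand_dataset):
        assert cumulative_outcome(hand_dataset) == 3.0
        zeros = make_dataset(choice1=[0, 1], transition=[0, 0], outcome=[0, 0])
        assert cumulative_outcome(zeros) == 0.0

    def test_omitted_trials_excluded(self):
        ds = make_dataset(choice1=[0, 0, 0], transition=[0, 0, 0],
                          outcome=[1, 1, 1], omitted=[False, True, False])
        assert cumulative_outcome(ds) == 2.0


# ---------------------------------------------------------------------
# Independent sums-of-squares oracle for the 2-group x 2x2-within design


def anova_ss_oracle(y: np.ndarray, group_of: np.ndarray) -> dict[str, float]:
    """Textbook SS decomposition for a balanced mixed design.

    ``y`` has shape (subjects, 2, 2) = (subject, W1 level, W2 level);
    ``group_of`` assigns each subject to group 0 or 1 (equal sizes).
    Returns F statistics computed purely from cell means.
    """
    n_subj = y.shape[0]
    groups = np.unique(group_of)
    a = len(groups)
    n = n_subj // a
    M = y.mean()
    subj_mean = y.mean(axis=(1, 2))
    grp_mean = np.array([y[group_of == g].mean() for g in groups])
    ss_bs = 4 * ((subj_mean - M) ** 2).sum()
    ss_G = n * 4 * ((grp_mean - M) ** 2).sum()
    ss_SG = ss_bs - ss_G
    df_sg = a * (n - 1)
    out = {"group": (ss_G / (a - 1)) / (ss_SG / df_sg)}

    # W1 stratum
    p_mean = y.mean(axis=(0, 2))                       # (2,)
    gp_mean = np.stack([y[group_of == g].mean(axis=(0, 2)) for g in groups])
    sp_mean = y.mean(axis=2)                           # (subj, 2)
    ss_W1 = a * n * 2 * ((p_mean - M) ** 2).sum()
    ss_W1G = n * 2 * ((gp_mean - grp_mean[:, None] - p_mean[None, :] + M) ** 2).sum()
    resid = sp_mean - subj_mean[:, None] \
        - (gp_mean[group_of] - grp_mean[group_of, None])
    ss_W1SG = 2 * (resid ** 2).sum()
    out["W1"] = ss_W1 / (ss_W1SG / df_sg)
    out["W1:group"] = (ss_W1G / (a - 1)) / (ss_W1SG / df_sg)

    # W2 stratum (same formulas on the other axis)
    q_mean = y.mean(axis=(0, 1))
    gq_mean = np.stack([y[group_of == g].mean(axis=(0, 1)) for g in groups])
    sq_mean = y.mean(axis=1)
    ss_W2 = a * n * 2 * ((q_mean - M) ** 2).sum()
    ss_W2G = n * 2 * ((gq_mean - grp_mean[:, None] - q_mean[None, :] + M) ** 2).sum()
    resid = sq_mean - subj_mean[:, None] \
        - (gq_mean[group_of] - grp_mean[group_of, None])
    ss_W2SG = 2 * (resid ** 2).sum()
    out["W2"] = ss_W2 / (ss_W2SG / df_sg)
    out["W2:group"] = (ss_W2G / (a - 1)) / (ss_W2SG / df_sg)

    # W1 x W2 stratum
    pq_mean = y.mean(axis=0)                            # (2, 2)
    gpq_mean = np.stack([y[group_of == g].mean(axis=0) for g in groups])
    ss_I = a * n * ((pq_mean - p_mean[:, None] - q_mean[None, :] + M) ** 2).sum()
    ss_IG = n * ((gpq_mean
                  - gp_mean[:, :, None] - gq_mean[:, None, :] - pq_mean[None]
                  + grp_mean[:, None, None] + p_mean[None, :, None]
                  + q_mean[None, None, :] - M) ** 2).sum()
    cell_int = (y - sp_mean[:, :, None] - sq_mean[:, None, :] + subj_mean[:, None, None])
    grp_int = (gpq_mean - gp_mean[:, :, None] - gq_mean[:, None, :]
               + grp_mean[:, None, None])
    ss_ISG = ((cell_int - grp_int[group_of]) ** 2).sum()
    out["W1:W2"] = ss_I / (ss_ISG / df_sg)
    out["W1:W2:group"] = (ss_IG / (a - 1)) / (ss_ISG / df_sg)
    return out


def _long_from_cube(y, group_of):
    rows = []
    for s in range(y.shape[0]):
        for i, j in itertools.product(range(2), range(2)):
            rows.append({"subject": f"s{s}", "grp": f"g{group_of[s]}",
                         "W1": f"l{i}", "W2": f"l{j}", "dv": y[s, i, j]})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_matches_sums_of_squares_oracle(self):
        """Six hand-seeded subjects, 2 groups x 2x2 within: every F equals
        the independent cell-mean decomposition."""
        rng = np.random.default_rng(8)
        y = rng.normal(size=(6, 2, 2)) + np.array([[0.5, 0.0], [0.2, 0.6]])
        group_of = np.array([0, 0, 0, 1, 1, 1])
        y[group_of == 1] += np.array([[0.4, 0.0], [0.0, 0.0]])
        res = MixedAnova(_long_from_cube(y, group_of), dv="dv",
                         within=["W1", "W2"], subject="subject", between="grp").fit()
        oracle = anova_ss_oracle(y, group_of)
        for effect, F in oracle.items():
            mine = res.f(effect.replace("group", "grp"))
            assert mine == pytest.approx(F, abs=1e-10), effect

    def test_group_p_matches_permutation_reference(self):
        """The parametric p for the between effect agrees with a
        subject-label permutation test within Monte-Carlo error."""
        rng = np.random.default_rng(21)
        n = 10
        y = rng.normal(size=(2 * n, 2, 2))
        group_of = np.repeat([0, 1], n)
        y[group_of == 1] += 0.35  # moderate group shift
        res = MixedAnova(_long_from_cube(y, group_of), dv="dv",
                         within=["W1", "W2"], subject="subject", between="grp").fit()
        p_param = res.p("grp")
        # permutation reference: one-way F on subject means, labels shuffled
        subj_means = y.mean(axis=(1, 2))
        f_obs = stats.f_oneway(subj_means[group_of == 0], subj_means[group_of == 1])[0]
        count = 0
        n_perm = 10_000
        labels = group_of.copy()
        for _ in range(n_perm):
            rng.shuffle(labels)
            f = stats.f_oneway(subj_means[labels == 0], subj_means[labels == 1])[0]
            count += f >= f_obs
        p_perm = (count + 1) / (n_perm + 1)
        assert 0.01 < p_param < 0.9  # informative regime
        assert abs(p_param - p_perm) < 0.04

    def test_matches_pingouin_one_within_one_between(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        rows = []
        for g in ("A", "B"):
            for s in range(9):
                base = rng.normal()
                for w in ("w0", "w1"):
                    rows.append({"subject": f"{g}{s}", "grp": g, "w": w,
                                 "dv": base + 0.4 * (w == "w0") * (g == "B")
                                 + rng.normal()})
        df = pd.DataFrame(rows)
        mine = MixedAnova(df, dv="dv", within=["w"], subject="subject",
                          between="grp").fit()
        ref = pg.mixed_anova(data=df, dv="dv", within="w", subject="subject",
                             between="grp").set_index("Source")
        assert mine.f("grp") == pytest.approx(ref.loc["grp", "F"], rel=1e-9)
        assert mine.f("w") == pytest.approx(ref.loc["w", "F"], rel=1e-9)
        assert mine.f("w:grp") == pytest.approx(ref.loc["Interaction", "F"], rel=1e-9)

    def test_reduces_to_paired_t_in_degenerate_design(self):
        rng = np.random.default_rng(4)
        x0, x1 = rng.normal(size=10), rng.normal(size=10) + 0.5
        rows = [{"subject": f"s{s}", "w": w, "dv": v}
                for s, (a, b) in enumerate(zip(x0, x1))
                for w, v in (("w0", a), ("w1", b))]
        res = MixedAnova(pd.DataFrame(rows), dv="dv", within=["w"],
                         subject="subject").fit()
        t = stats.ttest_rel(x0, x1)
        assert res.f("w") == pytest.approx(t.statistic ** 2, rel=1e-10)
        assert res.p("w") == pytest.approx(t.pvalue, rel=1e-9)

    def test_constant_responses_give_zero_F(self):
        rows = [{"subject": f"s{s}", "w": w, "dv": 1.0}
                for s in range(4) for w in ("w0", "w1")]
        res = MixedAnova(pd.DataFrame(rows), dv="dv", within=["w"],
                         subject="subject").fit()
        assert res.f("w") == 0.0 and res.p("w") == 1.0

    def test_missing_cells_rejected(self):
        rows = [{"subject": "s0", "w": "w0", "dv": 1.0},
                {"subject": "s0", "w": "w1", "dv": 2.0},
                {"subject": "s1", "w": "w0", "dv": 1.5}]
        with pytest.raises(ValueError):
            MixedAnova(pd.DataFrame(rows), dv="dv", within=["w"], subject="subject")


class TestSignatureClassification:
    def _result(self, p_out, p_int):
        from twostep.factorial import AnovaResults

        table = pd.DataFrame([
            {"effect": "outcome_cat", "df1": 1, "df2": 21, "F": 1.0, "p": p_out},
            {"effect": "outcome_cat:transition", "df1": 1, "df2": 21, "F": 1.0,
             "p": p_int},
        ])
        return AnovaResults(table, design="test")

    @pytest.mark.parametrize("p_out,p_int,expected", [
        (0.001, 0.9, "model_free"),
        (0.9, 0.001, "model_based"),
        (0.01, 0.01, "mixed"),
        (0.5, 0.5, "neither"),
    ])
    def test_four_way_classification(self, p_out, p_int, expected):
        assert classify_signature(self._result(p_out, p_int)) == expected

    def test_missing_effect_raises(self):
        with pytest.raises(KeyError):
            classify_signature(self._result(0.5, 0.5),
                               interaction_effect="nonexistent")
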