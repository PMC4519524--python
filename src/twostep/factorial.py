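"""Stay/shift factorial analysis of first-stage choices.

The model-agnostic analysis of the two-step task: for every consecutive
pair of trials, classify the earlier trial by its outcome (better/worse)
and transition (common/rare), and record whether the later trial repeats
the first-stage choice.  Model-free control predicts a main effect of the
previous outcome on stay probability; model-based control predicts an
outcome-by-transition interaction (the crossover pattern).

Stay probabilities are arcsine-square-root transformed and entered into a
mixed-design ANOVA (:class:`MixedAnova`) with subject group as the
between factor and the two-level task factors (outcome category,
transition, optionally valence) as within factors.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import PUNISHMENT, REWARD, SubjectDataset

__all__ = [
    "StayTable",
    "compute_stay_table",
    "stay_long_table",
    "arcsine_transform",
    "MixedAnova",
    "AnovaResults",
    "classify_signature",
    "cumulative_outcome",
]

logger = logging.getLogger(__name__)

OUTCOME_CATS = ("better", "worse")  # reward/no-loss vs no-reward/loss
TRANSITIONS = ("common", "rare")


@dataclass
class StayTable:
    """Per-subject 2x2 stay probabilities and contributing pair counts.

    Rows index the previous trial's outcome category (better, worse);
    columns its transition (common, rare).  A cell with ``n_pairs == 0``
    has an undefined (NaN) stay probability.
    """

    subject_id: str
    group: str
    valence: str
    p_stay: np.ndarray  # (2, 2) float, NaN where undefined
    n_pairs: np.ndarray  # (2, 2) int

    @property
    def complete(self) -> bool:
        """True when every cell has at least one contributing trial pair."""
        return bool(np.all(self.n_pairs > 0))

    def to_frame(self, arcsine: bool = True) -> pd.DataFrame:
        rows = []
        for i, oc in enumerate(OUTCOME_CATS):
            for j, tr in enumerate(TRANSITIONS):
                p = self.p_stay[i, j]
                rows.append({
                    "subject_id": self.subject_id, "group": self.group,
                    "valence": self.valence, "outcome_cat": oc, "transition": tr,
                    "stay_p": p, "n_pairs": int(self.n_pairs[i, j]),
                    **({"stay_p_arcsine": arcsine_transform(p) if not np.isnan(p) else np.nan}
                       if arcsine else {}),
                })
        return pd.DataFrame(rows)


def _is_better(outcome: np.ndarray, valence: str) -> np.ndarray:
    """Valence-unifying outcome category: reward or avoided loss counts as better."""
    if valence == REWARD:
        return outcome > 0
    return outcome >= 0  # punishment: no loss is the better outcome


def compute_stay_table(dataset: SubjectDataset) -> StayTable:
    """Tabulate stay behaviour over consecutive non-omitted trial pairs.

    For each pair of adjacent trials (t-1, t) with neither omitted, the
    earlier trial is classified by (outcome category, transition) and the
    pair scores a stay when both first-stage choices agree.  Pairs that
    span an omitted trial are skipped.
    """
    ok = ~dataset.omitted
    if int(ok.sum()) < 2:
        raise ValueError("need at least two non-omitted trials")
    better = _is_better(dataset.outcome, dataset.valence)
    stays = np.zeros((2, 2))
    counts = np.zeros((2, 2), dtype=np.int64)
    for t in range(1, dataset.n_trials):
        if not (ok[t - 1] and ok[t]):
            continue
        i = 0 if better[t - 1] else 1
        j = int(dataset.transition[t - 1])  # 0 common, 1 rare
        counts[i, j] += 1
        stays[i, j] += float(dataset.choice1[t] == dataset.choice1[t - 1])
    with np.errstate(invalid="ignore"):
        p = np.where(counts > 0, stays / np.maximum(counts, 1), np.nan)
    return StayTable(dataset.subject_id, dataset.group, dataset.valence, p, counts)


def stay_long_table(datasets: Sequence[SubjectDataset],
                    drop_incomplete: bool = True) -> pd.DataFrame:
    """Long-format stay probabilities for a collection of subject datasets.

    Subjects with any empty cell in any of their valences are excluded
    listwise (logged) so the factorial design stays complete.
    """
    tables = [compute_stay_table(d) for d in datasets]
    if drop_incomplete:
        bad = {t.subject_id for t in tables if not t.complete}
        if bad:
            logger.warning("excluding %d subject(s) with empty stay cells: %s",
                           len(bad), sorted(bad))
        tables = [t for t in tables if t.subject_id not in bad]
    if not tables:
        return pd.DataFrame(columns=["subject_id", "group", "valence", "outcome_cat",
                                     "transition", "stay_p", "n_pairs", "stay_p_arcsine"])
    return pd.concat([t.to_frame() for t in tables], ignore_index=True)


def arcsine_transform(p) -> float | np.ndarray:
    """Variance-stabilising arcsine-square-root transform, arcsin(sqrt(p))."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def cumulative_outcome(dataset: SubjectDataset) -> float:
    """Sum of outcomes over non-omitted trials (cumulative earnings/losses)."""
    return float(dataset.outcome[~dataset.omitted].sum())


# ---------------------------------------------------------------------
# Mixed-design ANOVA


@dataclass
class AnovaResults:
    """F table of a fitted mixed-design ANOVA."""

    table: pd.DataFrame  # effect, df1, df2, F, p
    design: str

    def effect(self, name: str) -> pd.Series:
        match = self.table[self.table["effect"] == name]
        if match.empty:
            raise KeyError(f"no effect {name!r}; have {list(self.table['effect'])}")
        return match.iloc[0]

    def f(self, name: str) -> float:
        return float(self.effect(name)["F"])

    def p(self, name: str) -> float:
        return float(self.effect(name)["p"])

    def summary(self) -> str:
        lines = [f"Mixed-design ANOVA: {self.design}"]
        for _, r in self.table.iterrows():
            star = " *" if r["p"] < 0.05 else ""
            lines.append(f"  {r['effect']:<40} F({r['df1']:.0f}, {r['df2']:.0f}) "
                         f"= {r['F']:8.3f}  p = {r['p']:.4f}{star}")
        return "\n".join(lines)


class MixedAnova:
    """Mixed-design ANOVA with two-level within factors.

    One optional between-subjects factor and one or more within-subject
    factors, each with exactly two levels.  Because every within factor
    has a single degree of freedom, each within-subject effect reduces
    exactly to a per-subject contrast score; effects are then tested by
    one-way ANOVA machinery on those scores, which reproduces the
    classical sums-of-squares partition with subject-nested error strata
    (and sphericity holds trivially).

    Parameters
    ----------
    data : DataFrame
        Long format, one row per subject x within-cell.
    dv : str
        Response column.
    within : sequence of str
        Within-subject factor columns (each must have exactly 2 levels).
    subject : str
        Subject identifier column.
    between : str, optional
        Between-subjects factor column (any number of groups).
    """

    def __init__(self, data: pd.DataFrame, dv: str, within: Sequence[str],
                 subject: str, between: str | None = None):
        self.data = data
        self.dv = dv
        self.within = list(within)
        self.subject = subject
        self.between = between
        self._validate()

    def _validate(self) -> None:
        df = self.data
        cols = [self.dv, self.subject, *self.within] + ([self.between] if self.between else [])
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if df[self.dv].isna().any():
            raise ValueError("dv contains missing values (no imputation)")
        self.levels = {}
        for w in self.within:
            lv = tuple(sorted(df[w].unique()))
            if len(lv) != 2:
                raise ValueError(f"within factor {w!r} must have exactly 2 levels, has {len(lv)}")
            self.levels[w] = lv
        counts = df.groupby([self.subject, *self.within], sort=False).size()
        if (counts != 1).any():
            raise ValueError("design incomplete or duplicated: every subject needs "
                             "exactly one observation per within-cell")
        n_cells = 2 ** len(self.within)
        per_subj = df.groupby(self.subject).size()
        if (per_subj != n_cells).any():
            raise ValueError("every subject must have all within-cells")
        if self.between is not None:
            gmap = df.groupby(self.subject)[self.between].nunique()
            if (gmap != 1).any():
                raise ValueError("a subject appears in more than one group")
            sizes = df.drop_duplicates(self.subject).groupby(self.between).size()
            if (sizes < 2).any():
                raise ValueError("each group needs >= 2 subjects")
            self.group_levels = tuple(sorted(sizes.index))
        else:
            self.group_levels = ()

    def _contrast_scores(self, factors: Sequence[str]) -> pd.DataFrame:
        """Per-subject contrast scores for a within-effect (or subject means)."""
        df = self.data.copy()
        sign = np.ones(len(df))
        for w in factors:
            sign *= np.where(df[w] == self.levels[w][0], 1.0, -1.0)
        df["_c"] = df[self.dv] * sign
        agg = df.groupby(self.subject, sort=True)["_c"].mean().rename("score").reset_index()
        if self.between is not None:
            gmap = self.data.drop_duplicates(self.subject).set_index(self.subject)[self.between]
            agg[self.between] = agg[self.subject].map(gmap)
        return agg

    @staticmethod
    def _f_from_ss(ss_eff: float, df1: int, ss_err: float, df2: int) -> tuple[float, float]:
        if ss_err <= 0.0:
            # degenerate error stratum: report F = 0 when there is also no
            # effect variance, otherwise infinite F with p = 0
            if ss_eff <= 1e-300:
                return 0.0, 1.0
            return math.inf, 0.0
        F = (ss_eff / df1) / (ss_err / df2)
        return F, float(stats.f.sf(F, df1, df2))

    def _test_scores(self, scores: pd.DataFrame):
        """Tests on per-subject scores: grand-mean and/or group effects.

        Returns (F_mean, p_mean, df, F_group, p_group, df_group) with the
        grand mean tested as the unweighted mean of group means (Type III).
        """
        y = scores["score"].to_numpy(dtype=float)
        n = len(y)
        if self.between is None:
            mean = y.mean()
            ss_err = float(((y - mean) ** 2).sum())
            F, p = self._f_from_ss(n * mean ** 2, 1, ss_err, n - 1)
            return (F, p, (1, n - 1), None, None, None)
        a = len(self.group_levels)
        groups = [scores.loc[scores[self.between] == g, "score"].to_numpy()
                  for g in self.group_levels]
        ns = np.array([len(g) for g in groups])
        means = np.array([g.mean() for g in groups])
        ss_err = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
        df2 = n - a
        # grand-mean contrast (unweighted over groups)
        theta = means.mean()
        scale = float((1.0 / a ** 2) * np.sum(1.0 / ns))
        F_mean, p_mean = self._f_from_ss(theta ** 2 / scale, 1, ss_err, df2)
        # group effect on the scores
        grand = float(np.sum(ns * means) / n)
        ss_g = float(np.sum(ns * (means - grand) ** 2))
        F_g, p_g = self._f_from_ss(ss_g, a - 1, ss_err, df2)
        return (F_mean, p_mean, (1, df2), F_g, p_g, (a - 1, df2))

    def fit(self) -> AnovaResults:
        """Compute F and p for every main effect and interaction of the design."""
        rows = []
        if self.between is not None:
            scores = self._contrast_scores([])
            _, _, _, F_g, p_g, dfg = self._test_scores(scores)
            rows.append({"effect": self.between, "df1": dfg[0], "df2": dfg[1],
                         "F": F_g, "p": p_g})
        for r in range(1, len(self.within) + 1):
            for combo in itertools.combinations(self.within, r):
                scores = self._contrast_scores(combo)
                F, p, dfm, F_g, p_g, dfg = self._test_scores(scores)
                name = ":".join(combo)
                rows.append({"effect": name, "df1": dfm[0], "df2": dfm[1],
                             "F": F, "p": p})
                if self.between is not None:
                    rows.append({"effect": f"{name}:{self.between}",
                                 "df1": dfg[0], "df2": dfg[1], "F": F_g, "p": p_g})
        design = " x ".join(self.within) + (f" (between: {self.between})"
                                            if self.between else " (within only)")
        return AnovaResults(pd.DataFrame(rows), design)


def classify_signature(result: AnovaResults, alpha_level: float = 0.05,
                       outcome_effect: str = "outcome_cat",
                       interaction_effect: str = "outcome_cat:transition") -> str:
    """Classify a stay-probability ANOVA into a learning-strategy signature.

    * ``model_free``  — only the previous-outcome main effect is significant
    * ``model_based`` — only the outcome-by-transition interaction is
    * ``mixed``       — both are significant
    * ``neither``     — neither is
    """
    p_out = result.p(outcome_effect)
    p_int = result.p(interaction_effect)
    out_sig = p_out < alpha_level
    int_sig = p_int < alpha_level
    if out_sig and int_sig:
        return "mixed"
    if out_sig:
        return "model_free"
    if int_sig:
        return "model_based"
    return "neither"
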