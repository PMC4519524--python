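"""Maximum-likelihood fitting, model selection and group comparison.

Two model families are exposed in the statsmodels idiom: construct a
model from one subject's trial log(s) and call :meth:`RLModel.fit` to
obtain an :class:`RLFitResults` with estimates, standard errors and a
``summary()`` table.

* :class:`QSarsa` — pure model-free SARSA learner; free parameters
  (alpha, beta).
* :class:`HybridRL` — hybrid model-based/model-free learner; free
  parameters (alpha, beta, rho, omega).  Q-SARSA is the special case
  omega = 0, rho = 0.

Per-subject log-evidence is approximated by BIC, and models are compared
at the group level with a random-effects Dirichlet scheme over model
frequencies (:func:`bms_random_effects`).  Fitted parameters are compared
between groups by one-way MANOVA with univariate follow-ups
(:func:`compare_params_between_groups`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from ._likelihood import nll_arrays
from .agents import AgentParams, PARAM_NAMES
from .data import SubjectDataset

__all__ = [
    "ModelSpec",
    "QSARSA",
    "HYBRID",
    "RLModel",
    "QSarsa",
    "HybridRL",
    "RLFitResults",
    "nll",
    "fit_subject",
    "bic_log_evidence",
    "log_evidence",
    "BmsResult",
    "bms_random_effects",
    "ConvergenceError",
    "normality_screen",
    "compare_params_between_groups",
    "ParamComparisonResult",
]

BETA_MAX = 20.0  # search-space cap on the inverse temperature

# Unconstrained search space: logistic map for [0, 1] parameters, log map
# for beta (capped at BETA_MAX), identity for rho.  (lo, hi) bound the
# optimizer; (start_lo, start_hi) bound the random restarts.
_LOGIT99 = math.log(0.99 / 0.01)
_TRANSFORMS = {
    "alpha": ("logit", -16.0, 16.0, -_LOGIT99, _LOGIT99),
    "omega": ("logit", -16.0, 16.0, -_LOGIT99, _LOGIT99),
    "beta": ("log", math.log(1e-3), math.log(BETA_MAX), math.log(0.1), math.log(BETA_MAX)),
    "rho": ("identity", -10.0, 10.0, -2.0, 2.0),
}


def _to_natural(name: str, x: float) -> float:
    kind = _TRANSFORMS[name][0]
    if kind == "logit":
        return 1.0 / (1.0 + math.exp(-x))
    if kind == "log":
        return math.exp(x)
    return x


def _from_natural(name: str, v: float) -> float:
    kind = _TRANSFORMS[name][0]
    if kind == "logit":
        v = min(max(v, 1e-12), 1.0 - 1e-12)
        return math.log(v / (1.0 - v))
    if kind == "log":
        return math.log(max(v, 1e-12))
    return v


@dataclass(frozen=True)
class ModelSpec:
    """A model family: which agent parameters are free, which are frozen."""

    name: str
    free_params: tuple[str, ...]
    fixed_params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.free_params) & set(self.fixed_params)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        missing = set(PARAM_NAMES) - set(self.free_params) - set(self.fixed_params)
        if missing - {"lam"}:
            raise ValueError(f"unspecified parameters: {sorted(missing)}")

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.free_params)

    def build_params(self, free: Mapping[str, float]) -> AgentParams:
        d = {"lam": 1.0, **self.fixed_params, **free}
        return AgentParams(**d)


QSARSA = ModelSpec("qsarsa", ("alpha", "beta"), {"rho": 0.0, "omega": 0.0, "lam": 1.0})
HYBRID = ModelSpec("hybrid", ("alpha", "beta", "rho", "omega"), {"lam": 1.0})
MODEL_SPECS = {"qsarsa": QSARSA, "hybrid": HYBRID}


def nll(dataset: SubjectDataset | Sequence[SubjectDataset], spec: ModelSpec,
        params: AgentParams | Mapping[str, float],
        p_common: float = 0.7, fast: bool = True) -> tuple[float, int]:
    """Negative log-likelihood of the observed choices and its term count.

    Both stage choices of every non-omitted trial contribute one term each
    (``n_obs = 2 x non-omitted trials``); omitted trials reset the
    perseveration reference.  For a sequence of datasets the agent state
    is reset at each dataset boundary and the terms are summed.
    """
    if isinstance(params, AgentParams):
        p = params
    else:
        p = spec.build_params(dict(params))
    p.validate()
    datasets = [dataset] if isinstance(dataset, SubjectDataset) else list(dataset)
    if not datasets or any(d.n_trials == 0 for d in datasets):
        raise ValueError("empty dataset")
    total, n_obs = 0.0, 0
    for d in datasets:
        v, n = nll_arrays(d.choice1, d.state2, d.choice2, d.outcome, d.omitted,
                          p.alpha, p.beta, p.rho, p.omega, p.lam, p_common,
                          fast=fast)
        total += v
        n_obs += n
    if not math.isfinite(total):
        raise FloatingPointError("non-finite likelihood accumulation")
    return total, n_obs


def bic_log_evidence(nll_value: float, k: int, n_obs: int) -> float:
    """BIC approximation to the per-subject log model evidence.

    log_evidence = -nll - (k/2) * ln(n_obs)
    """
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    return -nll_value - 0.5 * k * math.log(n_obs)


class RLModel:
    """Reinforcement-learning choice model for one subject's trial log(s).

    Parameters
    ----------
    data : SubjectDataset or sequence of SubjectDataset
        The trial log(s) whose choices are modelled.  Passing several
        datasets (e.g. both task valences) fits shared parameters with
        learner state reset at each dataset boundary.
    spec : ModelSpec
        Which parameters are free (:data:`QSARSA` or :data:`HYBRID`).
    p_common : float
        The (known) common-transition probability used for the
        model-based values.
    """

    def __init__(self, data: SubjectDataset | Sequence[SubjectDataset],
                 spec: ModelSpec, p_common: float = 0.7):
        self.datasets = [data] if isinstance(data, SubjectDataset) else list(data)
        if not self.datasets:
            raise ValueError("no data")
        self.spec = spec
        self.p_common = p_common
        self.subject_id = "+".join(dict.fromkeys(d.subject_id for d in self.datasets))

    # -- likelihood ----------------------------------------------------
    def nll(self, params: AgentParams | Mapping[str, float]) -> tuple[float, int]:
        return nll(self.datasets, self.spec, params, p_common=self.p_common)

    def loglike(self, params: AgentParams | Mapping[str, float]) -> float:
        return -self.nll(params)[0]

    def _free_from_theta(self, theta: np.ndarray) -> dict[str, float]:
        return {name: _to_natural(name, theta[i])
                for i, name in enumerate(self.spec.free_params)}

    def _objective(self, theta: np.ndarray) -> float:
        p = self.spec.build_params(self._free_from_theta(theta))
        return nll_arrays_sum(self.datasets, p, self.p_common)

    # -- estimation ----------------------------------------------------
    def fit(self, n_restarts: int = 20, seed: int | None = 0,
            start: Mapping[str, float] | None = None) -> "RLFitResults":
        """Maximum-likelihood fit from seeded random restarts.

        Minimises the negative log-likelihood over the transformed
        (unconstrained) parameter space with L-BFGS-B, starting from
        ``n_restarts`` uniform draws in the transformed start box (plus
        ``start`` if given); deterministic given ``seed``.
        """
        if n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        rng = np.random.default_rng(seed)
        names = self.spec.free_params
        bounds = [(_TRANSFORMS[n][1], _TRANSFORMS[n][2]) for n in names]
        starts = [
            np.array([rng.uniform(_TRANSFORMS[n][3], _TRANSFORMS[n][4]) for n in names])
            for _ in range(n_restarts)
        ]
        if start is not None:
            starts.insert(0, np.array([_from_natural(n, start[n]) for n in names]))

        best, failures = None, []
        for x0 in starts:
            try:
                res = optimize.minimize(self._objective, x0, method="L-BFGS-B",
                                        bounds=bounds)
            except (FloatingPointError, ValueError) as exc:  # pragma: no cover
                failures.append(str(exc))
                continue
            if not math.isfinite(res.fun):
                failures.append("non-finite objective")
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise RuntimeError(
                f"all {len(starts)} restarts failed for {self.spec.name} on "
                f"{self.subject_id}: {failures[:3]}")

        free = self._free_from_theta(best.x)
        params = self.spec.build_params(free)
        nll_value, n_obs = self.nll(params)
        bse = self._standard_errors(free)
        return RLFitResults(
            model=self, params=params, estimates=free, nll=nll_value,
            n_obs=n_obs, bse=bse, converged=bool(best.success),
            n_restarts=n_restarts, seed=seed,
        )

    def _standard_errors(self, free: Mapping[str, float]) -> dict[str, float]:
        """Asymptotic SEs from a finite-difference Hessian of the nll.

        Returns NaN per parameter when the Hessian is singular or the
        estimate sits on a bound (where the quadratic approximation fails).
        """
        from statsmodels.tools.numdiff import approx_hess1

        names = self.spec.free_params
        x = np.array([free[n] for n in names])

        def f(v: np.ndarray) -> float:
            d = dict(zip(names, v))
            d = {k: min(max(val, 1e-9), 1 - 1e-9) if k in ("alpha", "omega") else val
                 for k, val in d.items()}
            if "beta" in d:
                d["beta"] = max(d["beta"], 1e-9)
            return nll(self.datasets, self.spec, self.spec.build_params(d),
                       p_common=self.p_common)[0]

        try:
            hess = approx_hess1(x, f)
            cov = np.linalg.inv(hess)
            var = np.diag(cov)
            se = np.where(var > 0, np.sqrt(np.abs(var)), np.nan)
        except Exception:
            se = np.full(len(names), np.nan)
        return dict(zip(names, se))


def nll_arrays_sum(datasets: Sequence[SubjectDataset], p: AgentParams,
                   p_common: float) -> float:
    """Fast summed nll used inside the optimizer (no validation)."""
    total = 0.0
    for d in datasets:
        v, _ = nll_arrays(d.choice1, d.state2, d.choice2, d.outcome, d.omitted,
                          p.alpha, p.beta, p.rho, p.omega, p.lam, p_common)
        total += v
    return total


class QSarsa(RLModel):
    """Pure model-free SARSA learner (free parameters: alpha, beta)."""

    def __init__(self, data, p_common: float = 0.7):
        super().__init__(data, QSARSA, p_common=p_common)


class HybridRL(RLModel):
    """Hybrid model-based/model-free learner (alpha, beta, rho, omega)."""

    def __init__(self, data, p_common: float = 0.7):
        super().__init__(data, HYBRID, p_common=p_common)


@dataclass
class RLFitResults:
    """Maximum-likelihood estimates for one subject and model family."""

    model: RLModel
    params: AgentParams
    estimates: dict[str, float]
    nll: float
    n_obs: int
    bse: dict[str, float]
    converged: bool
    n_restarts: int
    seed: int | None

    @property
    def subject_id(self) -> str:
        return self.model.subject_id

    @property
    def model_name(self) -> str:
        return self.model.spec.name

    @property
    def k(self) -> int:
        return self.model.spec.k

    @property
    def log_evidence(self) -> float:
        """BIC approximation to the log model evidence."""
        return bic_log_evidence(self.nll, self.k, self.n_obs)

    @property
    def aic(self) -> float:
        return 2.0 * self.nll + 2.0 * self.k

    @property
    def bic(self) -> float:
        return 2.0 * self.nll + self.k * math.log(self.n_obs)

    def to_row(self) -> dict:
        row = {"subject_id": self.subject_id, "model": self.model_name,
               "nll": self.nll, "n_obs": self.n_obs,
               "log_evidence": self.log_evidence, "converged": self.converged}
        row.update(self.estimates)
        row.update({f"se_{k}": v for k, v in self.bse.items()})
        return row

    def summary(self) -> str:
        lines = [
            f"{self.model_name} fit: subject {self.subject_id}",
            f"  nll = {self.nll:.4f}   n_obs = {self.n_obs}   "
            f"log-evidence (BIC) = {self.log_evidence:.4f}",
            f"  converged = {self.converged}   restarts = {self.n_restarts}",
            f"  {'param':>8} {'estimate':>10} {'std err':>10}",
        ]
        for name in self.model.spec.free_params:
            lines.append(f"  {name:>8} {self.estimates[name]:>10.4f} "
                         f"{self.bse.get(name, float('nan')):>10.4f}")
        return "\n".join(lines)


def fit_subject(dataset: SubjectDataset | Sequence[SubjectDataset],
                spec: ModelSpec, n_restarts: int = 20, seed: int | None = 0,
                p_common: float = 0.7) -> RLFitResults:
    """Functional wrapper: fit one model family to one subject's data."""
    return RLModel(dataset, spec, p_common=p_common).fit(n_restarts=n_restarts, seed=seed)


def log_evidence(fit: RLFitResults) -> float:
    """Per-subject log model evidence (BIC approximation) of a fit."""
    return bic_log_evidence(fit.nll, fit.k, fit.n_obs)


# ---------------------------------------------------------------------
# Random-effects Bayesian model selection


class ConvergenceError(RuntimeError):
    """Variational iteration failed to converge; carries the alpha trace."""

    def __init__(self, msg: str, trace: np.ndarray):
        super().__init__(msg)
        self.trace = trace


@dataclass
class BmsResult:
    """Dirichlet posterior over model frequencies in the population."""

    model_names: tuple[str, ...]
    dirichlet_alpha: np.ndarray
    expected_frequency: np.ndarray
    exceedance_probability: np.ndarray
    n_subjects: int
    n_iterations: int

    @property
    def best_model(self) -> str:
        return self.model_names[int(np.argmax(self.exceedance_probability))]

    def to_dict(self) -> dict:
        return {
            "model_names": list(self.model_names),
            "dirichlet_alpha": self.dirichlet_alpha.tolist(),
            "expected_frequency": self.expected_frequency.tolist(),
            "exceedance_probability": self.exceedance_probability.tolist(),
            "n_subjects": self.n_subjects,
            "best_model": self.best_model,
        }

    def summary(self) -> str:
        lines = [f"Random-effects model selection ({self.n_subjects} subjects)"]
        for i, name in enumerate(self.model_names):
            lines.append(
                f"  {name:>8}: alpha = {self.dirichlet_alpha[i]:.3f}  "
                f"E[freq] = {self.expected_frequency[i]:.3f}  "
                f"xp = {self.exceedance_probability[i]:.4f}")
        return "\n".join(lines)


def bms_random_effects(log_evidence_matrix, model_names: Sequence[str] | None = None,
                       prior_alpha: float = 1.0, n_mc_samples: int = 1_000_000,
                       seed: int | None = 0, tol: float = 1e-8,
                       max_iter: int = 10_000) -> BmsResult:
    """Group-level random-effects model selection from per-subject log-evidence.

    Treats the model identity of each subject as drawn from an unknown
    population frequency vector with a Dirichlet prior, and estimates the
    Dirichlet posterior by variational iteration: subject-wise model
    responsibilities proportional to ``exp(log_evidence + digamma(alpha_m)
    - digamma(sum alpha))``, then ``alpha_m = prior_alpha + sum of
    responsibilities``.  Exceedance probabilities (the posterior
    probability each model is the most frequent) come from Monte-Carlo
    sampling of the fitted Dirichlet.
    """
    if isinstance(log_evidence_matrix, pd.DataFrame):
        if model_names is None:
            model_names = tuple(log_evidence_matrix.columns)
        L = log_evidence_matrix.to_numpy(dtype=float)
    else:
        L = np.asarray(log_evidence_matrix, dtype=float)
    if L.ndim != 2 or L.shape[0] < 1 or L.shape[1] < 2:
        raise ValueError("need a (subjects x models) matrix with >= 2 models")
    if not np.all(np.isfinite(L)):
        raise ValueError("log-evidence entries must be finite")
    n, K = L.shape
    if model_names is None:
        model_names = tuple(f"model{i}" for i in range(K))

    alpha = np.full(K, float(prior_alpha))
    trace = [alpha.copy()]
    for it in range(1, max_iter + 1):
        u = L + special.digamma(alpha) - special.digamma(alpha.sum())
        u -= u.max(axis=1, keepdims=True)
        g = np.exp(u)
        g /= g.sum(axis=1, keepdims=True)
        new_alpha = prior_alpha + g.sum(axis=0)
        trace.append(new_alpha.copy())
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    else:
        raise ConvergenceError(
            f"variational iteration did not converge in {max_iter} steps",
            np.array(trace))

    expected = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    samples = rng.dirichlet(alpha, size=int(n_mc_samples))
    winners = np.argmax(samples, axis=1)
    xp = np.bincount(winners, minlength=K) / float(n_mc_samples)
    return BmsResult(tuple(model_names), alpha, expected, xp, n, it)


# ---------------------------------------------------------------------
# Between-group parameter comparison


def normality_screen(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk test of a sample; used to gate the sqrt transform.

    Returns ``(W, p)``; a degenerate (constant) sample is reported as
    ``(nan, 0.0)``, i.e. treated as non-normal.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("normality screen needs n >= 3")
    if np.ptp(x) == 0.0:
        return float("nan"), 0.0
    w, p = stats.shapiro(x)
    return float(w), float(p)


def _sqrt_transform(name: str, x: np.ndarray) -> np.ndarray:
    """Variance-stabilising square root; signed for the unbounded rho."""
    if name == "rho":
        return np.sign(x) * np.sqrt(np.abs(x))
    return np.sqrt(np.clip(x, 0.0, None))


@dataclass
class ParamComparisonResult:
    """Univariate and multivariate between-group tests on fitted parameters."""

    univariate: pd.DataFrame  # param, F, df1, df2, p, transformed
    multivariate: dict | None  # Wilks' lambda and its F approximation
    transformed: dict[str, bool]
    multivariate_fallback: bool = False

    def summary(self) -> str:
        lines = ["Between-group comparison of fitted parameters"]
        if self.multivariate is not None:
            m = self.multivariate
            lines.append(
                f"  MANOVA Wilks' lambda = {m['wilks_lambda']:.4f}, "
                f"F({m['df1']:.0f}, {m['df2']:.0f}) = {m['F']:.3f}, p = {m['p']:.4f}")
        elif self.multivariate_fallback:
            lines.append("  MANOVA unavailable (singular covariance); univariate only")
        for _, r in self.univariate.iterrows():
            star = " *" if r["p"] < 0.05 else ""
            lines.append(
                f"  {r['param']:>8}: F({r['df1']:.0f}, {r['df2']:.0f}) = "
                f"{r['F']:.3f}, p = {r['p']:.4f}{star}")
        return "\n".join(lines)


def compare_params_between_groups(
        fits_by_group: Mapping[str, Sequence[RLFitResults] | pd.DataFrame],
        transform: str = "auto", alpha_level: float = 0.05,
) -> ParamComparisonResult:
    """Compare fitted parameters between groups (one-way MANOVA + univariate F).

    Parameters flagged non-normal by a Shapiro-Wilk screen (p < 0.05 in
    either group) are square-root transformed before testing
    (``sign(x) * sqrt(|x|)`` for the unbounded rho).  ``transform`` may be
    ``"auto"`` (screen-gated), ``"always"`` or ``"never"``.
    """
    frames = {}
    for gname, fits in fits_by_group.items():
        if isinstance(fits, pd.DataFrame):
            frames[gname] = fits.copy()
        else:
            frames[gname] = pd.DataFrame([f.estimates for f in fits])
    groups = list(frames)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    param_names = [c for c in frames[groups[0]].columns]
    for g, df in frames.items():
        if len(df) < 2:
            raise ValueError(f"group {g!r} needs >= 2 subjects")

    flags: dict[str, bool] = {}
    for p in param_names:
        if transform == "always":
            flags[p] = True
        elif transform == "never":
            flags[p] = False
        else:
            flags[p] = any(
                normality_screen(frames[g][p].to_numpy())[1] < alpha_level
                for g in groups)

    long = []
    for g in groups:
        df = frames[g][param_names].copy()
        for p in param_names:
            if flags[p]:
                df[p] = _sqrt_transform(p, df[p].to_numpy())
        df["group"] = g
        long.append(df)
    data = pd.concat(long, ignore_index=True)

    rows = []
    for p in param_names:
        samples = [data.loc[data["group"] == g, p].to_numpy() for g in groups]
        F, pval = stats.f_oneway(*samples)
        if not math.isfinite(F):  # identical values in every group
            F, pval = 0.0, 1.0
        rows.append({"param": p, "F": float(F), "df1": len(groups) - 1,
                     "df2": len(data) - len(groups), "p": float(pval),
                     "transformed": flags[p]})
    univariate = pd.DataFrame(rows)

    multivariate, fallback = None, False
    try:
        from statsmodels.multivariate.manova import MANOVA

        formula = " + ".join(param_names) + " ~ C(group)"
        mv = MANOVA.from_formula(formula, data=data)
        tbl = mv.mv_test().results["C(group)"]["stat"]
        row = tbl.loc["Wilks' lambda"]
        multivariate = {
            "wilks_lambda": float(row["Value"]),
            "F": float(row["F Value"]),
            "df1": float(row["Num DF"]),
            "df2": float(row["Den DF"]),
            "p": float(row["Pr > F"]),
        }
    except Exception:
        fallback = True
    return ParamComparisonResult(univariate, multivariate, flags, fallback)
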