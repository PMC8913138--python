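"""Logistic regression by maximum likelihood, with Wald and likelihood-ratio
tests for nested models and the model-selection ladder used to pick the best
subjective, objective and hybrid mortality models.

The fitter is a plain iteratively-reweighted-least-squares (Newton) solver.
It never raises on difficult data: non-convergence is reported through
``converged=False`` and quasi-complete separation through
``separation_flag=True`` (flagged when some fitted linear predictor exceeds
``ETA_BOUND`` in magnitude, i.e. a fitted probability is numerically 0 or
1), so that thousands of refits inside cross-validation loops run without
exception handling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .cohort import PREDICTOR_COLUMNS, Cohort

logger = logging.getLogger(__name__)

#: |linear predictor| beyond which fitted probabilities are numerically 0/1
ETA_BOUND = 30.0
MAX_ITER = 100
LL_RTOL = 1e-10


@dataclass(frozen=True)
class ModelSpec:
    """Ordered predictor list; the empty tuple is the intercept-only NULL."""

    predictors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.predictors)) != len(self.predictors):
            raise ValueError(f"duplicate predictors in {self.predictors}")

    @property
    def name(self) -> str:
        return "+".join(self.predictors) if self.predictors else "NULL"

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return set(self.predictors) <= set(other.predictors)


@dataclass
class LogisticFit:
    spec: ModelSpec
    names: tuple[str, ...]  # ("intercept", *predictors)
    params: np.ndarray
    bse: np.ndarray
    loglik: float
    n: int
    converged: bool
    separation_flag: bool
    n_iter: int
    cov: np.ndarray = field(repr=False, default=None)

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(self.bse[self.names.index(name)])

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted death risk for a design matrix without intercept."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return expit(self.params[0] + X @ self.params[1:])


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    test_kind: str  # "wald" | "lrt"


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # sum_i [ y_i eta_i - log(1 + e^{eta_i}) ], numerically stable
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def build_design(data: pd.DataFrame, predictors: tuple[str, ...]) -> np.ndarray:
    """Design matrix with leading intercept column, predictors untransformed."""
    n = len(data)
    X = np.ones((n, 1 + len(predictors)))
    for j, name in enumerate(predictors, start=1):
        if name not in data.columns:
            raise ValueError(f"predictor {name!r} not in cohort columns")
        X[:, j] = data[name].to_numpy(dtype=float)
    return X


def fit_logistic_xy(
    y: np.ndarray,
    X: np.ndarray,
    spec: ModelSpec | None = None,
    max_iter: int = MAX_ITER,
    ll_rtol: float = LL_RTOL,
) -> LogisticFit:
    """IRLS maximum likelihood on a design matrix ``X`` (intercept included).

    Standard errors come from the inverse observed information at the
    optimum.  Columns that do not enter the likelihood (zero weight in the
    information matrix) get ``nan`` standard errors.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    spec = spec if spec is not None else ModelSpec(tuple(f"x{j}" for j in range(1, p)))
    names = ("intercept", *spec.predictors) if len(spec.predictors) == p - 1 else (
        "intercept",
        *(f"x{j}" for j in range(1, p)),
    )

    beta = np.zeros(p)
    ybar = min(max(y.mean(), 0.5 / n), 1 - 0.5 / n)
    beta[0] = np.log(ybar / (1 - ybar))
    ll = _loglik(y, X @ beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-12)
        info = X.T @ (X * w[:, None])
        score = X.T @ (y - mu)
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            delta = np.linalg.pinv(info) @ score
        # step-halving guards against overshoot far from the optimum
        step = 1.0
        ll_new = ll
        for _ in range(30):
            cand = beta + step * delta
            ll_new = _loglik(y, X @ cand)
            if ll_new >= ll - 1e-12:
                break
            step /= 2
        beta = beta + step * delta
        if abs(ll_new - ll) < ll_rtol * (abs(ll) + ll_rtol):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    eta = X @ beta
    mu = expit(eta)
    w = np.maximum(mu * (1 - mu), 1e-12)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.pinv(info)
    diag = np.diag(cov).copy()
    # unidentified directions (e.g. a constant-zero predictor) -> nan SE
    col_scale = np.abs(X).max(axis=0)
    unident = (diag <= 1e-12) & (np.arange(p) > 0)
    diag[diag < 0] = np.nan
    bse = np.sqrt(diag)
    bse[unident & (col_scale == 0)] = np.nan
    separation = bool(np.max(np.abs(eta)) > ETA_BOUND)
    if not converged:
        logger.warning(
            "logistic fit (%s) did not converge in %d iterations", spec.name, max_iter
        )
    return LogisticFit(
        spec=spec,
        names=names,
        params=beta,
        bse=bse,
        loglik=ll,
        n=n,
        converged=converged,
        separation_flag=separation,
        n_iter=it,
        cov=cov,
    )


def fit_logistic(cohort: Cohort | pd.DataFrame, spec: ModelSpec) -> LogisticFit:
    """Fit a logistic mortality model on a cohort.

    Rows missing any used predictor are excluded (complete-case) with a
    logged count; the cohort must contain both outcome classes.
    """
    data = cohort.data if isinstance(cohort, Cohort) else cohort
    cols = ["outcome", *spec.predictors]
    complete = data[cols].notna().all(axis=1)
    n_drop = int((~complete).sum())
    if n_drop:
        logger.warning(
            "excluded %d record(s) with missing %s", n_drop, spec.predictors
        )
    sub = data.loc[complete]
    y = sub["outcome"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError(
            "cohort contains a single outcome class; cannot fit a logistic model"
        )
    X = build_design(sub, spec.predictors)
    return fit_logistic_xy(y, X, spec=spec)


def wald_test(fit: LogisticFit, predictor: str) -> TestResult:
    """Single-coefficient Wald chi-square test (df = 1)."""
    if predictor not in fit.names:
        raise ValueError(f"predictor {predictor!r} not in fitted model {fit.spec.name}")
    z = fit.coef(predictor) / fit.se(predictor)
    stat = float(z * z)
    return TestResult(stat, 1, float(stats.chi2.sf(stat, 1)), "wald")


def likelihood_ratio_test(nested: LogisticFit, full: LogisticFit) -> TestResult:
    """LRT of a nested model pair: 2(l_full - l_nested) ~ chi2(df)."""
    if not nested.spec.is_nested_in(full.spec):
        raise ValueError(
            f"{nested.spec.name} is not nested in {full.spec.name}"
        )
    if nested.n != full.n:
        raise ValueError(
            "fits use different case counts; refit both models on the common "
            "complete-case subset"
        )
    df = len(full.spec.predictors) - len(nested.spec.predictors)
    stat = 2.0 * (full.loglik - nested.loglik)
    if stat < -1e-6:
        logger.warning(
            "LRT statistic %.3g < 0 (%s vs %s): convergence failure suspected",
            stat,
            full.spec.name,
            nested.spec.name,
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return TestResult(stat, max(df, 1) if df > 0 else 0, p, "lrt")


SUBJECTIVE_INDEXES = ("MID", "SPR", "SPRL", "SPRR")
OBJECTIVE_SCORES = ("PIM2", "TISS28")


@dataclass
class LadderReport:
    selected: ModelSpec
    wald_table: pd.DataFrame  # variable, estimate, se, p, significant
    lrt_table: pd.DataFrame  # comparison, statistic, df, p
    subjective_best: ModelSpec | None
    objective_best: ModelSpec | None


def selection_ladder(
    cohort: Cohort,
    subjective: tuple[str, ...] = SUBJECTIVE_INDEXES,
    objective: tuple[str, ...] = OBJECTIVE_SCORES,
    alpha: float = 0.05,
) -> LadderReport:
    """Model-selection procedure over subjective and objective predictors.

    (i) univariate Wald screen within each group; (ii) likelihood-ratio
    tests of each significant variable against NULL and of combined group
    models against each single-variable model, retaining an added variable
    only when the combined-vs-single p-value is below ``alpha``;
    (iii) a final hybrid (best-subjective + best-objective) compared against
    each component.  All tests performed are returned in the report.
    """
    wald_rows: list[dict] = []
    lrt_rows: list[dict] = []
    null_fit = fit_logistic(cohort, ModelSpec(()))
    fits: dict[tuple[str, ...], LogisticFit] = {(): null_fit}

    def get_fit(preds: tuple[str, ...]) -> LogisticFit:
        if preds not in fits:
            fits[preds] = fit_logistic(cohort, ModelSpec(preds))
        return fits[preds]

    def record_lrt(small: tuple[str, ...], big: tuple[str, ...]) -> float:
        res = likelihood_ratio_test(get_fit(small), get_fit(big))
        lrt_rows.append(
            {
                "comparison": f"{ModelSpec(big).name} vs. {ModelSpec(small).name}",
                "statistic": res.statistic,
                "df": res.df,
                "p": res.p_value,
            }
        )
        return res.p_value

    def group_best(variables: tuple[str, ...]) -> ModelSpec | None:
        significant = []
        for var in variables:
            f = get_fit((var,))
            res = wald_test(f, var)
            wald_rows.append(
                {
                    "variable": var,
                    "estimate": f.coef(var),
                    "se": f.se(var),
                    "p": res.p_value,
                    "significant": res.p_value < alpha,
                }
            )
            if res.p_value < alpha:
                significant.append(var)
        if not significant:
            return None
        # LRT of each significant single model vs NULL; best = lowest p
        null_p = {var: record_lrt((), (var,)) for var in significant}
        significant.sort(key=lambda v: (null_p[v], variables.index(v)))
        current = (significant[0],)
        if len(significant) > 1:
            combined = tuple(significant)
            record_lrt((), combined)
            for var in significant[1:]:
                cand = (*current, var)
                p = record_lrt(current, cand)
                if p < alpha:
                    current = cand
        return ModelSpec(current)

    subj_best = group_best(subjective)
    obj_best = group_best(objective)

    if subj_best is None and obj_best is None:
        selected = ModelSpec(())
    elif subj_best is None:
        selected = obj_best
    elif obj_best is None:
        selected = subj_best
    else:
        hybrid = tuple(dict.fromkeys((*subj_best.predictors, *obj_best.predictors)))
        record_lrt((), hybrid)
        p_obj_adds = record_lrt(subj_best.predictors, hybrid)
        p_subj_adds = record_lrt(obj_best.predictors, hybrid)
        if p_obj_adds < alpha and p_subj_adds < alpha:
            selected = ModelSpec(hybrid)
        elif p_subj_adds < alpha:  # objective adds nothing over subjective
            selected = subj_best
        elif p_obj_adds < alpha:
            selected = obj_best
        else:
            # neither component improves the other: lower LRT-vs-NULL p wins,
            # then fewer predictors
            def key(spec: ModelSpec) -> tuple:
                res = likelihood_ratio_test(null_fit, get_fit(spec.predictors))
                return (res.p_value, len(spec.predictors))

            selected = min((subj_best, obj_best), key=key)

    return LadderReport(
        selected=selected,
        wald_table=pd.DataFrame(wald_rows),
        lrt_table=pd.DataFrame(lrt_rows),
        subjective_best=subj_best,
        objective_best=obj_best,
    )
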