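"""Population-level arm: case/control selection, per-SD logistic odds
ratio, and rank-based ROC AUC.

Selection applies the study exclusion rules in order: males out, incomplete
genetic or phenotypic records out, controls with any personal or family
history of disease out, and finally at most one control per family (the
oldest eligible member by default, to maximise accrued risk-free years; a
seeded random choice is available).

Association is a maximum-likelihood logistic fit of disease status on the
standardized PRS; the exponentiated coefficient is the odds ratio per SD
with a Wald 95% interval.  AUC is the Mann-Whitney pair statistic: the
fraction of case-control pairs where the case scores higher, ties credited
half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

ROSTER_COLUMNS = [
    "sample_id",
    "family_id",
    "sex",
    "age",
    "bc_status",
    "personal_history",
    "family_history",
    "genotyped",
    "phenotype_complete",
]


class SeparationError(ValueError):
    """Raised when the logistic likelihood has no finite maximiser."""


@dataclass
class SelectionResult:
    """Outcome of the case/control filter cascade."""

    case_ids: list[str]
    control_ids: list[str]
    tally: dict[str, int]  # criterion -> number removed, in application order

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    @property
    def n_controls(self) -> int:
        return len(self.control_ids)

    def tally_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"criterion": list(self.tally), "n_removed": list(self.tally.values())}
        )


@dataclass
class AssociationResult:
    """Per-SD logistic association plus discrimination summaries."""

    or_per_sd: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    auc_prs: float | None = None
    auc_age: float | None = None
    auc_joint: float | None = None

    def to_dict(self) -> dict:
        return {
            "or_per_sd": self.or_per_sd,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "auc_prs": self.auc_prs,
            "auc_age": self.auc_age,
            "auc_joint": self.auc_joint,
        }


def select_case_control(
    roster: pd.DataFrame,
    control_tie_break: str = "oldest",
    rng: np.random.Generator | None = None,
) -> SelectionResult:
    """Apply the exclusion cascade and return cases, controls and a tally.

    Roster columns: sample_id, family_id, sex, age, bc_status in
    {case, control_eligible, ineligible}, personal_history, family_history,
    genotyped, phenotype_complete.  Criteria in order: (i) males removed;
    (ii) incomplete genetic/phenotypic records removed; (iii) controls with
    personal or family history removed; (iv) one control per family.
    """
    missing = [c for c in ROSTER_COLUMNS if c not in roster.columns]
    if missing:
        raise ValueError(f"roster lacks columns: {missing}")
    for flag in ("personal_history", "family_history", "genotyped", "phenotype_complete"):
        if roster[flag].isna().any():
            raise ValueError(f"roster flag {flag!r} has missing values")
    df = roster.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    tally: dict[str, int] = {}

    males = df["sex"] != "female"
    tally["male"] = int(males.sum())
    df = df[~males]

    incomplete = ~(df["genotyped"].astype(bool) & df["phenotype_complete"].astype(bool))
    tally["incomplete_information"] = int(incomplete.sum())
    df = df[~incomplete]

    cases = df[df["bc_status"] == "case"]
    pool = df[df["bc_status"] == "control_eligible"]

    history = pool["personal_history"].astype(bool) | pool["family_history"].astype(bool)
    tally["personal_or_family_history"] = int(history.sum())
    pool = pool[~history]

    before = len(pool)
    if control_tie_break == "oldest":
        pool = pool.sort_values(["age", "sample_id"], ascending=[False, True])
        pool = pool.groupby("family_id", sort=False).head(1)
    elif control_tie_break == "random":
        if rng is None:
            raise ValueError("random tie-break requires an rng")
        pool = pool.sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31)))
        pool = pool.groupby("family_id", sort=False).head(1)
    else:
        raise ValueError(f"unknown control_tie_break {control_tie_break!r}")
    tally["one_per_family"] = before - len(pool)

    if len(cases) == 0:
        raise ValueError("no cases remain after selection")
    if len(pool) == 0:
        raise ValueError("no controls remain after selection")
    return SelectionResult(
        case_ids=cases["sample_id"].tolist(),
        control_ids=sorted(pool["sample_id"].tolist()),
        tally=tally,
    )


def _check_inputs(status: np.ndarray, X: np.ndarray) -> None:
    if set(np.unique(status)) - {0, 1}:
        raise ValueError("status must be binary 0/1")
    if status.sum() == 0 or status.sum() == status.size:
        raise ValueError("need at least one case and one control")
    if np.any(np.var(X, axis=0) == 0):
        raise ValueError("a predictor has zero variance")


def _fit_logit(status: np.ndarray, X: np.ndarray):
    """IRLS logit fit; converts non-finite likelihood geometry into
    SeparationError."""
    design = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(status, design).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError et al.
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge")
    if np.any(np.abs(fit.params[1:]) > 25) or not np.all(np.isfinite(fit.bse)):
        raise SeparationError("perfect or quasi-perfect separation detected")
    return fit


def fit_logistic(z, status, covariate=None) -> AssociationResult:
    """Odds ratio per SD of the standardized score from a logistic fit.

    ``or_per_sd = exp(beta_z)`` with a Wald 95% CI ``exp(beta +/- 1.96 SE)``.
    An optional covariate (age) is adjusted for; the reported OR stays the
    score's.
    """
    z = np.asarray(z, dtype=float)
    y = np.asarray(status, dtype=int)
    X = z[:, None] if covariate is None else np.column_stack([z, np.asarray(covariate, float)])
    _check_inputs(y, X)
    fit = _fit_logit(y, X)
    beta, se = fit.params[1], fit.bse[1]
    zcrit = stats.norm.ppf(0.975)
    return AssociationResult(
        or_per_sd=float(np.exp(beta)),
        ci_low=float(np.exp(beta - zcrit * se)),
        ci_high=float(np.exp(beta + zcrit * se)),
        n_cases=int(y.sum()),
        n_controls=int((1 - y).sum()),
    )


def auc(scores, status) -> float:
    """Rank-based (Mann-Whitney) AUC; ties get half credit."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(status, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("status must be binary 0/1")
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs at least one sample of each class")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def joint_model(z, age, status) -> AssociationResult:
    """Two-covariate logistic model; ``auc_joint`` from fitted probabilities.

    Raises on a rank-deficient design (e.g. a duplicated covariate).
    """
    z = np.asarray(z, dtype=float)
    a = np.asarray(age, dtype=float)
    y = np.asarray(status, dtype=int)
    X = np.column_stack([z, a])
    _check_inputs(y, X)
    centred = X - X.mean(axis=0)
    if np.linalg.matrix_rank(centred) < 2:
        raise ValueError("rank-deficient design: covariates are collinear")
    fit = _fit_logit(y, X)
    beta, se = fit.params[1], fit.bse[1]
    zcrit = stats.norm.ppf(0.975)
    probs = fit.predict(sm.add_constant(X, has_constant="add"))
    return AssociationResult(
        or_per_sd=float(np.exp(beta)),
        ci_low=float(np.exp(beta - zcrit * se)),
        ci_high=float(np.exp(beta + zcrit * se)),
        n_cases=int(y.sum()),
        n_controls=int((1 - y).sum()),
        auc_joint=auc(probs, y),
    )


def associate(z, age, status) -> AssociationResult:
    """Full association summary: univariable per-SD OR with CI, AUC of the
    score alone, of age alone, and of the joint score+age model."""
    uni = fit_logistic(z, status)
    uni.auc_prs = auc(z, status)
    uni.auc_age = auc(age, status)
    uni.auc_joint = joint_model(z, age, status).auc_joint
    return uni
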