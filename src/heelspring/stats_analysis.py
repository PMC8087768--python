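"""Statistical stage: one-tailed Pearson tests, z-scoring, random-intercept LMM.

The analysis mirrors a repeated-measures gait study: per-gait summary
statistics, directional (one-tailed) Pearson correlations between the AT
moment arm and ankle SNW / mass-specific tendon stress / mass-specific
elastic energy, and a linear mixed model of ankle SNW with a subject
random intercept and standardized (z-scored) fixed effects, fitted by
maximum likelihood with Wald tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ValidationError

__all__ = [
    "CorrelationResult", "MixedModelResult", "pearson_one_tailed", "zscore",
    "random_intercept_lmm", "gait_summary", "correlation_table",
    "holm_adjust", "t_from_r",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    t_stat: float
    df: int
    p_one_tailed: float
    direction: str  # "positive" or "negative"


@dataclass
class MixedModelResult:
    """Standardized fixed-effect estimates from a subject random-intercept fit."""

    beta: Dict[str, float]
    wald_z: Dict[str, float]
    p_value: Dict[str, float]
    random_intercept_var: float
    residual_var: float
    loglike: float
    converged: bool


def t_from_r(r: float, df: int) -> float:
    """The t statistic implied by a Pearson r with the given df (= n - 2)."""
    if not -1.0 < r < 1.0:
        raise ValidationError(f"r must be strictly inside (-1, 1) to form t, got {r}")
    return r * np.sqrt(df / (1.0 - r * r))


def pearson_one_tailed(x: Sequence[float], y: Sequence[float],
                       direction: str) -> CorrelationResult:
    """Directional Pearson product-moment correlation test.

    The p-value is the tail probability of t = r sqrt(df / (1 - r^2)) with
    df = n - 2 in the stated direction.
    """
    if direction not in ("positive", "negative"):
        raise ValidationError(f"direction must be 'positive' or 'negative', got {direction!r}")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant input: correlation undefined")
    r = float(sps.pearsonr(x, y).statistic)
    df = x.size - 2
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
        p = 0.0 if (r > 0) == (direction == "positive") else 1.0
    else:
        t = t_from_r(r, df)
        p = float(sps.t.sf(t, df)) if direction == "positive" else float(sps.t.cdf(t, df))
    return CorrelationResult(r=r, t_stat=float(t), df=df, p_one_tailed=p, direction=direction)


def zscore(x: Sequence[float]) -> np.ndarray:
    """Center and scale to sample mean 0, sample SD 1 (ddof = 1)."""
    x = np.asarray(x, float)
    if x.size < 2:
        raise ValidationError(f"need at least 2 observations to z-score, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError("constant input: z-score undefined")
    return (x - x.mean()) / sd


def _name_collinear(X: np.ndarray, names: Sequence[str]) -> List[str]:
    """Columns implicated in a rank deficiency, by tiny R diagonal of a QR."""
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * 1e-10 if diag.size else 0.0
    return [names[i] for i in np.nonzero(diag <= tol)[0]]


def random_intercept_lmm(
    y: Sequence[float],
    X: pd.DataFrame | np.ndarray,
    subject: Sequence[str],
    column_names: Optional[Sequence[str]] = None,
) -> MixedModelResult:
    """Maximum-likelihood fit of y = X beta + u_subject + eps.

    One random-intercept variance component per subject; fixed effects are
    expected to be z-scored so the betas are standardized weights.  Wald z
    tests per coefficient.  An intercept column is added internally.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    y = np.asarray(y, float)
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(float)
    else:
        Xm = np.asarray(X, float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        names = list(column_names) if column_names else [f"x{i}" for i in range(Xm.shape[1])]
    subject = np.asarray(subject)
    groups, counts = np.unique(subject, return_counts=True)
    if groups.size < 2 or np.min(counts) < 2:
        raise ValidationError("need >= 2 subjects with >= 2 observations each")
    exog = np.column_stack([np.ones(len(y)), Xm])
    exog_names = ["intercept", *names]
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        bad = _name_collinear(exog, exog_names)
        raise ValidationError(f"singular design matrix; collinear columns: {bad}")
    fit = None
    last_err: Exception | None = None
    for method in ("bfgs", "lbfgs", "cg", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = MixedLM(y, exog, groups=subject)
                fit = model.fit(reml=False, method=method, maxiter=500)
            break
        except np.linalg.LinAlgError as exc:  # optimizer-dependent Hessian failure
            last_err = exc
    if fit is None:
        raise ValidationError(f"mixed-model fit failed: {last_err}")
    beta = dict(zip(exog_names, fit.fe_params))
    se = dict(zip(exog_names, fit.bse_fe))
    wald = {k: beta[k] / se[k] if se[k] > 0 else np.inf for k in beta}
    pvals = {k: float(2.0 * sps.norm.sf(abs(wald[k]))) for k in beta}
    return MixedModelResult(
        beta=beta,
        wald_z={k: float(v) for k, v in wald.items()},
        p_value=pvals,
        random_intercept_var=float(fit.cov_re.iloc[0, 0]) if hasattr(fit.cov_re, "iloc")
        else float(np.atleast_2d(fit.cov_re)[0, 0]),
        residual_var=float(fit.scale),
        loglike=float(fit.llf),
        converged=bool(fit.converged),
    )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(p_values, float)
    order = np.argsort(p)
    m = p.size
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted


# -- outcome-table analyses --------------------------------------------------

def gait_summary(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of Froude and per-joint SNW by gait."""
    rows = []
    for gait, grp in outcomes.groupby("gait", sort=False):
        row = {"gait": gait, "n_steps": len(grp)}
        for col in ("froude", "snw_hip", "snw_knee", "snw_ankle"):
            row[f"{col}_mean"] = grp[col].mean()
            row[f"{col}_sd"] = grp[col].std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows)


_CORR_VARIABLES: Tuple[Tuple[str, str, str], ...] = (
    # (outcome column, test direction, label)
    ("snw_ankle", "positive", "ankle SNW"),
    ("stress_mean_per_kg", "negative", "mass-specific stress"),
    ("energy_per_kg", "negative", "mass-specific energy"),
)


def correlation_table(
    outcomes: pd.DataFrame,
    subjects: pd.DataFrame,
    gaits: Optional[Sequence[str]] = None,
    subject_means: bool = False,
) -> pd.DataFrame:
    """Directional correlations of per-step outcomes with the AT moment arm.

    ``subjects`` needs columns ``subject_id`` and ``at_moment_arm``.  By
    default steps are pooled within each gait (step-level df); with
    ``subject_means=True`` each subject contributes one mean value per gait,
    which keeps the nominal test size honest under repeated steps.
    """
    arm = subjects.set_index("subject_id")["at_moment_arm"]
    rows = []
    for gait in gaits if gaits is not None else outcomes["gait"].unique():
        grp = outcomes[outcomes["gait"] == gait]
        if subject_means:
            grp = grp.groupby("subject_id", as_index=False).mean(numeric_only=True)
        xs = arm.reindex(grp["subject_id"]).to_numpy()
        for col, direction, label in _CORR_VARIABLES:
            res = pearson_one_tailed(xs, grp[col].to_numpy(), direction)
            rows.append({
                "gait": gait, "variable": label, "column": col, "n": len(grp),
                "r": res.r, "t": res.t_stat, "df": res.df,
                "p_one_tailed": res.p_one_tailed, "direction": direction,
            })
    return pd.DataFrame(rows)


def snw_mixed_model(
    outcomes: pd.DataFrame,
    subjects: pd.DataFrame,
    gait: str = "sprint",
) -> MixedModelResult:
    """Mixed model of ankle SNW on z-scored morphometric/kinematic predictors.

    Fixed effects: AT moment arm, external moment arm R_Ankle, body mass,
    Froude number, GRF-proportional impulse, tendon CSA; subject random
    intercept.
    """
    sub = subjects.set_index("subject_id")
    grp = outcomes[outcomes["gait"] == gait].reset_index(drop=True)
    if grp.empty:
        raise ValidationError(f"no outcomes for gait {gait!r}")
    X = pd.DataFrame({
        "at_moment_arm": sub["at_moment_arm"].reindex(grp["subject_id"]).to_numpy(),
        "r_ankle_ext": grp["r_ankle_ext"].to_numpy(),
        "body_mass": sub["body_mass"].reindex(grp["subject_id"]).to_numpy(),
        "froude": grp["froude"].to_numpy(),
        "grf_impulse": grp["force_impulse"].to_numpy(),
        "tendon_csa": sub["tendon_csa"].reindex(grp["subject_id"]).to_numpy(),
    })
    Xz = pd.DataFrame({c: zscore(X[c]) for c in X.columns})
    yz = zscore(grp["snw_ankle"].to_numpy())
    return random_intercept_lmm(yz, Xz, grp["subject_id"].to_numpy())
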