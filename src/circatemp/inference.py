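"""Bootstrap and FDR machinery for cluster-association analyses.

Confidence intervals are bias-corrected (BC, no acceleration) percentile
bootstrap intervals; omnibus p-values for group differences come from
null-imposed resampling (group effects removed by within-group centering
before resampling, so the bootstrap distribution of the F-type statistic is
generated under the null); binary outcomes are modelled by maximum-
likelihood logistic regression with per-SD odds ratios for continuous
predictors; and all omnibus p-values of one analysis battery are corrected
together by the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm
from statsmodels.api import Logit
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from ._utils import check_seed

__all__ = [
    "BootstrapCI",
    "bootstrap_ci",
    "group_compare_continuous",
    "logistic_outcome",
    "fdr_correct",
    "AssociationReport",
    "build_report",
]


@dataclass
class BootstrapCI:
    estimate: float
    lower: float
    upper: float
    B: int
    seed: int | None
    method: str = "bias-corrected percentile"
    degenerate: bool = False


def bootstrap_ci(
    sample: np.ndarray,
    statistic,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> BootstrapCI:
    """Bias-corrected percentile bootstrap CI of ``statistic(sample)``.

    z0 is estimated from the proportion of resample statistics below the
    point estimate (ties counted half); interval endpoints sit at the
    normal-adjusted percentiles Phi(2*z0 +/- z_{1-alpha/2}).
    """
    sample = np.asarray(sample)
    n = len(sample)
    if n < 3:
        raise ValueError("bootstrap needs n >= 3")
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(check_seed(seed))
    est = float(statistic(sample))
    idx = rng.integers(0, n, size=(B, n))
    stats = np.array([statistic(sample[row]) for row in idx], dtype=float)
    if np.ptp(stats) < 1e-15:
        return BootstrapCI(est, est, est, B, seed, degenerate=True)
    prop = (np.sum(stats < est) + 0.5 * np.sum(stats == est)) / B
    prop = np.clip(prop, 1.0 / (B + 1), B / (B + 1.0))
    z0 = norm.ppf(prop)
    zcrit = norm.ppf(1.0 - alpha / 2.0)
    lo_q, hi_q = norm.cdf(2 * z0 - zcrit), norm.cdf(2 * z0 + zcrit)
    lower, upper = np.quantile(stats, [lo_q, hi_q])
    return BootstrapCI(est, float(lower), float(upper), B, seed)


def _f_statistic(y: np.ndarray, onehot: np.ndarray) -> float:
    """Classic one-way F for group mean differences (vector-friendly)."""
    n, k = len(y), onehot.shape[1]
    counts = onehot.sum(axis=0)
    group_means = (onehot.T @ y) / counts
    grand = y.mean()
    ssb = float(np.sum(counts * (group_means - grand) ** 2))
    ssw = float(np.sum((y - onehot @ group_means) ** 2))
    if ssw <= 0:
        return np.inf
    return (ssb / (k - 1)) / (ssw / (n - k))


def group_compare_continuous(
    outcome: np.ndarray,
    labels: np.ndarray,
    b_ci: int = 1000,
    b_p: int = 500,
    seed: int = 0,
    permutation: bool = False,
) -> dict:
    """Per-group means with BC bootstrap CIs, a bootstrap omnibus p, and
    pairwise contrasts.

    The omnibus p-value resamples the F-type statistic under the null
    obtained by within-group centering (group effects removed, residuals
    pooled); ``permutation=True`` uses a label-permutation null instead.
    """
    y = np.asarray(outcome, dtype=float)
    labels = np.asarray(labels)
    ok = np.isfinite(y)
    y, labels = y[ok], labels[ok]
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if (labels == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 subjects")
    seed = check_seed(seed)
    rng = np.random.default_rng(seed)
    onehot = (labels[:, None] == groups[None, :]).astype(float)
    n = len(y)

    f_obs = _f_statistic(y, onehot)
    if permutation:
        null_fs = np.array(
            [_f_statistic(y, onehot[rng.permutation(n)]) for _ in range(b_p)]
        )
    else:
        centered = y - onehot @ ((onehot.T @ y) / onehot.sum(axis=0))
        y_null = y.mean() + centered
        idx = rng.integers(0, n, size=(b_p, n))
        null_fs = np.array([_f_statistic(y_null[row], onehot) for row in idx])
    p_omnibus = float((1 + np.sum(null_fs >= f_obs)) / (b_p + 1))

    per_group = {}
    for i, g in enumerate(groups):
        ci = bootstrap_ci(y[labels == g], np.mean, B=b_ci, seed=seed + 17 * (i + 1))
        per_group[str(g)] = {"mean": ci.estimate, "ci_low": ci.lower, "ci_high": ci.upper}

    pairwise = {}
    for i, gi in enumerate(groups):
        for gj in groups[i + 1 :]:
            yi, yj = y[labels == gi], y[labels == gj]
            diff = float(yi.mean() - yj.mean())
            # null: both groups centered; resample each group's residuals
            ri, rj = yi - yi.mean(), yj - yj.mean()
            di = ri[rng.integers(0, len(ri), size=(b_p, len(ri)))].mean(axis=1)
            dj = rj[rng.integers(0, len(rj), size=(b_p, len(rj)))].mean(axis=1)
            null_diffs = di - dj
            p = float((1 + np.sum(np.abs(null_diffs) >= abs(diff))) / (b_p + 1))
            pairwise[f"{gi}_vs_{gj}"] = {"diff": diff, "p": p}

    return {
        "per_group": per_group,
        "p_omnibus": p_omnibus,
        "pairwise": pairwise,
        "f_statistic": f_obs,
        "b_ci": b_ci,
        "b_p": b_p,
        "seed": seed,
    }


def _fit_logit(y: np.ndarray, X: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return Logit(y, X).fit(disp=0, maxiter=200)


def logistic_outcome(
    outcome: np.ndarray,
    predictors: pd.DataFrame,
    standardize: list[str] | None = None,
    b_ci: int = 1000,
    seed: int = 0,
) -> dict:
    """Maximum-likelihood logistic model with per-SD odds ratios.

    Columns named in ``standardize`` (continuous cosinor parameters) are
    z-scored so their ORs are per SD.  Odds-ratio CIs are BC bootstrap
    intervals over case resampling (skipped when ``b_ci=0``); complete
    separation is detected and reported as non-estimable rather than
    silently diverging.  The omnibus p is the likelihood-ratio test of the
    full model against intercept-only.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    X = predictors.astype(float).copy()
    standardize = standardize or []
    for col in standardize:
        X[col] = (X[col] - X[col].mean()) / X[col].std(ddof=0)
    names = list(X.columns)
    Xd = np.column_stack([np.ones(len(y)), X.to_numpy()])

    try:
        res = _fit_logit(y, Xd)
        if not res.mle_retvals.get("converged", True) or np.any(
            np.abs(res.params[1:]) > 15
        ):
            raise PerfectSeparationError("divergent coefficients")
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        return {"estimable": False, "diagnostic": str(exc)}

    llr_p = float(res.llr_pvalue) if np.isfinite(res.llr_pvalue) else float(
        chi2.sf(res.llr, res.df_model)
    )
    coefs = dict(zip(names, res.params[1:]))
    out = {
        "estimable": True,
        "odds_ratios": {k: float(np.exp(v)) for k, v in coefs.items()},
        "coef_p": dict(zip(names, map(float, res.pvalues[1:]))),
        "p_omnibus": llr_p,
        "n": int(len(y)),
        "seed": seed,
    }

    if b_ci:
        rng = np.random.default_rng(check_seed(seed))
        n = len(y)
        boot = []
        for _ in range(b_ci):
            idx = rng.integers(0, n, size=n)
            if y[idx].min() == y[idx].max():
                boot.append([np.nan] * len(names))
                continue
            try:
                boot.append(_fit_logit(y[idx], Xd[idx]).params[1:])
            except (PerfectSeparationError, np.linalg.LinAlgError):
                boot.append([np.nan] * len(names))
        boot = np.asarray(boot, dtype=float)
        cis = {}
        zcrit = norm.ppf(0.975)
        for j, name in enumerate(names):
            bj = boot[:, j]
            bj = bj[np.isfinite(bj)]
            est = res.params[1 + j]
            if len(bj) < 50 or np.ptp(bj) < 1e-15:
                cis[name] = {"ci_low": np.nan, "ci_high": np.nan}
                continue
            prop = np.clip(
                (np.sum(bj < est) + 0.5 * np.sum(bj == est)) / len(bj),
                1.0 / (len(bj) + 1), len(bj) / (len(bj) + 1.0),
            )
            z0 = norm.ppf(prop)
            lo, hi = np.quantile(bj, [norm.cdf(2 * z0 - zcrit), norm.cdf(2 * z0 + zcrit)])
            cis[name] = {"ci_low": float(np.exp(lo)), "ci_high": float(np.exp(hi))}
        out["or_ci"] = cis
        out["b_ci"] = b_ci
    return out


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (cumulative-minimum form)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class AssociationReport:
    """Assembled analysis battery with one global FDR family over omnibus p's."""

    rows: pd.DataFrame
    details: dict = field(default_factory=dict)
    family: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "rows": self.rows.to_dict(orient="records"),
            "family": self.family,
        }


def build_report(
    subjects: pd.DataFrame,
    cluster_col: str = "cluster",
    continuous_outcomes: list[str] | None = None,
    binary_outcomes: list[str] | None = None,
    logistic_models: dict[str, tuple[str, list[str]]] | None = None,
    b_ci: int = 1000,
    b_p: int = 500,
    seed: int = 0,
) -> AssociationReport:
    """Run the full association battery on one per-subject table.

    ``continuous_outcomes`` are compared across clusters with bootstrap
    omnibus tests and per-cluster BC CIs; ``binary_outcomes`` are modelled
    by logistic regression on cluster indicators; ``logistic_models`` maps a
    model name to (binary outcome, predictor columns) for adjusted models.
    All omnibus p-values form a single BH-FDR family; pairwise p-values are
    corrected within their own family.
    """
    continuous_outcomes = continuous_outcomes or []
    binary_outcomes = binary_outcomes or []
    logistic_models = logistic_models or {}
    seed = check_seed(seed)
    labels = subjects[cluster_col].to_numpy()
    rows, details, family = [], {}, []
    omnibus_ps, pairwise_keys, pairwise_ps = [], [], []

    for i, col in enumerate(continuous_outcomes):
        if col not in subjects:
            warnings.warn(f"outcome column {col!r} missing; row skipped")
            continue
        res = group_compare_continuous(
            subjects[col].to_numpy(), labels, b_ci=b_ci, b_p=b_p, seed=seed + 101 * (i + 1)
        )
        details[col] = res
        family.append(col)
        omnibus_ps.append(res["p_omnibus"])
        for g, d in res["per_group"].items():
            rows.append(
                {
                    "outcome": col, "kind": "continuous", "cluster": g,
                    "estimate": d["mean"], "ci_low": d["ci_low"], "ci_high": d["ci_high"],
                    "p": res["p_omnibus"],
                }
            )
        for pair, d in res["pairwise"].items():
            pairwise_keys.append(f"{col}:{pair}")
            pairwise_ps.append(d["p"])

    cluster_dummies = pd.get_dummies(subjects[cluster_col], prefix="cluster", drop_first=True)
    for i, col in enumerate(binary_outcomes):
        if col not in subjects:
            warnings.warn(f"outcome column {col!r} missing; row skipped")
            continue
        y = subjects[col].astype(float).to_numpy()
        res = logistic_outcome(
            y, cluster_dummies, b_ci=b_ci, seed=seed + 211 * (i + 1)
        )
        details[col] = res
        if not res.get("estimable", False):
            continue
        family.append(col)
        omnibus_ps.append(res["p_omnibus"])
        # per-cluster outcome probabilities with BC CIs (Table-1 style rows)
        for j, g in enumerate(np.unique(labels)):
            ci = bootstrap_ci(
                y[labels == g], np.mean, B=b_ci, seed=seed + 307 * (i + 1) + j
            )
            rows.append(
                {
                    "outcome": col, "kind": "binary", "cluster": str(g),
                    "estimate": ci.estimate, "ci_low": ci.lower, "ci_high": ci.upper,
                    "p": res["p_omnibus"],
                }
            )

    for i, (name, (ycol, pred_cols)) in enumerate(logistic_models.items()):
        res = logistic_outcome(
            subjects[ycol].astype(float).to_numpy(),
            subjects[pred_cols],
            standardize=[c for c in pred_cols if subjects[c].nunique() > 2],
            b_ci=b_ci,
            seed=seed + 401 * (i + 1),
        )
        details[name] = res
        if not res.get("estimable", False):
            continue
        family.append(name)
        omnibus_ps.append(res["p_omnibus"])
        for pred, orv in res["odds_ratios"].items():
            ci = res.get("or_ci", {}).get(pred, {"ci_low": np.nan, "ci_high": np.nan})
            rows.append(
                {
                    "outcome": name, "kind": "logistic", "cluster": pred,
                    "estimate": orv, "ci_low": ci["ci_low"], "ci_high": ci["ci_high"],
                    "p": res["p_omnibus"],
                }
            )

    frame = pd.DataFrame(rows)
    if len(frame) == 0:
        raise ValueError("no analysable rows in the battery")
    fdr = dict(zip(family, fdr_correct(omnibus_ps)))
    frame["p_fdr"] = frame["outcome"].map(fdr)
    details["_pairwise_fdr"] = (
        dict(zip(pairwise_keys, fdr_correct(pairwise_ps))) if pairwise_ps else {}
    )
    return AssociationReport(rows=frame, details=details, family=family)
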