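"""Group statistics: normality annotation, nonparametric two- and multi-group
tests with Bonferroni pairwise contrasts, rank correlations and
covariate-limited linear models.

All endpoints in this pipeline are compared nonparametrically (Mann-Whitney U
for patients vs controls, Kruskal-Wallis across the four groups with
Bonferroni-adjusted subgroup-vs-control contrasts, family size 3); the
Shapiro-Wilk test only annotates endpoints, it never switches the test.
Covariate adjustment is ordinary least squares with explicit dummy coding
(controls as the reference level) and predictors limited to group membership,
age and MoCA.  Tests are two-sided, alpha = 0.05, ties use mid-ranks.

scipy.stats and statsmodels provide the numerics behind this surface.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "StatResult",
    "shapiro_wilk",
    "mann_whitney",
    "kruskal_wallis",
    "bonferroni",
    "spearman",
    "fit_adjusted_model",
    "run_full_analysis",
]

ALPHA = 0.05
#: Bonferroni family: the three patient-subgroup-vs-control contrasts
PAIRWISE_FAMILY = 3
EXACT_MW_MAX_PRODUCT = 400


@dataclass(frozen=True)
class StatResult:
    endpoint: str
    comparison: str
    test: str  # shapiro_wilk | mann_whitney | kruskal_wallis | spearman | ols
    statistic: float
    p_value: float
    p_adjusted: float = math.nan
    beta: float = math.nan
    n_per_group: dict = field(default_factory=dict)


def shapiro_wilk(x: Sequence[float], endpoint: str = "") -> StatResult:
    """Shapiro-Wilk W and p (Royston approximation via scipy); 3 <= n <= 5000."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("sample has zero variance")
    w, p = sps.shapiro(x)
    return StatResult(endpoint=endpoint, comparison="normality",
                      test="shapiro_wilk", statistic=float(w), p_value=float(p),
                      n_per_group={"n": int(x.size)})


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    both = np.concatenate([a, b])
    return np.unique(both).size < both.size


def mann_whitney(a: Sequence[float], b: Sequence[float], endpoint: str = "",
                 comparison: str = "") -> StatResult:
    """Two-sided Mann-Whitney U.

    Exact enumeration when n_a*n_b <= 400 and there are no ties; otherwise the
    tie-corrected normal approximation (no continuity correction, so the
    two-group case agrees with Kruskal-Wallis).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    exact = a.size * b.size <= EXACT_MW_MAX_PRODUCT and not _has_ties(a, b)
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic",
                           use_continuity=False)
    return StatResult(endpoint=endpoint, comparison=comparison,
                      test="mann_whitney", statistic=float(res.statistic),
                      p_value=float(min(res.pvalue, 1.0)),
                      n_per_group={"a": int(a.size), "b": int(b.size)})


def kruskal_wallis(groups: Sequence[Sequence[float]], endpoint: str = "",
                   comparison: str = "") -> StatResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p."""
    cleaned = [np.asarray(g, dtype=float) for g in groups]
    cleaned = [g[~np.isnan(g)] for g in cleaned]
    cleaned = [g for g in cleaned if g.size > 0]
    if len(cleaned) < 2:
        raise ValueError("need at least 2 non-empty groups")
    if np.ptp(np.concatenate(cleaned)) == 0:
        # all observations identical: H = 0 by definition
        return StatResult(endpoint=endpoint, comparison=comparison,
                          test="kruskal_wallis", statistic=0.0, p_value=1.0,
                          n_per_group={str(i): int(g.size) for i, g in enumerate(cleaned)})
    h, p = sps.kruskal(*cleaned)
    return StatResult(endpoint=endpoint, comparison=comparison,
                      test="kruskal_wallis", statistic=float(h), p_value=float(p),
                      n_per_group={str(i): int(g.size) for i, g in enumerate(cleaned)})


def bonferroni(pairwise: Sequence[StatResult],
               family_size: int | None = None) -> list[StatResult]:
    """p_adjusted = min(1, m*p) for a family of m comparisons."""
    m = len(pairwise) if family_size is None else family_size
    if m < len(pairwise):
        raise ValueError("family size smaller than number of results")
    return [replace(r, p_adjusted=min(1.0, m * r.p_value)) for r in pairwise]


def spearman(x: Sequence[float], y: Sequence[float], endpoint: str = "",
             comparison: str = "") -> StatResult:
    """Spearman rho (Pearson correlation of mid-ranks) with t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    rho, p = sps.spearmanr(x, y)
    return StatResult(endpoint=endpoint, comparison=comparison, test="spearman",
                      statistic=float(rho), p_value=float(p),
                      n_per_group={"n": int(x.size)})


def _design_matrix(data: pd.DataFrame, predictors: Sequence[str],
                   group_mode: str) -> tuple[pd.DataFrame, list[str]]:
    cols: dict[str, np.ndarray] = {"const": np.ones(len(data))}
    names: list[str] = []
    for pred in predictors:
        if pred == "group":
            if group_mode == "binary":
                cols["patient"] = (data["group"] != "control").astype(float).to_numpy()
                names.append("patient")
            else:
                for g in ("central", "peripheral", "combined"):
                    cols[g] = (data["group"] == g).astype(float).to_numpy()
                    names.append(g)
        else:
            cols[pred] = data[pred].astype(float).to_numpy()
            names.append(pred)
    return pd.DataFrame(cols, index=data.index), names


def _check_full_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        collinear = []
        for col in X.columns:
            others = X.drop(columns=[col]).to_numpy()
            beta, *_ = np.linalg.lstsq(others, X[col].to_numpy(), rcond=None)
            resid = X[col].to_numpy() - others @ beta
            if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(X[col])):
                collinear.append(col)
        raise ValueError(f"design matrix is rank deficient; collinear columns: "
                         f"{collinear or list(X.columns)}")


def fit_adjusted_model(outcome: str, data: pd.DataFrame,
                       predictors: Sequence[str] = ("group", "age", "moca"),
                       group_mode: str = "binary") -> list[StatResult]:
    """OLS of ``outcome`` on group (dummy-coded, controls reference), age, MoCA.

    ``group_mode="binary"`` collapses the three impairment groups into a single
    patient indicator; ``"categorical"`` keeps one dummy per subgroup.  Rows
    with a missing outcome or predictor are dropped; a rank-deficient design
    raises with the collinear columns named.
    """
    needed = [outcome] + [p for p in predictors if p != "group"]
    if "group" in predictors:
        needed.append("group")
    missing_cols = set(needed) - set(data.columns)
    if missing_cols:
        raise ValueError(f"missing columns: {sorted(missing_cols)}")
    sub = data.dropna(subset=[c for c in needed if c != "group"])
    X, coef_names = _design_matrix(sub, predictors, group_mode)
    y = sub[outcome].astype(float).to_numpy()
    if len(sub) <= X.shape[1]:
        raise ValueError("not enough observations for the number of parameters")
    _check_full_rank(X)
    fit = sm.OLS(y, X).fit()
    n_per_group = (sub["group"].value_counts().to_dict()
                   if "group" in sub.columns else {"n": len(sub)})
    out = []
    for name in coef_names:
        out.append(StatResult(
            endpoint=outcome, comparison=f"{name} (adjusted)", test="ols",
            statistic=float(fit.tvalues[name]), p_value=float(fit.pvalues[name]),
            beta=float(fit.params[name]),
            n_per_group={str(k): int(v) for k, v in n_per_group.items()}))
    return out


# --------------------------------------------------------------------------
# full battery
# --------------------------------------------------------------------------

def _descriptive(values: pd.Series) -> str:
    v = values.dropna()
    if v.empty:
        return ""
    return f"{v.median():.3g} [{v.min():.3g}-{v.max():.3g}]"


def run_full_analysis(summary: pd.DataFrame, cohort: pd.DataFrame,
                      endpoints: Sequence[str] | None = None) -> pd.DataFrame:
    """The per-endpoint battery: group medians, patients-vs-controls
    Mann-Whitney, four-group Kruskal-Wallis, Bonferroni pairwise contrasts vs
    controls, and the covariate-adjusted OLS models (binary patient indicator
    and categorical group).

    Returns one tidy row per endpoint x task x test x comparison.
    """
    if "participant_id" not in summary.columns:
        raise ValueError("summary table must be keyed on participant_id")
    merged = summary.merge(cohort, on="participant_id", how="left", validate="m:1")
    if merged["group"].isna().any():
        orphans = merged.loc[merged["group"].isna(), "participant_id"].tolist()
        raise ValueError(f"participants missing from cohort table: {orphans}")
    if endpoints is None:
        skip = {"participant_id", "task", "group", "age", "moca", "va_decimal",
                "vf_radius", "va_logmar", "functional_type", "who_category"}
        endpoints = [c for c in summary.columns
                     if c not in skip and pd.api.types.is_numeric_dtype(summary[c])]
    missing = set(endpoints) - set(summary.columns)
    if missing:
        raise ValueError(f"missing endpoint columns: {sorted(missing)}")

    rows: list[dict] = []

    def emit(task: str, r: StatResult, descriptive: str = "") -> None:
        rows.append({
            "endpoint": r.endpoint, "task": task, "comparison": r.comparison,
            "test": r.test, "statistic": r.statistic, "p_value": r.p_value,
            "p_adjusted": r.p_adjusted, "beta": r.beta,
            "n_groups_json": json.dumps(r.n_per_group), "descriptive": descriptive,
        })

    for task, dtask in merged.groupby("task"):
        for ep in endpoints:
            if dtask[ep].dropna().empty:
                continue
            by_group = {g: dtask.loc[dtask["group"] == g, ep].dropna()
                        for g in ("control", "central", "peripheral", "combined")}
            present = {g: v for g, v in by_group.items() if len(v) > 0}
            dropped = [g for g, v in by_group.items() if len(v) == 0]
            if dropped:
                log.info("endpoint %s/%s: groups with no data excluded: %s",
                         ep, task, dropped)
            for g, v in present.items():
                emit(task, StatResult(endpoint=ep, comparison=f"median {g}",
                                      test="descriptive", statistic=float(v.median()),
                                      p_value=math.nan,
                                      n_per_group={g: int(len(v))}),
                     descriptive=_descriptive(v))
            # normality annotation only
            pooled = dtask[ep].dropna()
            if 3 <= len(pooled) <= 5000 and np.ptp(pooled.to_numpy()) > 0:
                emit(task, shapiro_wilk(pooled, endpoint=ep))
            controls = present.get("control")
            patients = pd.concat([v for g, v in present.items() if g != "control"]) \
                if len(present) > 1 else pd.Series(dtype=float)
            if controls is not None and len(patients) > 0:
                emit(task, mann_whitney(patients, controls, endpoint=ep,
                                        comparison="patients vs controls"))
            if len(present) >= 2:
                emit(task, kruskal_wallis(list(present.values()), endpoint=ep,
                                          comparison="across groups"))
            if controls is not None:
                contrasts = [
                    mann_whitney(present[g], controls, endpoint=ep,
                                 comparison=f"{g} vs controls")
                    for g in ("central", "peripheral", "combined") if g in present
                ]
                for r in bonferroni(contrasts, family_size=PAIRWISE_FAMILY):
                    emit(task, r)
            # covariate-adjusted models
            model_data = dtask[[ep, "group", "age", "moca"]]
            for mode in ("binary", "categorical"):
                try:
                    for r in fit_adjusted_model(ep, model_data,
                                                group_mode=mode):
                        emit(task, replace(r, comparison=f"{r.comparison} [{mode}]"))
                except ValueError as exc:
                    log.info("OLS for %s/%s (%s) skipped: %s", ep, task, mode, exc)

    return pd.DataFrame(rows)
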