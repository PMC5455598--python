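"""Adjusted effect estimation: stage-migration odds and survival hazards.

Two families of models are fit on a cohort table:

* binary logistic regression of declared node-positive status on the
  examined-lymph-node (ELN) count, adjusted for histology, T stage, tumor
  location and operation type — the "stage migration" model: more nodes
  examined means more patients correctly reclassified as node-positive;
* Cox proportional-hazards regression of overall survival on ELN count,
  adjusted for sex, age, histology, T stage and operation type (Efron tie
  handling).

Each model is fit with ELN either continuous (one adjusted OR/HR per
additional node) or as a categorical factor with one examined node as the
reference, which yields the per-count effect series that the break-point
scan consumes.  Sparse ELN levels are pooled with their nearest neighbour
before factor fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats

__all__ = [
    "ModelFit",
    "EffectSeries",
    "fit_stage_migration",
    "fit_survival_model",
    "eln_effect_series",
    "interaction_test",
    "positive_vs_examined_regression",
    "mean_positive_series",
]

MIGRATION_ADJUSTERS = ("histology", "t_stage", "tumor_location", "operation_type")
SURVIVAL_ADJUSTERS = ("sex", "age", "histology", "t_stage", "operation_type")


@dataclass
class ModelFit:
    """Coefficient table of one adjusted regression model (log scale)."""

    outcome: str
    coefficients: pd.DataFrame  # index: term; estimate, se, ci_low, ci_high, p_value
    n_used: int
    adjusters: tuple

    def ratio(self, term: str = "eln_count") -> dict[str, float]:
        """Effect as OR/HR with its 95% CI and p-value."""
        row = self.coefficients.loc[term]
        return {
            "estimate": float(np.exp(row["estimate"])),
            "ci_low": float(np.exp(row["ci_low"])),
            "ci_high": float(np.exp(row["ci_high"])),
            "p_value": float(row["p_value"]),
        }


@dataclass
class EffectSeries:
    """Per-ELN-count adjusted log effects versus the reference count."""

    table: pd.DataFrame  # columns: x, estimate, se, n_patients
    outcome: str
    adjusters: tuple
    pooling: dict       # raw ELN level -> pooled representative x
    reference_x: float


def _subset_cohort(cohort: pd.DataFrame, subset: str | None) -> pd.DataFrame:
    if subset in (None, "all"):
        return cohort
    masks = {
        "node-negative": cohort["n_stage"] == "N0",
        "node-positive": cohort["n_stage"] != "N0",
        "N2-only": cohort["n_stage"] == "N2",
    }
    if subset not in masks:
        raise ValueError(f"unknown subset {subset!r}; expected one of {sorted(masks)} or 'all'")
    out = cohort[masks[subset]]
    if len(out) == 0:
        raise ValueError(f"subset {subset!r} selects no patients")
    return out


def _onehot(cohort: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    """Design columns: age linear, categories one-hot vs their largest level."""
    parts = []
    for cov in covariates:
        if cov == "age":
            parts.append(cohort["age"].astype(float).rename("age"))
            continue
        counts = cohort[cov].value_counts()
        ref = counts.index[0]
        for level in sorted(c for c in counts.index if c != ref):
            parts.append((cohort[cov] == level).astype(float).rename(f"{cov}[{level}]"))
    if not parts:
        return pd.DataFrame(index=cohort.index)
    return pd.concat(parts, axis=1)


def _coef_table(estimate, se, names) -> pd.DataFrame:
    estimate = np.asarray(estimate, dtype=float)
    se = np.asarray(se, dtype=float)
    z = np.divide(estimate, se, out=np.zeros_like(estimate), where=se > 0)
    halfwidth = 1.959963984540054 * se
    return pd.DataFrame(
        {
            "estimate": estimate,
            "se": se,
            "ci_low": estimate - halfwidth,
            "ci_high": estimate + halfwidth,
            "p_value": 2 * stats.norm.sf(np.abs(z)),
        },
        index=pd.Index(names, name="term"),
    )


def _fit_logistic(y: np.ndarray, X: pd.DataFrame, outcome: str,
                  adjusters: tuple) -> ModelFit:
    design = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit()
    except Exception as exc:  # separation / singular design
        raise ValueError(f"logistic model could not be fit: {exc}") from exc
    if not np.all(np.isfinite(res.bse)):
        raise ValueError("logistic model produced non-finite standard errors "
                         "(complete separation or empty category)")
    return ModelFit(outcome, _coef_table(res.params, res.bse, design.columns),
                    n_used=len(X), adjusters=adjusters)


def _fit_cox(frame: pd.DataFrame, outcome: str, adjusters: tuple) -> ModelFit:
    if frame["event"].sum() < 1:
        raise ValueError("survival model needs at least one event")
    if (frame["time"] <= 0).any():
        raise ValueError("survival model requires strictly positive times")
    cph = CoxPHFitter()  # Efron partial likelihood for ties
    try:
        cph.fit(frame, duration_col="time", event_col="event")
    except Exception as exc:
        raise ValueError(f"Cox model could not be fit: {exc}") from exc
    return ModelFit(outcome,
                    _coef_table(cph.params_.to_numpy(),
                                cph.standard_errors_.to_numpy(),
                                list(cph.params_.index)),
                    n_used=len(frame), adjusters=adjusters)


def fit_stage_migration(cohort: pd.DataFrame,
                        adjusters: tuple = MIGRATION_ADJUSTERS) -> ModelFit:
    """Adjusted odds of declared node-positive disease per examined node.

    Logistic regression of node-positive (N1/N2) vs node-negative status
    on continuous ELN count plus the adjusters.  ``ratio("eln_count")``
    gives the per-node stage-migration OR.
    """
    y = (cohort["n_stage"] != "N0").to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both node-stage categories must be present")
    X = pd.concat([cohort["eln_count"].astype(float), _onehot(cohort, adjusters)], axis=1)
    return _fit_logistic(y, X, "node-positive-vs-negative", adjusters)


def fit_survival_model(cohort: pd.DataFrame, subset: str | None = None,
                       include_positive_count: bool = False,
                       adjusters: tuple = SURVIVAL_ADJUSTERS) -> ModelFit:
    """Adjusted hazard of death per examined node (Cox PH, Efron ties)."""
    sub = _subset_cohort(cohort, subset)
    cols = [sub["eln_count"].astype(float), _onehot(sub, adjusters)]
    if include_positive_count:
        cols.insert(1, sub["positive_count"].astype(float))
    frame = pd.concat(cols + [sub["time"].astype(float), sub["event"].astype(int)], axis=1)
    return _fit_cox(frame, "overall-survival", adjusters)


def _pool_levels(eln: np.ndarray, sparsity_floor: int,
                 terminal_percentile: float = 99.0):
    """Group raw ELN levels: terminal bin above the given percentile, then
    merge any group under the sparsity floor with its nearest neighbour.

    Returns (mapping raw level -> group id, group table with representative
    x = patient-weighted mean level and patient count).
    """
    levels, counts = np.unique(eln, return_counts=True)
    cap = np.percentile(eln, terminal_percentile)
    groups: list[dict] = []
    for lv, ct in zip(levels, counts):
        if groups and lv > cap and groups[-1]["members"][-1] > cap:
            g = groups[-1]
            g["members"].append(int(lv))
            g["count"] += int(ct)
            g["sum_x"] += int(lv) * int(ct)
        else:
            groups.append({"members": [int(lv)], "count": int(ct),
                           "sum_x": int(lv) * int(ct)})
    # nearest-neighbour pooling of sparse groups (tie -> lower neighbour)
    while len(groups) > 1:
        deficient = [i for i, g in enumerate(groups) if g["count"] < sparsity_floor]
        if not deficient:
            break
        i = min(deficient, key=lambda i: groups[i]["count"])
        rep = groups[i]["sum_x"] / groups[i]["count"]
        options = []
        if i > 0:
            options.append((abs(rep - groups[i - 1]["sum_x"] / groups[i - 1]["count"]), i - 1))
        if i < len(groups) - 1:
            options.append((abs(rep - groups[i + 1]["sum_x"] / groups[i + 1]["count"]), i + 1))
        _, j = min(options)
        lo, hi = sorted((i, j))
        groups[lo] = {
            "members": groups[lo]["members"] + groups[hi]["members"],
            "count": groups[lo]["count"] + groups[hi]["count"],
            "sum_x": groups[lo]["sum_x"] + groups[hi]["sum_x"],
        }
        del groups[hi]
    mapping = {}
    table = []
    for gid, g in enumerate(groups):
        x = g["sum_x"] / g["count"]
        for lv in g["members"]:
            mapping[lv] = gid
        table.append({"group": gid, "x": x, "n_patients": g["count"]})
    return mapping, pd.DataFrame(table).set_index("group")


def eln_effect_series(cohort: pd.DataFrame, outcome: str = "survival",
                      subset: str | None = None, sparsity_floor: int = 20,
                      terminal_percentile: float = 99.0,
                      include_positive_count: bool = False) -> EffectSeries:
    """Adjusted log OR/HR of each ELN count versus the smallest count.

    ELN enters the model as a categorical factor with the lowest retained
    level (normally one examined node) as reference; levels with fewer
    than ``sparsity_floor`` patients are pooled with their nearest
    neighbour and levels above the ``terminal_percentile`` ELN percentile
    form a terminal bin.  The reference entry has effect exactly 0.
    """
    if outcome not in ("survival", "stage-migration"):
        raise ValueError(f"outcome must be 'survival' or 'stage-migration', got {outcome!r}")
    sub = _subset_cohort(cohort, subset)
    eln = sub["eln_count"].to_numpy(dtype=int)
    mapping, group_table = _pool_levels(eln, sparsity_floor, terminal_percentile)
    if len(group_table) < 5:
        raise ValueError(
            f"only {len(group_table)} distinct ELN levels remain after pooling; "
            "at least 5 are needed to scan for a break")
    gid = np.array([mapping[v] for v in eln])
    ref = int(group_table.index[np.argmin(group_table["x"].to_numpy())])

    dummy_cols = {}
    for g in group_table.index:
        if g == ref:
            continue
        dummy_cols[f"eln_g{g}"] = (gid == g).astype(float)
    dummies = pd.DataFrame(dummy_cols, index=sub.index)

    if outcome == "stage-migration":
        adjusters = MIGRATION_ADJUSTERS
        y = (sub["n_stage"] != "N0").to_numpy(dtype=float)
        fit = _fit_logistic(y, pd.concat([dummies, _onehot(sub, adjusters)], axis=1),
                            "node-positive-vs-negative", adjusters)
    else:
        adjusters = SURVIVAL_ADJUSTERS
        cols = [dummies, _onehot(sub, adjusters)]
        if include_positive_count:
            cols.append(sub["positive_count"].astype(float))
        frame = pd.concat(cols + [sub["time"].astype(float), sub["event"].astype(int)], axis=1)
        fit = _fit_cox(frame, "overall-survival", adjusters)

    rows = []
    for g in group_table.index:
        if g == ref:
            est, se = 0.0, 0.0
        else:
            row = fit.coefficients.loc[f"eln_g{g}"]
            est, se = float(row["estimate"]), float(row["se"])
        rows.append({"x": float(group_table.loc[g, "x"]),
                     "estimate": est, "se": se,
                     "n_patients": int(group_table.loc[g, "n_patients"])})
    table = pd.DataFrame(rows).sort_values("x").reset_index(drop=True)
    pooling = {lv: float(group_table.loc[g, "x"]) for lv, g in mapping.items()}
    return EffectSeries(table=table, outcome=outcome, adjusters=adjusters,
                        pooling=pooling,
                        reference_x=float(group_table.loc[ref, "x"]))


def interaction_test(cohort: pd.DataFrame, grouping: dict | None = None,
                     outcome: str = "stage-migration",
                     subset: str | None = None) -> float:
    """Wald test of histology x ELN product terms.

    ``grouping`` maps each histology label to a group (default: each
    histology its own group); the test asks whether the per-node ELN
    effect differs across those groups, in the logistic stage-migration
    model or the Cox survival model.
    """
    sub = _subset_cohort(cohort, subset)
    if grouping is None:
        grouping = {h: h for h in sub["histology"].unique()}
    group = sub["histology"].map(grouping)
    if group.isna().any():
        missing = sorted(sub.loc[group.isna(), "histology"].unique())
        raise ValueError(f"grouping does not cover histology label(s) {missing}")
    counts = group.value_counts()
    if len(counts) < 2:
        raise ValueError("interaction test needs at least 2 histology groups; "
                         f"got {list(counts.index)}")
    outcome_flag = ((sub["n_stage"] != "N0") if outcome == "stage-migration"
                    else sub["event"].astype(bool))
    for g in counts.index:
        if outcome_flag[group == g].sum() == 0:
            raise ValueError(f"histology group {g!r} has no "
                             f"{'cases' if outcome == 'stage-migration' else 'events'}")

    ref = counts.index[0]
    eln = sub["eln_count"].astype(float)
    cols = {"eln_count": eln}
    inter_names = []
    for g in sorted(c for c in counts.index if c != ref):
        ind = (group == g).astype(float)
        cols[f"grp[{g}]"] = ind
        cols[f"eln:grp[{g}]"] = ind * eln
        inter_names.append(f"eln:grp[{g}]")
    adjusters = tuple(a for a in (MIGRATION_ADJUSTERS if outcome == "stage-migration"
                                  else SURVIVAL_ADJUSTERS) if a != "histology")
    X = pd.concat([pd.DataFrame(cols, index=sub.index), _onehot(sub, adjusters)], axis=1)

    if outcome == "stage-migration":
        y = (sub["n_stage"] != "N0").to_numpy(dtype=float)
        design = sm.add_constant(X, has_constant="add")
        res = sm.GLM(y, design, family=sm.families.Binomial()).fit()
        idx = [design.columns.get_loc(nm) for nm in inter_names]
        contrast = np.eye(len(design.columns))[idx]
        return float(res.wald_test(contrast, scalar=True).pvalue)
    frame = pd.concat([X, sub["time"].astype(float), sub["event"].astype(int)], axis=1)
    cph = CoxPHFitter()
    cph.fit(frame, duration_col="time", event_col="event")
    beta = cph.params_.loc[inter_names].to_numpy()
    cov = cph.variance_matrix_.loc[inter_names, inter_names].to_numpy()
    w = float(beta @ np.linalg.solve(cov, beta))
    return float(stats.chi2.sf(w, len(inter_names)))


def mean_positive_series(cohort: pd.DataFrame, sparsity_floor: int = 1,
                         terminal_percentile: float = 100.0) -> pd.DataFrame:
    """Mean positive-node count at each (pooled) ELN level."""
    eln = cohort["eln_count"].to_numpy(dtype=int)
    mapping, group_table = _pool_levels(eln, sparsity_floor, terminal_percentile)
    gid = pd.Series([mapping[v] for v in eln], index=cohort.index)
    means = cohort.groupby(gid)["positive_count"].mean()
    out = pd.DataFrame({
        "x": group_table["x"],
        "mean_positive": means,
        "n_patients": group_table["n_patients"],
    }).sort_values("x").reset_index(drop=True)
    return out


def positive_vs_examined_regression(cohort: pd.DataFrame,
                                    subset: str | None = None,
                                    sparsity_floor: int = 20,
                                    terminal_percentile: float = 99.0) -> tuple[float, float]:
    """OLS slope and R-squared of mean positive nodes on ELN count.

    Fit on the per-ELN-level means (one point per retained examined-node
    count, sparse levels pooled as in the effect series).  A constant
    series has no explainable variance; its R-squared is reported as NaN.
    """
    sub = _subset_cohort(cohort, subset)
    series = mean_positive_series(sub, sparsity_floor=sparsity_floor,
                                  terminal_percentile=terminal_percentile)
    if len(series) < 5:
        raise ValueError(f"need >= 5 distinct ELN counts, got {len(series)}")
    x = series["x"].to_numpy()
    y = series["mean_positive"].to_numpy()
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    slope = float(res.params[1])
    if np.var(y) == 0:
        return slope, float("nan")
    return slope, float(res.rsquared)
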