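"""Crossed random-intercept mixed models for the three outcome families.

Each Results-style analysis is a linear mixed model with two crossed random
intercepts (subject and video for agreement/recall; subject and trial for
anxiety) and either a diagnostic-group or a mean-centred symptom-severity
fixed-effect structure, fitted by REML with Wald z tests.  Implemented on
statsmodels MixedLM using variance components over one all-encompassing
group, the standard encoding of crossed (non-nested) factors.

Coding conventions: treatment coding with CONTROL and POSITIVE as reference
levels, so the Group coefficient is the PTSD - Control contrast at the
reference condition and likewise for Condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = ["ModelFit", "fit_crossed_mixed", "run_group_model", "run_severity_model",
           "OUTCOME_COLUMNS"]

#: outcome name -> (value column, crossed random factors)
OUTCOME_COLUMNS: dict[str, tuple[str, tuple[str, str]]] = {
    "anxiety": ("rating", ("subject_id", "trial_index")),
    "agreement": ("scaled", ("subject_id", "video_id")),
    "recall": ("proportion", ("subject_id", "video_id")),
}


@dataclass
class ModelFit:
    """Fixed-effect table and variance components of one fitted model."""

    outcome: str
    fixed_effects: dict[str, dict[str, float]]  # name -> estimate/se/z/p
    variance_components: dict[str, float]
    residual_variance: float
    n_obs: int
    converged: bool
    fit_method: str = "REML, Wald z"
    reference_levels: dict[str, str] = field(
        default_factory=lambda: {"group": "CONTROL", "condition": "POSITIVE"}
    )

    def coef(self, name: str) -> float:
        return self.fixed_effects[name]["estimate"]

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "fixed_effects": self.fixed_effects,
            "variance_components": self.variance_components,
            "residual_variance": self.residual_variance,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "fit_method": self.fit_method,
            "reference_levels": self.reference_levels,
        }


def fit_crossed_mixed(
    data: pd.DataFrame,
    outcome: str,
    fixed_terms: list[str],
    random_factors: list[str],
    reml: bool = True,
) -> ModelFit:
    """Fit a linear mixed model with independent crossed random intercepts.

    ``fixed_terms`` are patsy terms (already-coded numeric columns or
    interactions such as ``"group_ptsd:cond_traumatic"``); each factor in
    ``random_factors`` contributes an independent random intercept.  Rows
    with a missing outcome are dropped listwise.  Non-convergence never
    raises: the fit is returned with ``converged=False`` and a warning.
    """
    cols = [outcome] + sorted(
        {c for t in fixed_terms for c in t.split(":")} | set(random_factors)
    )
    df = data[cols].dropna(subset=[outcome]).reset_index(drop=True)
    if not len(df):
        raise ValueError("no non-missing rows for outcome " + outcome)
    for f in random_factors:
        if df[f].nunique() < 2:
            raise ValueError(f"random factor {f!r} needs at least 2 levels")
    formula = f"{outcome} ~ " + " + ".join(fixed_terms) if fixed_terms else f"{outcome} ~ 1"
    vc = {f: f"0 + C({f})" for f in random_factors}
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, df, groups=np.ones(len(df)), vc_formula=vc)
        try:
            result = model.fit(reml=reml, method="lbfgs")
        except np.linalg.LinAlgError:
            result = model.fit(reml=reml, method="powell")
        conv_msgs = [w for w in caught if issubclass(w.category, ConvergenceWarning)]
    if conv_msgs and not getattr(result, "converged", True):
        converged = False
        warnings.warn(
            f"mixed model for {outcome!r} did not converge; estimates are flagged",
            stacklevel=2,
        )

    fe: dict[str, dict[str, float]] = {}
    for name in result.fe_params.index:
        fe[name] = dict(
            estimate=float(result.fe_params[name]),
            se=float(result.bse_fe[name]),
            z=float(result.fe_params[name] / result.bse_fe[name]),
            p=float(result.pvalues[name]),
        )
    # statsmodels orders variance components by exog_vc.names, not by the
    # vc_formula dict insertion order
    vcomp = {
        name: float(v) for name, v in zip(model.exog_vc.names, result.vcomp)
    }
    return ModelFit(
        outcome=outcome,
        fixed_effects=fe,
        variance_components=vcomp,
        residual_variance=float(result.scale),
        n_obs=len(df),
        converged=converged,
        fit_method=("REML" if reml else "ML") + ", Wald z",
    )


def _coded(data: pd.DataFrame) -> pd.DataFrame:
    df = data.copy()
    df["group_ptsd"] = (df["group"] == "PTSD").astype(float)
    df["cond_traumatic"] = (df["condition"] == "TRAUMATIC").astype(float)
    return df


def _resolve(data: pd.DataFrame, outcome: str, required: set[str],
             session_average: bool) -> tuple[pd.DataFrame, str, list[str]]:
    if outcome not in OUTCOME_COLUMNS:
        raise ValueError(f"unknown outcome {outcome!r}; expected {sorted(OUTCOME_COLUMNS)}")
    value_col, factors = OUTCOME_COLUMNS[outcome]
    missing = {value_col, *required, "condition", *factors} - set(data.columns)
    if missing:
        raise ValueError(f"analysis table missing columns: {sorted(missing)}")
    if session_average:
        if outcome != "anxiety":
            raise ValueError("session_average applies to the anxiety outcome only")
        keys = ["subject_id", "condition", *sorted(required - {"condition"})]
        data = data.groupby(keys, as_index=False)[value_col].mean()
        return data, value_col, ["subject_id"]
    return data, value_col, list(factors)


def run_group_model(
    data: pd.DataFrame, outcome: str, session_average: bool = False
) -> ModelFit:
    """Group (PTSD vs Control) x Narrative (Traumatic vs Positive) model.

    ``data`` is the merged analysis table for one outcome family: it must
    carry ``group``, ``condition``, the outcome value column, and the
    outcome's two crossed grouping factors (see ``OUTCOME_COLUMNS``).  For
    anxiety, ``session_average=True`` collapses the 11 trial ratings to one
    mean per subject-session and drops the trial random intercept.
    """
    data, value_col, factors = _resolve(data, outcome, {"group"}, session_average)
    df = _coded(data)
    return fit_crossed_mixed(
        df,
        value_col,
        ["group_ptsd", "cond_traumatic", "group_ptsd:cond_traumatic"],
        factors,
    )


def run_severity_model(
    data: pd.DataFrame, outcome: str, session_average: bool = False
) -> ModelFit:
    """Symptom-severity (mean-centred PCL) x Narrative model.

    PCL totals are centred on the mean of the full analysis table before the
    interaction is formed, so the Condition coefficient refers to a subject
    of average severity.
    """
    data, value_col, factors = _resolve(data, outcome, {"pcl_total"}, session_average)
    df = data.copy()
    if float(np.var(df["pcl_total"])) == 0.0:
        raise ValueError("symptom severity has zero variance; severity model undefined")
    df["severity_c"] = df["pcl_total"] - df["pcl_total"].mean()
    df["cond_traumatic"] = (df["condition"] == "TRAUMATIC").astype(float)
    fit = fit_crossed_mixed(
        df,
        value_col,
        ["severity_c", "cond_traumatic", "severity_c:cond_traumatic"],
        factors,
    )
    fit.reference_levels = {"severity": "mean-centred PCL", "condition": "POSITIVE"}
    return fit
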