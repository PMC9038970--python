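"""Causal mediation: does segmentation agreement carry the memory deficit?

Per-subject mean agreement (mediator M) and mean recall (outcome Y) are
regressed on the predictor X (diagnostic group or mean-centred symptom
severity):

    M = a0 + a X + e_M          (mediator model)
    Y = c0 + c' X + b M + e_Y   (outcome model)

The quasi-Bayesian (Imai-style) decomposition draws parameter vectors from
each fit's asymptotic normal approximation; per draw the average causal
mediation effect is ACME = a*b, the average direct effect is ADE = c', and
the total effect is their sum, making ACME + ADE = total an exact identity
draw by draw.  Effect point estimates are draw
means, intervals are percentiles, p-values are two-sided Monte-Carlo tail
proportions; the proportion mediated is the per-draw ratio's median.  A nonparametric
bootstrap over subjects is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SubjectSummary",
    "Effect",
    "MediationResult",
    "aggregate_per_subject",
    "estimate_mediation",
    "proportion_mediated",
]

#: winsorisation bounds for the per-draw ACME/total ratio kept in metadata
_RATIO_CLIP = (-2.0, 3.0)


@dataclass
class SubjectSummary:
    subject_id: str
    group: str
    pcl_total: int
    mean_agreement: float
    mean_recall: float


@dataclass
class Effect:
    estimate: float
    ci_low: float
    ci_high: float
    p: float

    def to_dict(self) -> dict[str, float]:
        return dict(estimate=self.estimate, ci_low=self.ci_low,
                    ci_high=self.ci_high, p=self.p)


@dataclass
class MediationResult:
    predictor: str  # "GROUP" | "SEVERITY"
    acme: Effect
    ade: Effect
    total: Effect
    prop_mediated: float          # draw-median ratio, truncated to [0, 1]
    prop_mediated_raw: float      # winsorised mean of per-draw ratios
    prop_mediated_unstable: bool
    paths: dict[str, float]       # a, b, c_prime point estimates (OLS)
    r_squared_outcome: float
    n_subjects: int
    n_draws: int
    seed: int
    method: str = "quasi-bayesian"

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "acme": self.acme.to_dict(),
            "ade": self.ade.to_dict(),
            "total": self.total.to_dict(),
            "prop_mediated": self.prop_mediated,
            "prop_mediated_raw": self.prop_mediated_raw,
            "prop_mediated_unstable": self.prop_mediated_unstable,
            "paths": self.paths,
            "r_squared_outcome": self.r_squared_outcome,
            "n_subjects": self.n_subjects,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "method": self.method,
        }


def aggregate_per_subject(
    agreement: pd.DataFrame,
    recall_scores: pd.DataFrame,
    subjects: pd.DataFrame,
) -> pd.DataFrame:
    """One row per subject: mean scaled agreement and mean recall proportion.

    Means are unweighted over all non-missing videos, pooling both narrative
    conditions.  Subjects with no valid agreement score on any video are
    excluded with a warning.
    """
    agr = (
        agreement.dropna(subset=["scaled"])
        .groupby("subject_id")["scaled"]
        .mean()
        .rename("mean_agreement")
    )
    rec = (
        recall_scores.groupby("subject_id")["proportion"].mean().rename("mean_recall")
    )
    out = (
        subjects[["subject_id", "group", "pcl_total"]]
        .merge(agr, on="subject_id", how="left")
        .merge(rec, on="subject_id", how="left")
    )
    n_drop = int(out["mean_agreement"].isna().sum() + out["mean_recall"].isna().sum())
    if n_drop:
        warnings.warn(
            f"excluding {n_drop} subject(s) with no valid agreement/recall scores",
            stacklevel=2,
        )
        out = out.dropna(subset=["mean_agreement", "mean_recall"])
    return out.reset_index(drop=True)


def _mc_p(draws: np.ndarray) -> float:
    """Two-sided Monte-Carlo p-value of the draw distribution against 0."""
    p = 2.0 * min(np.mean(draws <= 0.0), np.mean(draws >= 0.0))
    return float(min(1.0, max(p, 1.0 / len(draws))))


def _effect(draws: np.ndarray) -> Effect:
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return Effect(float(draws.mean()), float(lo), float(hi), _mc_p(draws))


def estimate_mediation(
    summaries: pd.DataFrame,
    predictor: str,
    n_draws: int = 1000,
    seed: int = 0,
    bootstrap: bool = False,
) -> MediationResult:
    """Decompose the predictor's effect on recall into indirect and direct.

    Parameters
    ----------
    summaries
        Per-subject table from :func:`aggregate_per_subject`.
    predictor
        "GROUP" (PTSD=1 vs CONTROL=0) or "SEVERITY" (mean-centred PCL).
    n_draws
        Monte-Carlo draws from the fits' asymptotic normal approximation
        (or bootstrap resamples when ``bootstrap=True``).
    seed
        Mandatory RNG seed; results are bit-reproducible given it.
    """
    predictor = predictor.upper()
    if predictor not in {"GROUP", "SEVERITY"}:
        raise ValueError("predictor must be 'GROUP' or 'SEVERITY'")
    if len(summaries) < 20:
        raise ValueError("mediation requires at least 20 subjects")
    if predictor == "GROUP":
        x = (summaries["group"] == "PTSD").to_numpy(float)
    else:
        pcl = summaries["pcl_total"].to_numpy(float)
        x = pcl - pcl.mean()
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant; mediation undefined")
    m = summaries["mean_agreement"].to_numpy(float)
    y = summaries["mean_recall"].to_numpy(float)
    rng = np.random.default_rng(seed)

    med_fit = sm.OLS(m, sm.add_constant(x)).fit()
    out_fit = sm.OLS(y, sm.add_constant(np.column_stack([x, m]))).fit()

    if bootstrap:
        n = len(x)
        a_d = np.empty(n_draws)
        b_d = np.empty(n_draws)
        c_d = np.empty(n_draws)
        for i in range(n_draws):
            idx = rng.integers(0, n, n)
            mf = sm.OLS(m[idx], sm.add_constant(x[idx])).fit()
            of = sm.OLS(y[idx], sm.add_constant(np.column_stack([x[idx], m[idx]]))).fit()
            a_d[i], b_d[i], c_d[i] = mf.params[1], of.params[2], of.params[1]
        method = "bootstrap"
    else:
        med_draws = rng.multivariate_normal(med_fit.params, med_fit.cov_params(), n_draws)
        out_draws = rng.multivariate_normal(out_fit.params, out_fit.cov_params(), n_draws)
        a_d = med_draws[:, 1]
        b_d = out_draws[:, 2]
        c_d = out_draws[:, 1]
        method = "quasi-bayesian"

    acme_d = a_d * b_d
    total_d = acme_d + c_d

    # proportion mediated: per-draw ratio acme/total; draws whose total sits
    # near zero produce exploding ratios, so the point estimate is the draw
    # median (robust to those tails); the winsorised mean is kept in metadata
    # and the headline number is truncated to [0, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(total_d != 0.0, acme_d / total_d, np.nan)
    ratios = ratios[np.isfinite(ratios)]
    prop_point = float(np.median(ratios)) if ratios.size else float("nan")
    prop_raw = (
        float(np.clip(ratios, *_RATIO_CLIP).mean()) if ratios.size else float("nan")
    )
    total_eff = _effect(total_d)
    unstable = total_eff.ci_low <= 0.0 <= total_eff.ci_high
    if unstable:
        warnings.warn(
            "total effect indistinguishable from 0: proportion mediated is unstable",
            stacklevel=2,
        )

    return MediationResult(
        predictor=predictor,
        acme=_effect(acme_d),
        ade=_effect(c_d),
        total=total_eff,
        prop_mediated=float(min(1.0, max(0.0, prop_point))),
        prop_mediated_raw=prop_raw,
        prop_mediated_unstable=bool(unstable),
        paths=dict(
            a=float(med_fit.params[1]),
            b=float(out_fit.params[2]),
            c_prime=float(out_fit.params[1]),
        ),
        r_squared_outcome=float(out_fit.rsquared),
        n_subjects=len(summaries),
        n_draws=n_draws,
        seed=seed,
        method=method,
    )


def proportion_mediated(result: MediationResult) -> float:
    """Headline proportion mediated as a percentage of the total effect."""
    if result.prop_mediated_unstable:
        warnings.warn("proportion mediated flagged unstable", stacklevel=2)
    return 100.0 * result.prop_mediated
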