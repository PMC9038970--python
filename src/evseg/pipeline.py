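"""End-to-end orchestration: generate (or ingest), score, model, mediate.

``run_pipeline`` executes the full analysis chain in the order the study
reports it — anxiety manipulation check, segmentation agreement, free
recall, mediation — writing every intermediate artifact (CSV/JSON) plus a
structured report.  Deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GeneratorConfig, load_config
from .mediation import MediationResult, aggregate_per_subject, estimate_mediation
from .models import ModelFit, run_group_model, run_severity_model
from .recall_scoring import score_recall_table
from .segmentation import score_cohort
from .synthetic_cohort import CohortData, generate_cohort

__all__ = ["ReportBundle", "run_pipeline", "load_tables"]

logger = logging.getLogger("evseg")


@dataclass
class ReportBundle:
    config: dict
    seed: int
    descriptives: dict
    model_fits: dict[str, ModelFit]
    mediations: dict[str, MediationResult]
    exclusions: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "descriptives": self.descriptives,
            "model_fits": {k: v.to_dict() for k, v in self.model_fits.items()},
            "mediations": {k: v.to_dict() for k, v in self.mediations.items()},
            "exclusions": self.exclusions,
        }

    def to_markdown(self) -> str:
        d = self.descriptives
        lines = [
            "# Event segmentation & memory pipeline report",
            "",
            f"Seed: {self.seed}",
            "",
            "## Descriptives",
            f"- Boundaries per video: mean {d['presses']['mean']:.2f} "
            f"(range {d['presses']['min']:.0f}-{d['presses']['max']:.0f}, "
            f"SD {d['presses']['sd']:.2f})",
            f"- Anxiety by group: PTSD {d['anxiety']['group_means']['PTSD']:.2f}, "
            f"Control {d['anxiety']['group_means']['CONTROL']:.2f}",
            f"- Agreement by group: PTSD {d['agreement']['group_means']['PTSD']:.2f}, "
            f"Control {d['agreement']['group_means']['CONTROL']:.2f}",
            f"- Recall by group: PTSD {d['recall']['group_means']['PTSD']:.2f}, "
            f"Control {d['recall']['group_means']['CONTROL']:.2f}",
            "",
            "## Mixed models (fixed effects, REML, Wald z)",
        ]
        for name, fit in self.model_fits.items():
            lines.append(f"### {name}")
            for term, stats in fit.fixed_effects.items():
                lines.append(
                    f"- {term}: B = {stats['estimate']:.4f} "
                    f"(SE {stats['se']:.4f}, p = {stats['p']:.3g})"
                )
        lines.append("")
        lines.append("## Mediation (quasi-Bayesian decomposition)")
        for name, med in self.mediations.items():
            lines.append(
                f"- {name}: ACME = {med.acme.estimate:.4f} "
                f"[{med.acme.ci_low:.4f}, {med.acme.ci_high:.4f}], "
                f"ADE = {med.ade.estimate:.4f}, total = {med.total.estimate:.4f}, "
                f"proportion mediated = {100 * med.prop_mediated:.0f}%, "
                f"outcome R^2 = {med.r_squared_outcome:.2f}"
            )
        return "\n".join(lines) + "\n"


def load_tables(data_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read previously written cohort tables from a directory of CSVs."""
    data_dir = Path(data_dir)
    tables = {}
    for name in ("subjects", "press_log", "recall", "anxiety"):
        path = data_dir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing input table: {path}")
        tables[name] = pd.read_csv(path)
    return tables


def _descriptives(
    press_counts: pd.Series,
    anxiety: pd.DataFrame,
    agreement: pd.DataFrame,
    recall_scores: pd.DataFrame,
    subjects: pd.DataFrame,
) -> dict:
    grp = subjects.set_index("subject_id")["group"]

    def group_means(df: pd.DataFrame, col: str) -> dict[str, float]:
        g = df.assign(group=df["subject_id"].map(grp)).groupby("group")[col].mean()
        return {k: float(v) for k, v in g.items()}

    def cond_means(df: pd.DataFrame, col: str) -> dict[str, float]:
        g = df.groupby("condition")[col].mean()
        return {k: float(v) for k, v in g.items()}

    return {
        "presses": {
            "mean": float(press_counts.mean()),
            "sd": float(press_counts.std()),
            "min": float(press_counts.min()),
            "max": float(press_counts.max()),
        },
        "anxiety": {
            "group_means": group_means(anxiety, "rating"),
            "condition_means": cond_means(anxiety, "rating"),
        },
        "agreement": {
            "group_means": group_means(agreement.dropna(subset=["scaled"]), "scaled"),
            "condition_means": cond_means(agreement.dropna(subset=["scaled"]), "scaled"),
        },
        "recall": {
            "group_means": group_means(recall_scores, "proportion"),
            "condition_means": cond_means(recall_scores, "proportion"),
        },
    }


def run_pipeline(
    config: GeneratorConfig | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
    data_dir: str | Path | None = None,
    n_draws: int = 1000,
) -> ReportBundle:
    """Run the full chain and write artifacts + report under ``out_dir``.

    With ``data_dir`` given, tables are ingested from CSVs in the documented
    schema instead of being generated (``config`` still supplies video
    durations).  ``seed`` overrides the config seed for generation and
    seeds the mediation draws.
    """
    if not isinstance(config, GeneratorConfig):
        config = load_config(config)
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    durations: dict[str, float] = {v.video_id: float(v.duration_s) for v in config.videos}

    if data_dir is None:
        logger.info("stage generate: seed=%d, n=%d+%d subjects",
                    config.seed, config.n_ptsd, config.n_control)
        cohort = generate_cohort(config, score=True)
        cohort.write(out)
        subjects, press_log = cohort.subjects, cohort.press_log
        agreement, norms = cohort.agreement, cohort.norms
        recall, anxiety = cohort.recall, cohort.anxiety
        roster = cohort.roster
    else:
        logger.info("stage ingest: reading tables from %s", data_dir)
        tables = load_tables(data_dir)
        subjects, press_log = tables["subjects"], tables["press_log"]
        recall, anxiety = tables["recall"], tables["anxiety"]
        roster = press_log[["subject_id", "video_id", "condition"]].drop_duplicates()
        agreement, norms = score_cohort(press_log, durations, roster=roster)

    agreement.to_csv(out / "agreement.csv", index=False)
    norms.to_csv(out / "norms.csv", index=False)
    recall_scores = score_recall_table(recall)
    recall_scores.to_csv(out / "recall_scores.csv", index=False)

    n_degenerate = int(agreement["scaled"].isna().sum())
    logger.info("stage agreement: %d viewings, %d degenerate", len(agreement), n_degenerate)

    press_counts = (
        press_log.groupby(["subject_id", "video_id"]).size().astype(float)
    )
    # zero-press viewings still count as observations of 0 presses
    n_zero = len(roster) - len(press_counts)
    if n_zero > 0:
        press_counts = pd.concat(
            [press_counts, pd.Series(np.zeros(n_zero))], ignore_index=True
        )

    subj_cols = subjects[["subject_id", "group", "pcl_total"]]
    anx_table = anxiety.merge(subj_cols, on="subject_id")
    agr_table = agreement.merge(subj_cols, on="subject_id")
    rec_table = recall_scores.merge(subj_cols, on="subject_id")

    logger.info("stage fit: six crossed mixed models")
    fits: dict[str, ModelFit] = {}
    for outcome, table in (
        ("anxiety", anx_table),
        ("agreement", agr_table),
        ("recall", rec_table),
    ):
        fits[f"{outcome}_group"] = run_group_model(table, outcome)
        fits[f"{outcome}_severity"] = run_severity_model(table, outcome)
    (out / "model_fits.json").write_text(
        json.dumps({k: f.to_dict() for k, f in fits.items()}, indent=1)
    )

    logger.info("stage mediate: group and severity decompositions")
    summaries = aggregate_per_subject(agreement, recall_scores, subjects)
    med_seed = config.seed if seed is None else int(seed)
    mediations = {
        "group": estimate_mediation(summaries, "GROUP", n_draws=n_draws, seed=med_seed),
        "severity": estimate_mediation(
            summaries, "SEVERITY", n_draws=n_draws, seed=med_seed + 1
        ),
    }
    (out / "mediation.json").write_text(
        json.dumps({k: m.to_dict() for k, m in mediations.items()}, indent=1)
    )

    report = ReportBundle(
        config={"n_ptsd": config.n_ptsd, "n_control": config.n_control,
                "seed": config.seed,
                "videos": {v.video_id: v.duration_s for v in config.videos}},
        seed=config.seed,
        descriptives=_descriptives(press_counts, anxiety, agreement, recall_scores, subjects),
        model_fits=fits,
        mediations=mediations,
        exclusions={
            "degenerate_agreement_scores": n_degenerate,
            "subjects_excluded_from_mediation": int(len(subjects) - len(summaries)),
        },
    )
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
    (out / "report.md").write_text(report.to_markdown())
    return report
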