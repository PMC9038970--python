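"""Free-recall scoring: A1-unit proportions and interrater reliability.

Recall is scored as the proportion of low-level action units (A1 units in
the action-coding-system hierarchy) that a participant reproduced for a
video.  Cohen's kappa is provided to validate binary unit codings between
two raters the same way human coders are validated before production
scoring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic_cohort import RecallRecord

__all__ = ["proportion_recalled", "score_recall_table", "cohens_kappa"]


def proportion_recalled(record: RecallRecord) -> float:
    """Exact quotient n_recalled / n_units_total for one subject-video."""
    if record.n_units_total < 1:
        raise ValueError("n_units_total must be at least 1")
    if record.n_recalled > record.n_units_total:
        raise ValueError(
            f"n_recalled {record.n_recalled} exceeds n_units_total {record.n_units_total}"
        )
    return record.n_recalled / record.n_units_total


def score_recall_table(recall_df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised recall proportions for a tidy recall table.

    Expects columns subject_id, video_id, condition, n_units_total,
    n_recalled; returns the same rows with a ``proportion`` column.
    """
    if (recall_df["n_units_total"] < 1).any():
        raise ValueError("n_units_total must be at least 1 in every row")
    if (recall_df["n_recalled"] > recall_df["n_units_total"]).any():
        bad = recall_df.index[recall_df["n_recalled"] > recall_df["n_units_total"]][0]
        raise ValueError(f"n_recalled exceeds n_units_total at row {bad}")
    out = recall_df[["subject_id", "video_id", "condition"]].copy()
    out["proportion"] = recall_df["n_recalled"] / recall_df["n_units_total"]
    return out


def cohens_kappa(coder_a, coder_b) -> float:
    """Chance-corrected agreement between two binary coders.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed proportion of
    items on which the coders agree and p_e the agreement expected from
    their marginal rates.  Undefined (raises) when p_e = 1, i.e. both
    coders are constant with identical marginals.
    """
    a = np.asarray(coder_a, dtype=int)
    b = np.asarray(coder_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("coder vectors must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("kappa requires at least 2 items")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("coder decisions must be binary (0/1)")
    n = a.size
    p_o = float(np.mean(a == b))
    pa1, pb1 = a.mean(), b.mean()
    p_e = float(pa1 * pb1 + (1 - pa1) * (1 - pb1))
    if p_e == 1.0:
        raise ValueError(
            "kappa undefined: both coders constant with identical marginals (p_e = 1)"
        )
    return (p_o - p_e) / (1 - p_e)
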