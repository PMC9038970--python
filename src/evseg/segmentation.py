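"""Segmentation binning, sample norms, and agreement scoring.

Button presses are collapsed into one-second bins; the sample norm for a
video is the per-bin proportion of the reference group marking a boundary
there; a participant's agreement is the Pearson correlation between their
binary bin vector and the norm, min-max rescaled against the best and worst
correlations attainable with the same number of marked bins.  The rescaling
removes the mechanical dependence of the raw correlation on how many
boundaries a participant chose to report: a sparse and a prolific segmenter
who both place their marks as well as possible each score 1.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_cohort import Condition, PressLog

__all__ = [
    "BinnedSegmentation",
    "NormProfile",
    "AgreementScore",
    "bin_presses",
    "compute_norms",
    "score_agreement",
    "score_cohort",
]

logger = logging.getLogger("evseg")


@dataclass
class BinnedSegmentation:
    subject_id: str
    video_id: str
    condition: Condition
    indicator: np.ndarray  # binary, length ceil(duration / bin_width)

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator, dtype=np.int8)
        if not np.isin(self.indicator, (0, 1)).all():
            raise ValueError("indicator entries must be 0 or 1")

    @property
    def k(self) -> int:
        """Number of marked bins."""
        return int(self.indicator.sum())


@dataclass
class NormProfile:
    video_id: str
    proportions: np.ndarray  # per-bin proportion of reference group, in [0, 1]
    n_ref: int

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if np.any(self.proportions < 0) or np.any(self.proportions > 1):
            raise ValueError("norm proportions must lie in [0, 1]")


@dataclass
class AgreementScore:
    subject_id: str
    video_id: str
    condition: Condition
    raw_r: float
    scaled: float  # in [0, 1], or NaN when degenerate
    k: int


def bin_presses(
    press_log: PressLog, duration_s: float, bin_width: float = 1.0
) -> BinnedSegmentation:
    """Collapse press times into a binary per-bin indicator vector.

    Bin ``b`` covers the half-open interval [b*w, (b+1)*w); a press at
    exactly ``duration_s`` is clamped into the final bin.  A bin is marked
    if at least one press falls in it, so multiple presses in one bin count
    once.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    times = np.asarray(press_log.press_times_s, dtype=float)
    bad = np.flatnonzero((times < 0) | (times > duration_s))
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"press time {times[i]} (row {i}, subject {press_log.subject_id}, "
            f"video {press_log.video_id}) outside [0, {duration_s}]"
        )
    n_bins = math.ceil(duration_s / bin_width)
    indicator = np.zeros(n_bins, dtype=np.int8)
    if times.size:
        idx = np.minimum((times // bin_width).astype(int), n_bins - 1)
        indicator[idx] = 1
    return BinnedSegmentation(
        press_log.subject_id, press_log.video_id, press_log.condition, indicator
    )


def compute_norms(binned: Sequence[BinnedSegmentation]) -> NormProfile:
    """Per-bin proportion of the reference group marking a boundary.

    The reference group is whoever is passed in — by default the whole
    sample for that video, including the participant being scored.
    """
    if len(binned) < 2:
        raise ValueError("norms require at least 2 participants")
    video_ids = {b.video_id for b in binned}
    if len(video_ids) != 1:
        raise ValueError(f"norms must be computed within one video, got {video_ids}")
    lengths = {len(b.indicator) for b in binned}
    if len(lengths) != 1:
        raise ValueError(f"indicator length mismatch within video: {lengths}")
    mat = np.stack([b.indicator for b in binned]).astype(float)
    return NormProfile(binned[0].video_id, mat.mean(axis=0), n_ref=len(binned))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        return math.nan
    return float(xc @ yc) / denom


def _extreme_r(norms: np.ndarray, k: int, best: bool) -> float:
    """Correlation of the best (or worst) k-bin indicator with the norms.

    For fixed k the Pearson correlation is increasing in the sum of norm
    values over the marked bins, so the optimum marks the k highest-norm
    bins (ties broken toward the lowest bin index via a stable sort).
    """
    order = np.argsort(-norms if best else norms, kind="stable")
    v = np.zeros(norms.shape[0], dtype=float)
    v[order[:k]] = 1.0
    return _pearson(v, norms)


def score_agreement(binned: BinnedSegmentation, norms: NormProfile) -> AgreementScore:
    """Raw and rescaled agreement of one participant with the sample norm.

    ``raw_r`` is the Pearson correlation of the binary indicator with the
    norm profile; ``scaled`` min-max rescales it between the worst and best
    correlations attainable by any vector with the same number of marked
    bins, clamped to [0, 1] against floating-point spill.  Degenerate cases
    (no presses, every bin marked, or a constant norm profile) yield NaN.
    """
    if binned.video_id != norms.video_id:
        raise ValueError(
            f"video mismatch: {binned.video_id!r} vs {norms.video_id!r}"
        )
    ind = binned.indicator.astype(float)
    prop = norms.proportions
    if ind.shape != prop.shape:
        raise ValueError(
            f"length mismatch: indicator {ind.shape[0]} vs norms {prop.shape[0]}"
        )
    k = binned.k
    n = ind.shape[0]
    raw_r = _pearson(ind, prop)
    if k == 0 or k == n or np.ptp(prop) == 0:
        warnings.warn(
            f"degenerate agreement for subject {binned.subject_id}, "
            f"video {binned.video_id} (k={k}): scaled score undefined",
            stacklevel=2,
        )
        return AgreementScore(
            binned.subject_id, binned.video_id, binned.condition,
            raw_r, math.nan, k,
        )
    r_max = _extreme_r(prop, k, best=True)
    r_min = _extreme_r(prop, k, best=False)
    if r_max == r_min:
        scaled = math.nan
    else:
        scaled = min(1.0, max(0.0, (raw_r - r_min) / (r_max - r_min)))
    return AgreementScore(
        binned.subject_id, binned.video_id, binned.condition, raw_r, scaled, k
    )


def score_cohort(
    press_df: pd.DataFrame,
    durations: Mapping[str, float],
    roster: pd.DataFrame | None = None,
    bin_width: float = 1.0,
    leave_one_out: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score segmentation agreement for every subject-video in a cohort.

    Parameters
    ----------
    press_df
        One row per press: columns subject_id, video_id, condition, time_s.
    durations
        video_id -> duration in seconds.
    roster
        One row per viewing (subject_id, video_id, condition).  Subjects who
        never pressed still segmented the video; without a roster they would
        be invisible in ``press_df``, so passing it is how zero-press
        viewings enter (and get NaN scores).  Defaults to the subject-video
        pairs present in ``press_df``.
    leave_one_out
        Exclude the scored participant from the norm (default: the whole
        sample, index participant included).

    Returns
    -------
    (agreement, norms)
        ``agreement`` has one row per viewing with raw_r, scaled and k;
        ``norms`` has one row per video-bin with the reference proportion.
    """
    if roster is None:
        roster = press_df[["subject_id", "video_id", "condition"]].drop_duplicates()
    presses = {
        key: grp["time_s"].to_numpy()
        for key, grp in press_df.groupby(["subject_id", "video_id"], sort=False)
    }
    agreement_rows: list[dict] = []
    norm_rows: list[dict] = []
    n_degenerate = 0
    for video_id, video_roster in roster.groupby("video_id", sort=False):
        dur = durations[video_id]
        binned = [
            bin_presses(
                PressLog(
                    row.subject_id,
                    video_id,
                    Condition(row.condition),
                    presses.get((row.subject_id, video_id), np.empty(0)),
                ),
                dur,
                bin_width,
            )
            for row in video_roster.itertuples()
        ]
        norms = compute_norms(binned)
        for bin_index, p in enumerate(norms.proportions):
            norm_rows.append(
                dict(video_id=video_id, bin_index=bin_index, proportion=float(p))
            )
        mat_sum = np.sum([b.indicator for b in binned], axis=0, dtype=float)
        for b in binned:
            if leave_one_out:
                loo = (mat_sum - b.indicator) / (norms.n_ref - 1)
                ref = NormProfile(video_id, loo, norms.n_ref - 1)
            else:
                ref = norms
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sc = score_agreement(b, ref)
            if math.isnan(sc.scaled):
                n_degenerate += 1
            agreement_rows.append(
                dict(
                    subject_id=sc.subject_id,
                    video_id=sc.video_id,
                    condition=sc.condition.value,
                    k=sc.k,
                    raw_r=sc.raw_r,
                    scaled=sc.scaled,
                )
            )
    if n_degenerate:
        logger.info("segmentation: %d degenerate (NaN) agreement scores", n_degenerate)
    return pd.DataFrame(agreement_rows), pd.DataFrame(norm_rows)
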