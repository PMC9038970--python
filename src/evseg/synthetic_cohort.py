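"""Synthetic clinical-cohort generator with known ground truth.

Emulates the four data streams of a two-group (PTSD / trauma-exposed control)
event-cognition study: segmentation button presses while watching everyday
videos, free-recall unit counts, trial-level anxiety ratings after
autobiographical narrative priming, and a subject table with PCL symptom
totals.  The generative chain realises an explicit X -> M -> Y mediation
structure:

  group / PCL severity  ->  latent segmentation ability  ->  press behaviour
  ->  measured segmentation agreement (M)  ->  recall probability (Y),

with an additional direct group -> recall path.  Defaults are calibrated so
that the large-sample expectations of the generated cohort reproduce the
target sample statistics (see config module and docs/methods.md).

Randomness: a single root seed; every subject / video / stream draws from its
own substream keyed by stable CRC32 hashes, so regenerating any subset of the
cohort is reproducible independent of iteration order.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import GeneratorConfig, PCL_MAX, PCL_MIN, VideoSpec

__all__ = [
    "Group",
    "Condition",
    "SubjectRecord",
    "VideoTruth",
    "PressLog",
    "RecallRecord",
    "AnxietyRecord",
    "CohortData",
    "generate_subjects",
    "generate_video_truth",
    "generate_press_log",
    "generate_recall",
    "generate_anxiety",
    "generate_cohort",
]


class Group(str, Enum):
    PTSD = "PTSD"
    CONTROL = "CONTROL"


class Condition(str, Enum):
    TRAUMATIC = "TRAUMATIC"
    POSITIVE = "POSITIVE"


@dataclass
class SubjectRecord:
    subject_id: str
    group: Group
    pcl_total: int
    ability: float
    session_order: str  # "trauma_first" | "positive_first"

    def __post_init__(self) -> None:
        if not (PCL_MIN <= self.pcl_total <= PCL_MAX):
            raise ValueError(f"pcl_total {self.pcl_total} outside [{PCL_MIN}, {PCL_MAX}]")
        if not (0.0 < self.ability < 1.0):
            raise ValueError(f"ability {self.ability} must lie strictly in (0, 1)")


@dataclass
class VideoTruth:
    video_id: str
    duration_s: int
    boundary_times: np.ndarray
    salience: np.ndarray

    def __post_init__(self) -> None:
        self.boundary_times = np.asarray(self.boundary_times, dtype=float)
        self.salience = np.asarray(self.salience, dtype=float)
        if len(self.boundary_times) != len(self.salience):
            raise ValueError("salience must align with boundary_times")
        if np.any(np.diff(self.boundary_times) <= 0):
            raise ValueError("boundary_times must be strictly increasing")
        if self.boundary_times.size and (
            self.boundary_times[0] < 0 or self.boundary_times[-1] >= self.duration_s
        ):
            raise ValueError("boundary_times must lie in [0, duration_s)")
        if np.any(self.salience <= 0) or np.any(self.salience > 1):
            raise ValueError("salience must lie in (0, 1]")


@dataclass
class PressLog:
    subject_id: str
    video_id: str
    condition: Condition
    press_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.press_times_s = np.asarray(self.press_times_s, dtype=float)


@dataclass
class RecallRecord:
    subject_id: str
    video_id: str
    condition: Condition
    n_units_total: int
    n_recalled: int

    def __post_init__(self) -> None:
        if self.n_units_total <= 0:
            raise ValueError("n_units_total must be positive")
        if not (0 <= self.n_recalled <= self.n_units_total):
            raise ValueError("n_recalled must lie in [0, n_units_total]")


@dataclass
class AnxietyRecord:
    subject_id: str
    condition: Condition
    trial_index: int  # 1..n_trials
    rating: float


# ---------------------------------------------------------------------------
# Seeding: stable named substreams off one root seed
# ---------------------------------------------------------------------------

def _substream(seed: int, *tags: object) -> np.random.Generator:
    """RNG for a named substream; stable across runs and iteration order."""
    words = [int(seed) & 0x7FFFFFFF]
    for t in tags:
        words.append(zlib.crc32(str(t).encode("utf-8")))
    return np.random.default_rng(np.random.SeedSequence(words))


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# Subjects
# ---------------------------------------------------------------------------

def _draw_pcl(rng: np.random.Generator, mu: float, sigma: float, n: int) -> np.ndarray:
    """Truncated-normal PCL totals rounded to integers in [17, 85]."""
    if sigma == 0:
        vals = np.full(n, mu)
    else:
        a, b = (PCL_MIN - mu) / sigma, (PCL_MAX - mu) / sigma
        if a >= b:
            raise ValueError("invalid PCL truncation bounds for given mu/sigma")
        vals = stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)
    return np.clip(np.rint(vals), PCL_MIN, PCL_MAX).astype(int)


def generate_subjects(config: GeneratorConfig) -> list[SubjectRecord]:
    """Draw the subject table: group labels, PCL totals, latent ability.

    PCL totals come from group-specific truncated normals (parameters
    pre-calibrated so sample mean/SD match the targets after truncation and
    rounding).  Ability is logistic(alpha0 + alpha_pcl * z(PCL) + u_i) with
    alpha_pcl < 0, standardised against fixed reference constants.  Session
    order (which narrative primes session 2) alternates deterministically.
    """
    ab = config.ability
    subjects: list[SubjectRecord] = []
    specs = [(Group.PTSD, config.n_ptsd, config.pcl_ptsd), (Group.CONTROL, config.n_control, config.pcl_control)]
    idx = 0
    for group, n, pcl_params in specs:
        rng = _substream(config.seed, "pcl", group.value)
        pcl = _draw_pcl(rng, pcl_params.mu, pcl_params.sigma, n)
        u = _substream(config.seed, "ability", group.value).normal(0.0, ab.subject_sd, n)
        z = (pcl - ab.pcl_ref_mean) / ab.pcl_ref_sd
        ability = _logistic(ab.alpha0 + ab.alpha_pcl * z + u)
        # keep ability strictly interior against floating-point saturation
        ability = np.clip(ability, 1e-9, 1 - 1e-9)
        for j in range(n):
            subjects.append(
                SubjectRecord(
                    subject_id=f"S{idx + 1:03d}",
                    group=group,
                    pcl_total=int(pcl[j]),
                    ability=float(ability[j]),
                    session_order="trauma_first" if idx % 2 == 0 else "positive_first",
                )
            )
            idx += 1
    return subjects


# ---------------------------------------------------------------------------
# Videos: latent boundary structure
# ---------------------------------------------------------------------------

def generate_video_truth(
    video_id: str, duration_s: int, config: GeneratorConfig, seed: int | None = None
) -> VideoTruth:
    """Place latent normative boundaries by a gamma renewal process.

    Inter-boundary gaps ~ Gamma(gap_shape, mean_gap_s / gap_shape); boundary
    salience ~ Beta(salience_a, salience_b).  An empty boundary list is
    permitted (e.g. mean gap exceeding the duration).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    bp = config.boundary
    rng = _substream(config.seed if seed is None else seed, "truth", video_id)
    times = []
    t = float(rng.gamma(bp.gap_shape, bp.mean_gap_s / bp.gap_shape))
    while t < duration_s:
        times.append(t)
        t += rng.gamma(bp.gap_shape, bp.mean_gap_s / bp.gap_shape)
    times_arr = np.asarray(times, dtype=float)
    salience = rng.beta(bp.salience_a, bp.salience_b, size=len(times_arr))
    salience = np.clip(salience, 1e-12, 1.0)
    return VideoTruth(video_id, duration_s, times_arr, salience)


# ---------------------------------------------------------------------------
# Press logs
# ---------------------------------------------------------------------------

def generate_press_log(
    subject: SubjectRecord,
    truth: VideoTruth,
    condition: Condition,
    config: GeneratorConfig,
    seed: int | None = None,
) -> PressLog:
    """Simulate one subject's button presses for one video.

    Each latent boundary is detected with probability
    ``clip(base + slope*ability + cond_offset, 0, 1) ** (1/salience)`` —
    increasing in ability and in salience; detected boundaries are pressed
    with Gaussian timing jitter (truncated to the video).  False alarms form
    a homogeneous Poisson process with rate false_alarm_rate*(1-ability).
    """
    pp = config.press
    rng = _substream(
        config.seed if seed is None else seed, "press", subject.subject_id, truth.video_id
    )
    dur = float(truth.duration_s)
    eff = pp.base_hit_rate + pp.ability_hit_slope * subject.ability
    if condition is Condition.TRAUMATIC:
        eff += pp.condition_hit_offset
    eff = float(np.clip(eff, 0.0, 1.0))
    hit_prob = eff ** (1.0 / truth.salience) if truth.salience.size else np.empty(0)
    hits = rng.random(len(truth.boundary_times)) < hit_prob
    hit_times = truth.boundary_times[hits]
    if pp.jitter_sd_s > 0 and hit_times.size:
        hit_times = hit_times + rng.normal(0.0, pp.jitter_sd_s, hit_times.size)
    hit_times = np.clip(hit_times, 0.0, dur)

    fa_rate = pp.false_alarm_rate * (1.0 - subject.ability)
    n_fa = rng.poisson(fa_rate * dur)
    fa_times = rng.uniform(0.0, dur, n_fa)

    press = np.sort(np.concatenate([hit_times, fa_times]))
    return PressLog(subject.subject_id, truth.video_id, condition, press)


# ---------------------------------------------------------------------------
# Recall
# ---------------------------------------------------------------------------

def generate_recall(
    subject: SubjectRecord,
    scaled_agreement: float,
    video_id: str,
    condition: Condition,
    config: GeneratorConfig,
    seed: int | None = None,
) -> RecallRecord:
    """Draw the number of A1 action units recalled for one subject-video.

    Units are recalled independently with probability
    logistic(b0 + b_a*agreement + b_g*1[PTSD] + b_s*z(PCL) + b_c*1[TRAUMATIC]
    + e_i), where e_i is a per-subject encoding offset (one draw per
    subject) and z(PCL) uses the ability model's reference constants.  The
    agreement argument is the *measured* scaled agreement, which is what
    makes segmentation a genuine mediator of the group -> recall path.
    """
    rp = config.recall
    if rp.n_units_total <= 0:
        raise ValueError("n_units_total must be positive")
    root = config.seed if seed is None else seed
    e_i = float(
        _substream(root, "recall-subject", subject.subject_id).normal(0.0, rp.subject_noise_sd)
    )
    if not np.isfinite(scaled_agreement):
        # degenerate agreement (e.g. zero presses): fall back to the neutral midpoint
        scaled_agreement = 0.5
    ab = config.ability
    z_pcl = (subject.pcl_total - ab.pcl_ref_mean) / ab.pcl_ref_sd
    logit = (
        rp.intercept
        + rp.agreement_slope * float(scaled_agreement)
        + rp.group_offset * (subject.group is Group.PTSD)
        + rp.severity_offset * z_pcl
        + rp.condition_offset * (condition is Condition.TRAUMATIC)
        + e_i
    )
    p = float(_logistic(logit))
    rng = _substream(root, "recall", subject.subject_id, video_id)
    n_rec = int(rng.binomial(rp.n_units_total, p))
    return RecallRecord(subject.subject_id, video_id, condition, rp.n_units_total, n_rec)


# ---------------------------------------------------------------------------
# Anxiety ratings
# ---------------------------------------------------------------------------

def generate_anxiety(
    subject: SubjectRecord,
    condition: Condition,
    config: GeneratorConfig,
    seed: int | None = None,
) -> list[AnxietyRecord]:
    """Simulate the 11 per-session anxiety probes on the 1-10 Likert scale."""
    ap = config.anxiety
    root = config.seed if seed is None else seed
    u_i = float(_substream(root, "anx-subject", subject.subject_id).normal(0.0, ap.subject_sd))
    mu = (
        ap.baseline
        + ap.group_effect * (subject.group is Group.PTSD)
        + ap.condition_effect * (condition is Condition.TRAUMATIC)
        + ap.interaction
        * ((subject.group is Group.PTSD) and (condition is Condition.TRAUMATIC))
    )
    rng = _substream(root, "anx", subject.subject_id, condition.value)
    noise = rng.normal(0.0, ap.residual_sd, ap.n_trials) if ap.residual_sd > 0 else np.zeros(ap.n_trials)
    ratings = np.clip(mu + u_i + noise, ap.clip_lo, ap.clip_hi)
    return [
        AnxietyRecord(subject.subject_id, condition, t + 1, float(r))
        for t, r in enumerate(ratings)
    ]


# ---------------------------------------------------------------------------
# Whole-cohort assembly
# ---------------------------------------------------------------------------

def _video_condition(subject: SubjectRecord, video_index: int, n_videos: int) -> Condition:
    """First half of the videos belong to session 2, the rest to session 3."""
    in_first_session = video_index < (n_videos + 1) // 2
    if subject.session_order == "trauma_first":
        return Condition.TRAUMATIC if in_first_session else Condition.POSITIVE
    return Condition.POSITIVE if in_first_session else Condition.TRAUMATIC


@dataclass
class CohortData:
    """A fully generated cohort as tidy tables plus the generating truth."""

    config: GeneratorConfig
    subjects: pd.DataFrame       # subject_id, group, pcl_total, ability, session_order
    video_truths: dict[str, VideoTruth]
    press_log: pd.DataFrame      # one row per press: subject_id, video_id, condition, time_s
    roster: pd.DataFrame         # subject_id, video_id, condition (every viewing)
    agreement: pd.DataFrame = field(default_factory=pd.DataFrame)
    norms: pd.DataFrame = field(default_factory=pd.DataFrame)
    recall: pd.DataFrame = field(default_factory=pd.DataFrame)
    anxiety: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def durations(self) -> dict[str, int]:
        return {v.video_id: v.duration_s for v in self.config.videos}

    def write(self, out_dir: str | Path) -> None:
        """Write the four CSV tables plus truth.json (UTF-8, comma-separated)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(out / "subjects.csv", index=False)
        self.press_log.to_csv(out / "press_log.csv", index=False)
        if len(self.recall):
            self.recall.to_csv(out / "recall.csv", index=False)
        if len(self.anxiety):
            self.anxiety.to_csv(out / "anxiety.csv", index=False)
        truth = {
            "seed": self.config.seed,
            "videos": {
                vid: {
                    "duration_s": t.duration_s,
                    "boundary_times": t.boundary_times.tolist(),
                    "salience": t.salience.tolist(),
                }
                for vid, t in self.video_truths.items()
            },
            "ability": {
                row.subject_id: row.ability for row in self.subjects.itertuples()
            },
            "recall_params": {
                "intercept": self.config.recall.intercept,
                "agreement_slope": self.config.recall.agreement_slope,
                "group_offset": self.config.recall.group_offset,
                "condition_offset": self.config.recall.condition_offset,
            },
            "anxiety_observed_cell_means": self.config.anxiety.observed_cell_means(),
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1))


def generate_cohort(config: GeneratorConfig, score: bool = True) -> CohortData:
    """Generate a complete cohort; optionally score agreement and draw recall.

    With ``score=True`` (default) the measured segmentation-agreement scores
    are computed from the generated press logs (whole-sample norms) and the
    recall table is drawn conditional on them, completing the mediation
    chain.  ``score=False`` stops after presses/anxiety, for callers that
    want to run the scoring stage themselves.
    """
    subjects = generate_subjects(config)
    subj_df = pd.DataFrame(
        [
            dict(
                subject_id=s.subject_id,
                group=s.group.value,
                pcl_total=s.pcl_total,
                ability=s.ability,
                session_order=s.session_order,
            )
            for s in subjects
        ]
    )
    truths = {
        v.video_id: generate_video_truth(v.video_id, v.duration_s, config)
        for v in config.videos
    }
    n_videos = len(config.videos)

    press_rows: list[dict] = []
    roster_rows: list[dict] = []
    logs: dict[tuple[str, str], PressLog] = {}
    for s in subjects:
        for vi, v in enumerate(config.videos):
            cond = _video_condition(s, vi, n_videos)
            log = generate_press_log(s, truths[v.video_id], cond, config)
            logs[(s.subject_id, v.video_id)] = log
            roster_rows.append(
                dict(subject_id=s.subject_id, video_id=v.video_id, condition=cond.value)
            )
            for t in log.press_times_s:
                press_rows.append(
                    dict(
                        subject_id=s.subject_id,
                        video_id=v.video_id,
                        condition=cond.value,
                        time_s=float(t),
                    )
                )
    press_df = pd.DataFrame(
        press_rows, columns=["subject_id", "video_id", "condition", "time_s"]
    )
    roster_df = pd.DataFrame(roster_rows)

    anx_rows = [
        dict(
            subject_id=r.subject_id,
            condition=r.condition.value,
            trial_index=r.trial_index,
            rating=r.rating,
        )
        for s in subjects
        for cond in (Condition.TRAUMATIC, Condition.POSITIVE)
        for r in generate_anxiety(s, cond, config)
    ]
    anx_df = pd.DataFrame(anx_rows)

    cohort = CohortData(
        config=config,
        subjects=subj_df,
        video_truths=truths,
        press_log=press_df,
        roster=roster_df,
        anxiety=anx_df,
    )
    if not score:
        return cohort

    from .segmentation import score_cohort

    agreement, norms = score_cohort(press_df, cohort.durations, roster=roster_df)
    cohort.agreement = agreement
    cohort.norms = norms

    subj_map = {s.subject_id: s for s in subjects}
    rec_rows = []
    for row in agreement.itertuples():
        rec = generate_recall(
            subj_map[row.subject_id],
            row.scaled,
            row.video_id,
            Condition(row.condition),
            config,
        )
        rec_rows.append(
            dict(
                subject_id=rec.subject_id,
                video_id=rec.video_id,
                condition=rec.condition.value,
                n_units_total=rec.n_units_total,
                n_recalled=rec.n_recalled,
            )
        )
    cohort.recall = pd.DataFrame(rec_rows)
    return cohort
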