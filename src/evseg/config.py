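"""Configuration for the synthetic cohort generator and the analysis pipeline.

The defaults encode the study conditions the generator is calibrated to: a
clinical PTSD group and a matched control group who segment and recall six
everyday-activity videos after autobiographical narrative priming.  All
generative coefficients live here so a single config object (or YAML file)
fully determines a cohort given a seed.

Calibrated defaults were solved once, offline, so that large-sample
expectations of the generated data match the target sample statistics
(group PCL means/SDs, anxiety cell means, agreement and recall group means,
mean boundaries per video); see docs/methods.md for the procedure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "VideoSpec",
    "PCLParams",
    "AbilityParams",
    "BoundaryParams",
    "PressParams",
    "RecallParams",
    "AnxietyParams",
    "GeneratorConfig",
    "load_config",
    "save_config",
    "DEFAULT_VIDEOS",
]

#: The six everyday-activity videos with their durations in seconds.
DEFAULT_VIDEOS: tuple[tuple[str, int], ...] = (
    ("breakfast", 329),
    ("party", 376),
    ("plants", 354),
    ("library", 249),
    ("sweeping", 263),
    ("dishes", 327),
)

PCL_MIN, PCL_MAX = 17, 85


@dataclass
class VideoSpec:
    video_id: str
    duration_s: int

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")


@dataclass
class PCLParams:
    """Latent (pre-truncation) normal parameters for a group's PCL total.

    Scores are drawn from N(mu, sigma^2) truncated to [17, 85] and rounded to
    integers.  ``mu``/``sigma`` are calibrated so the *post-truncation* mean
    and SD match the target sample statistics (truncation at the floor of 17
    otherwise inflates a low-severity group's mean).
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("PCL sigma must be nonnegative")


@dataclass
class AbilityParams:
    """Latent segmentation-fidelity model.

    ability_i = logistic(alpha0 + alpha_pcl * z_i + u_i),  u_i ~ N(0, subject_sd^2)

    where z_i standardises the subject's PCL total against fixed reference
    constants (the pooled mean/SD of the default two-group cohort), so a
    subject's ability does not depend on who else was sampled.  alpha_pcl < 0:
    higher symptom severity lowers segmentation fidelity.
    """

    alpha0: float = 0.98
    alpha_pcl: float = -0.30
    subject_sd: float = 1.2
    pcl_ref_mean: float = 37.6
    pcl_ref_sd: float = 19.6

    def __post_init__(self) -> None:
        if self.subject_sd < 0:
            raise ValueError("ability subject_sd must be nonnegative")
        if self.pcl_ref_sd <= 0:
            raise ValueError("pcl_ref_sd must be positive")


@dataclass
class BoundaryParams:
    """Latent normative event-boundary structure per video.

    Boundaries are a gamma renewal process (shape ``gap_shape``, mean gap
    ``mean_gap_s`` seconds); per-boundary salience is Beta(a, b).
    """

    mean_gap_s: float = 8.48
    gap_shape: float = 4.0
    salience_a: float = 4.0
    salience_b: float = 2.0

    def __post_init__(self) -> None:
        if self.mean_gap_s <= 0 or self.gap_shape <= 0:
            raise ValueError("renewal-process parameters must be positive")
        if self.salience_a <= 0 or self.salience_b <= 0:
            raise ValueError("Beta salience shapes must be positive")


@dataclass
class PressParams:
    """Button-press observation model.

    A boundary with salience s is detected with probability
    ``clip(base_hit_rate + ability_hit_slope * ability, 0, 1) ** (1 / s)``
    (increasing in both ability and salience; exactly 1 at ability = 1 with
    the default base 0 / slope 1).  Detected boundaries are reported with
    Gaussian timing jitter; false alarms are a homogeneous Poisson process
    with rate ``false_alarm_rate * (1 - ability)`` per second.
    """

    base_hit_rate: float = 0.0
    ability_hit_slope: float = 1.0
    jitter_sd_s: float = 0.9
    false_alarm_rate: float = 0.075
    condition_hit_offset: float = 0.0  # traumatic-narrative shift; 0 = no priming effect

    def __post_init__(self) -> None:
        if self.jitter_sd_s < 0 or self.false_alarm_rate < 0:
            raise ValueError("press-model rates/sds must be nonnegative")


@dataclass
class RecallParams:
    """Unit-level recall model encoding the mediation structure.

    Each of ``n_units_total`` A1 action units is recalled independently with
    probability logistic(intercept + agreement_slope * scaled_agreement
    + group_offset * 1[PTSD] + severity_offset * z(PCL)
    + condition_offset * 1[TRAUMATIC] + e_i),
    e_i ~ N(0, subject_noise_sd^2) a per-subject encoding offset.
    agreement_slope > 0 is the mediator->outcome path; the direct
    (non-mediated) memory deficit is split between a diagnosis component
    (group_offset < 0) and a continuous symptom-severity component
    (severity_offset < 0 per standardised PCL unit, same reference
    standardisation as ability) so that both the group and the severity
    mediation decompositions are well defined.
    """

    intercept: float = -2.65
    agreement_slope: float = 2.21
    group_offset: float = -0.005
    severity_offset: float = -0.044
    condition_offset: float = -0.06
    subject_noise_sd: float = 0.33
    n_units_total: int = 40

    def __post_init__(self) -> None:
        if self.n_units_total <= 0:
            raise ValueError("n_units_total must be a positive integer")
        if self.subject_noise_sd < 0:
            raise ValueError("subject_noise_sd must be nonnegative")


@dataclass
class AnxietyParams:
    """Trial-level anxiety-rating model (1-10 Likert, clipped).

    rating = baseline + group_effect*1[PTSD] + condition_effect*1[TRAUMATIC]
             + interaction*1[PTSD]*1[TRAUMATIC] + u_i + e, clipped to [1, 10],
    with 11 trials per subject-session.  The latent coefficients are solved so
    the *observed* (post-clipping) cell-mean contrasts equal the calibration
    targets.
    """

    baseline: float = 1.1938
    group_effect: float = 1.4232
    condition_effect: float = 1.1682
    interaction: float = 0.7479
    subject_sd: float = 0.8
    residual_sd: float = 1.1
    n_trials: int = 11
    clip_lo: float = 1.0
    clip_hi: float = 10.0

    def __post_init__(self) -> None:
        if self.subject_sd < 0 or self.residual_sd < 0:
            raise ValueError("anxiety sds must be nonnegative")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")

    def observed_cell_means(self) -> dict[str, float]:
        """Large-n expected cell means after clipping (closed form)."""
        from scipy import stats

        s = float((self.subject_sd**2 + self.residual_sd**2) ** 0.5)
        out = {}
        for key, m in self.latent_cell_means().items():
            if s == 0:
                out[key] = float(min(max(m, self.clip_lo), self.clip_hi))
                continue
            a = (self.clip_lo - m) / s
            b = (self.clip_hi - m) / s
            out[key] = float(
                self.clip_lo * stats.norm.cdf(a)
                + self.clip_hi * stats.norm.sf(b)
                + m * (stats.norm.cdf(b) - stats.norm.cdf(a))
                + s * (stats.norm.pdf(a) - stats.norm.pdf(b))
            )
        return out

    def latent_cell_means(self) -> dict[str, float]:
        return {
            "control_positive": self.baseline,
            "ptsd_positive": self.baseline + self.group_effect,
            "control_traumatic": self.baseline + self.condition_effect,
            "ptsd_traumatic": self.baseline
            + self.group_effect
            + self.condition_effect
            + self.interaction,
        }


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic cohort."""

    n_ptsd: int = 63
    n_control: int = 64
    seed: int = 0
    videos: list[VideoSpec] = field(
        default_factory=lambda: [VideoSpec(v, d) for v, d in DEFAULT_VIDEOS]
    )
    pcl_ptsd: PCLParams = field(default_factory=lambda: PCLParams(mu=55.179, sigma=14.798))
    pcl_control: PCLParams = field(default_factory=lambda: PCLParams(mu=6.880, sigma=8.0))
    ability: AbilityParams = field(default_factory=AbilityParams)
    boundary: BoundaryParams = field(default_factory=BoundaryParams)
    press: PressParams = field(default_factory=PressParams)
    recall: RecallParams = field(default_factory=RecallParams)
    anxiety: AnxietyParams = field(default_factory=AnxietyParams)

    def __post_init__(self) -> None:
        if self.n_ptsd <= 0 or self.n_control <= 0:
            raise ValueError(
                f"group sizes must be positive (n_ptsd={self.n_ptsd}, "
                f"n_control={self.n_control})"
            )
        if not self.videos:
            raise ValueError("at least one video is required")


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(x) for x in obj]
    return obj


def save_config(config: GeneratorConfig, path: str | Path) -> None:
    """Write a config as YAML (round-trips through :func:`load_config`)."""
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


def load_config(path: str | Path) -> GeneratorConfig:
    """Load a YAML/JSON config file; missing sections fall back to defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict[str, Any]) -> GeneratorConfig:
    kwargs: dict[str, Any] = {}
    section_types = {
        "pcl_ptsd": PCLParams,
        "pcl_control": PCLParams,
        "ability": AbilityParams,
        "boundary": BoundaryParams,
        "press": PressParams,
        "recall": RecallParams,
        "anxiety": AnxietyParams,
    }
    for key, value in raw.items():
        if key == "videos":
            kwargs["videos"] = [
                VideoSpec(**v) if isinstance(v, dict) else VideoSpec(*v) for v in value
            ]
        elif key in section_types:
            kwargs[key] = section_types[key](**value)
        elif key in {"n_ptsd", "n_control", "seed"}:
            kwargs[key] = value
        else:
            raise ValueError(f"unknown config section: {key!r}")
    return GeneratorConfig(**kwargs)
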