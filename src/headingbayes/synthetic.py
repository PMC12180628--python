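"""Synthetic heading-estimation experiments.

Forward-simulates trial tables with the structure of the three
experiments: 12 headings (+/-3, 9, 15, 21, 27, 33 degrees), response
probes of 80/160/240/360 degrees, and the per-condition repetition counts
of each design. Responses come from the package's own generative model
(encode, add von Mises sensory noise, decode, scale by alpha, clip), so
synthetic data are exchangeable with real trial tables for every analysis
in the package.

Stimulus kinematics (constant 1.5 m/s vs a 0-3-0 m/s triangular speed
profile, both travelling 0.75 m in 0.5 s) are carried as design metadata:
the observer model is speed-profile-blind, matching the empirical null
effect of the profile, and the travel-distance identity is checkable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .angles import deg2rad, rad2deg, wrap_rad
from .encoding import SensoryMapping, encode
from .observer import (
    DecoderTable,
    ObserverParams,
    ResponseCondition,
    ResponseMapping,
    standard_condition,
)
from .prior import PriorModel

__all__ = [
    "SpeedProfile",
    "CONSTANT_SPEED",
    "TRIANGULAR_SPEED",
    "Block",
    "ExperimentDesign",
    "DEFAULT_HEADING_SET_DEG",
    "make_design",
    "generate_trials",
    "travel_distance",
]

DEFAULT_HEADING_SET_DEG = (-33.0, -27.0, -21.0, -15.0, -9.0, -3.0,
                           3.0, 9.0, 15.0, 21.0, 27.0, 33.0)


@dataclass(frozen=True)
class SpeedProfile:
    """Simulated self-motion speed profile of the optic-flow stimulus.

    ``constant`` moves at ``constant_speed`` for ``duration`` seconds.
    ``triangular`` accelerates 0 -> peak_speed and decelerates back to 0
    with equal acceleration magnitudes; its duration must equal the
    triangle's total time 2 * peak_speed / accel_magnitude.
    """

    kind: str  # constant | triangular
    constant_speed: float = 1.5  # m/s
    peak_speed: float = 3.0  # m/s
    accel_magnitude: float = 12.0  # m/s^2
    duration: float = 0.5  # s

    def __post_init__(self):
        if self.kind not in ("constant", "triangular"):
            raise ValueError(f"unknown speed profile kind {self.kind!r}")


CONSTANT_SPEED = SpeedProfile("constant")
TRIANGULAR_SPEED = SpeedProfile("triangular")


def travel_distance(profile: SpeedProfile) -> float:
    """Distance travelled during the stimulus, in meters.

    Constant profile: speed x duration. Triangular profile: the area under
    the symmetric speed triangle, peak^2 / accel; raises if the stated
    duration is inconsistent with the triangle's total time.
    """
    if profile.kind == "constant":
        return profile.constant_speed * profile.duration
    t_total = 2.0 * profile.peak_speed / profile.accel_magnitude
    if abs(profile.duration - t_total) > 1e-9:
        raise ValueError(
            f"triangular profile duration {profile.duration} s does not match "
            f"the triangle's total time {t_total} s "
            f"(2 * {profile.peak_speed} / {profile.accel_magnitude})"
        )
    return profile.peak_speed**2 / profile.accel_magnitude


@dataclass(frozen=True)
class Block:
    """One block of trials: a probe condition, a speed profile, repetitions."""

    condition: ResponseCondition
    speed_profile: SpeedProfile
    reps_per_heading: int
    group: str = ""  # between-subject group; empty = all participants

    def n_trials(self, n_headings: int) -> int:
        return self.reps_per_heading * n_headings


@dataclass(frozen=True)
class ExperimentDesign:
    """Trial schedule of one experiment.

    ``seed`` fixes the (per-participant) randomized trial order, so the
    schedule of (heading, condition) pairs is a property of the design and
    does not change with the noise seed passed to ``generate_trials``.
    ``interleaved`` merges all blocks into one fully shuffled session.
    """

    experiment_id: str
    heading_set_deg: tuple = DEFAULT_HEADING_SET_DEG
    blocks: tuple = ()
    n_participants: int = 18
    seed: int = 0
    interleaved: bool = False

    def __post_init__(self):
        if any(abs(h) > 33.0 + 1e-9 for h in self.heading_set_deg) and \
                self.experiment_id in ("exp1", "exp2", "exp3"):
            raise ValueError(
                "standard designs keep headings within the stimulus range "
                f"[-33, 33] deg, got {self.heading_set_deg}"
            )

    @property
    def conditions(self) -> list[ResponseCondition]:
        seen = {}
        for b in self.blocks:
            seen.setdefault(b.condition.label, b.condition)
        return list(seen.values())

    @property
    def groups(self) -> list[str]:
        out = []
        for b in self.blocks:
            if b.group not in out:
                out.append(b.group)
        return out

    def n_trials_per_participant(self) -> int:
        nh = len(self.heading_set_deg)
        groups = self.groups
        if len(groups) <= 1:
            return sum(b.n_trials(nh) for b in self.blocks)
        # between-subject: each participant runs one group's blocks
        return max(
            sum(b.n_trials(nh) for b in self.blocks if b.group == g) for g in groups
        )


VALID_EXPERIMENT_IDS = ("exp1", "exp2", "exp3")


def make_design(
    experiment_id: str,
    *,
    exp3_reps_per_heading: int = 15,
    n_participants: int | None = None,
    seed: int = 0,
) -> ExperimentDesign:
    """Canonical designs of the three experiments.

    exp1: between-subject line (80 deg probe, 40 reps/heading/block) vs
    circle (360 deg probe, 15 reps/heading/block), each group running one
    constant-speed and one triangular-speed block (480 resp. 180 trials
    per block). exp2: within-subject line80 / arc80 / circle360 blocks at
    constant speed, 20 reps/heading (240 trials per block). exp3: arc80 /
    arc160 / arc240 fully interleaved, constant speed; the default 15
    reps/heading gives 540 trials (12 headings x 3 conditions x 15), while
    ``exp3_reps_per_heading=20`` reproduces the alternatively stated
    720-trial total.
    """
    if experiment_id not in VALID_EXPERIMENT_IDS:
        raise ValueError(
            f"unknown experiment id {experiment_id!r}; valid ids are "
            f"{list(VALID_EXPERIMENT_IDS)} (construct ExperimentDesign "
            "directly for custom designs)"
        )
    if experiment_id == "exp1":
        blocks = (
            Block(standard_condition("line80"), CONSTANT_SPEED, 40, group="line"),
            Block(standard_condition("line80"), TRIANGULAR_SPEED, 40, group="line"),
            Block(standard_condition("circle360"), CONSTANT_SPEED, 15, group="circle"),
            Block(standard_condition("circle360"), TRIANGULAR_SPEED, 15, group="circle"),
        )
        return ExperimentDesign(
            "exp1", blocks=blocks,
            n_participants=n_participants or 36, seed=seed,
        )
    if experiment_id == "exp2":
        blocks = tuple(
            Block(standard_condition(lb), CONSTANT_SPEED, 20)
            for lb in ("line80", "arc80", "circle360")
        )
        return ExperimentDesign(
            "exp2", blocks=blocks,
            n_participants=n_participants or 18, seed=seed,
        )
    blocks = tuple(
        Block(standard_condition(lb), CONSTANT_SPEED, exp3_reps_per_heading)
        for lb in ("arc80", "arc160", "arc240")
    )
    return ExperimentDesign(
        "exp3", blocks=blocks,
        n_participants=n_participants or 18, seed=seed, interleaved=True,
    )


def _participant_schedule(design: ExperimentDesign, p_idx: int, group: str):
    """Deterministic (heading, condition) schedule for one participant."""
    rng = np.random.default_rng([abs(design.seed), p_idx])
    blocks = [b for b in design.blocks if b.group == group]
    per_block = []
    for b in blocks:
        pairs = [
            (h, b.condition) for h in design.heading_set_deg
            for _ in range(b.reps_per_heading)
        ]
        per_block.append(pairs)
    if design.interleaved:
        pairs = [p for blk in per_block for p in blk]
        rng.shuffle(pairs)
        return pairs
    out = []
    for pairs in per_block:
        rng.shuffle(pairs)
        out.extend(pairs)
    return out


def generate_trials(
    design: ExperimentDesign,
    prior: PriorModel,
    params: ObserverParams,
    response_mapping: ResponseMapping,
    seed: int,
    *,
    n_participants: int | None = None,
    participant_heterogeneity: float = 0.3,
    mapping: SensoryMapping | None = None,
) -> pd.DataFrame:
    """Simulate a full trial table from the generative observer model.

    Per trial: draw m ~ vonMises(F~(theta0), kappa), decode to the
    posterior-mean estimate, scale by the condition's alpha and keep the
    report inside the probe. With more than one participant, each
    participant's kappa is drawn log-normally around the shared value
    (sigma_log = ``participant_heterogeneity``) to emulate individual
    variation; a single participant uses the shared kappa exactly.
    """
    if mapping is None:
        mapping = encode(prior)
    n_p = n_participants if n_participants is not None else design.n_participants
    groups = design.groups
    decoders: dict[float, DecoderTable] = {}
    frames = []
    for p_idx in range(n_p):
        group = groups[min(p_idx * len(groups) // n_p, len(groups) - 1)]
        schedule = _participant_schedule(design, p_idx, group)
        noise_rng = np.random.default_rng([abs(seed), p_idx])
        if n_p > 1 and participant_heterogeneity > 0:
            kappa_p = params.kappa * float(
                np.exp(participant_heterogeneity * noise_rng.standard_normal())
            )
        else:
            kappa_p = params.kappa
        if kappa_p not in decoders:
            decoders[kappa_p] = DecoderTable(
                mapping, prior, ObserverParams(kappa_p)
            )
        decoder = decoders[kappa_p]

        theta0 = np.array([h for h, _ in schedule], dtype=float)
        conds = [c for _, c in schedule]
        mu = mapping.forward(deg2rad(theta0))
        eta = stats.vonmises.rvs(
            kappa_p, size=len(schedule), random_state=noise_rng
        )
        # keep m on the branch centred at mu: same convention as the
        # change-of-variables response density
        m = mu + wrap_rad(eta)
        theta_hat = decoder.decode(m)  # unwrapped radians

        reported = np.empty(len(schedule))
        for i, cond in enumerate(conds):
            r = response_mapping.alpha_for(cond) * theta_hat[i]
            if cond.is_full_circle:
                reported[i] = rad2deg(wrap_rad(r))
            else:
                h = deg2rad(cond.half_range_deg)
                reported[i] = rad2deg(np.clip(r, -h, h))

        frames.append(
            pd.DataFrame(
                {
                    "participant_id": f"P{p_idx + 1:02d}",
                    "experiment_id": design.experiment_id,
                    "condition_label": [c.label for c in conds],
                    "true_heading_deg": theta0,
                    "reported_heading_deg": reported,
                    "trial_index": np.arange(len(schedule)),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
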