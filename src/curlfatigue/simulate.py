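"""Synthetic concentration-curl session generator.

Emulates the study protocol the rest of the pipeline assumes: each
subject-arm session is one warm-up set of 5 repetitions followed by 5 main
sets of 15 repetitions, recorded at 50 Hz on a wrist-worn 9-channel IMU
(3-axis accelerometer, gyroscope, magnetometer) together with a heart-rate
track, with one Borg RPE report per set.  Fatigue structure enters through

* per-set completion-time inflation (later sets take longer),
* per-set angular-velocity amplitude change on the gyroscope channels
  (muscular-endurance decline), and
* a positively skewed per-repetition waveform once the true RPE enters the
  fatigue band [17, 20].

Every generated repetition comes with ground truth (interval, true RPE,
fatigue flag) so segmentation, labelling and classification can be scored
without any external data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "SessionRecording",
    "generate_session",
    "generate_cohort",
    "rpe_trajectory",
]

BORG_MIN = 6
BORG_MAX = 20

IMU_CHANNELS = (
    "acc_x", "acc_y", "acc_z",
    "gyr_x", "gyr_y", "gyr_z",
    "mag_x", "mag_y", "mag_z",
)

#: Peak amplitude of the motion pulse on each kinematic channel
#: (m/s^2 for accelerometer, deg/s for gyroscope).
BASE_AMPLITUDES = {
    "acc_x": 1.5,
    "acc_y": 4.0,
    "acc_z": 2.0,
    "gyr_x": 120.0,
    "gyr_y": 15.0,
    "gyr_z": 80.0,
}

#: Channels carrying the primary curl motion; these receive the fatigue skew.
PRIMARY_CHANNELS = ("gyr_x", "gyr_z", "acc_y")


#: Magnetometer baseline (uT) and weak coupling to the arm-orientation pulse.
MAG_BASELINE = {"mag_x": 30.0, "mag_y": -12.0, "mag_z": 45.0}
MAG_COUPLING = {"mag_x": 0.5, "mag_y": 0.5, "mag_z": 2.0}
MAG_DRIFT_AMPLITUDE = 3.0     # uT, slow sinusoidal drift
MAG_DRIFT_PERIOD = 90.0       # s

HR_FLOOR = 30.0               # bpm, physiological lower clip


class ConfigurationError(ValueError):
    """Raised when a GeneratorConfig violates its invariants."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-protocol parameters for the synthetic cohort.

    Defaults mirror the data-collection protocol: 20 subjects, both arms,
    5 warm-up reps plus 5 x 15 main reps at 50 Hz with a 4.5 kg dumbbell,
    ~2 s per repetition early in the session.  ``set_time_inflation`` and
    ``endurance_change`` are the fractional per-set changes of completion
    time and gyroscope amplitude relative to the first main set.
    """

    n_subjects: int = 20
    arms_per_subject: int = 2
    warmup_reps: int = 5
    n_sets: int = 5
    reps_per_set: int = 15
    sampling_rate: float = 50.0
    base_rep_duration: float = 2.0
    dumbbell_mass: float = 4.5
    set_time_inflation: tuple[float, ...] = (0.017, 0.081, 0.143, 0.310)
    endurance_change: tuple[float, ...] = (0.006, 0.011, -0.055, -0.041)
    fatigue_skew: float = 1.0
    fatigue_deepening: float = 1.0         # waveform-skew growth across the fatigue band
    warmup_rpe_range: tuple[float, float] = (10.0, 12.0)
    final_rpe_range: tuple[float, float] = (17.0, 20.0)
    hr_noise_sd: float = 3.0
    hr_cap: float = 210.0
    inter_rep_gap: float = 0.5
    channel_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"acc": 0.05, "gyr": 1.0, "mag": 0.3}
    )
    seed: int = 0
    # secondary realism knobs (not part of the study protocol)
    within_set_rpe_fraction: float = 0.3   # share of a set's RPE rise spent inside the set
    rep_duration_jitter: float = 0.02      # lognormal sd of per-rep duration
    amplitude_jitter: float = 0.05         # lognormal sd of per-rep amplitude
    shape_jitter: float = 0.25             # sd of per-rep waveform-sharpness noise
    subject_scale_sd: float = 0.1          # lognormal sd of per-subject strength
    channel_profile_sd: float = 0.05       # lognormal sd of per-subject channel gains
    skew_gain_sd: float = 0.4              # lognormal sd of per-subject fatigue strength
    expression_concentration: float = 0.7  # Dirichlet alpha: how channel-specific fatigue is
    baseline_sharpness_max: float = 0.5    # upper bound of fresh-waveform sharpness
    max_skew: float = 4.0                  # cap on the total waveform-sharpness exponent
    mounting_rotation_sd: float = 0.15     # rad, per-session sensor-strap orientation spread
    fatigue_variability: float = 0.0       # growth of rep-to-rep vigor spread under fatigue
    rep_vigor_sd: float = 0.1              # log-sd of the coherent per-rep vigor factor
    fatigue_incoherence: float = 1.0       # log-sd of the incoherence shift at full fatigue
    rest_between_sets: float = 5.0         # s
    lead_in: float = 2.0                   # s of rest before the first set

    def __post_init__(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "arms_per_subject": self.arms_per_subject,
            "warmup_reps": self.warmup_reps,
            "n_sets": self.n_sets,
            "reps_per_set": self.reps_per_set,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {value}")
        if self.arms_per_subject > 2:
            raise ConfigurationError("arms_per_subject must be 1 or 2")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.base_rep_duration <= 0:
            raise ConfigurationError("base_rep_duration must be positive")
        if self.dumbbell_mass <= 0:
            raise ConfigurationError("dumbbell_mass must be positive")
        for name in ("set_time_inflation", "endurance_change"):
            if len(getattr(self, name)) != self.n_sets - 1:
                raise ConfigurationError(
                    f"{name} must have length n_sets - 1 = {self.n_sets - 1}, "
                    f"got {len(getattr(self, name))}"
                )
        for name in ("warmup_rpe_range", "final_rpe_range"):
            lo, hi = getattr(self, name)
            if not (BORG_MIN <= lo <= hi <= BORG_MAX):
                raise ConfigurationError(
                    f"{name} must lie within the Borg scale [6, 20], got ({lo}, {hi})"
                )
        if self.hr_cap > 210:
            raise ConfigurationError("hr_cap must be <= 210 bpm (watch limit)")
        if not (0 < self.inter_rep_gap < self.base_rep_duration):
            raise ConfigurationError(
                "inter_rep_gap must be positive and shorter than base_rep_duration"
            )
        if self.fatigue_incoherence < 0 or self.rep_vigor_sd < 0:
            raise ConfigurationError(
                "fatigue_incoherence and rep_vigor_sd must be non-negative"
            )


@dataclass
class SessionRecording:
    """One subject-arm recording: IMU + heart-rate samples plus set metadata.

    ``samples`` holds columns ``t``, the nine IMU channels and ``heart_rate``;
    ``set_boundaries`` are 0-based half-open sample-index pairs, one per set
    including the warm-up; ``reported_rpe`` is the integer Borg rating the
    subject reported at the end of each set.
    """

    subject_id: str
    arm: str
    sampling_rate: float
    samples: pd.DataFrame
    set_boundaries: list[tuple[int, int]]
    reported_rpe: list[int]
    dumbbell_mass: float

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def set_slice(self, set_index: int) -> pd.DataFrame:
        start, end = self.set_boundaries[set_index]
        return self.samples.iloc[start:end]


GROUND_TRUTH_COLUMNS = [
    "subject_id", "arm", "set_index", "rep_index",
    "start_sample", "end_sample", "true_rpe", "is_fatigued",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _subject_traits(config: GeneratorConfig, subject_id: str) -> dict:
    """Deterministic per-subject draws shared by both arms.

    Derived from a CRC of the subject id (not the subject's position in the
    cohort) so adding subjects never perturbs existing ones.  Traits:

    * ``offset`` — where the subject sits within the warm-up and final RPE
      ranges (uniform);
    * ``scale`` — overall strength multiplier (lognormal);
    * ``profile`` — per-channel gain multipliers, the subject's curl style
      (lognormal per kinematic channel);
    * ``skew_gain`` — how strongly fatigue reshapes this subject's
      waveform (lognormal);
    * ``expression`` — how that reshaping distributes over the primary
      motion channels (Dirichlet, mean 1 per channel): individuals
      compensate differently, some mostly in elbow rotation, others in
      the sideways acceleration;
    * ``baseline_sharpness`` — the subject's fresh (unfatigued) waveform
      sharpness: some lifters jerk the dumbbell even without fatigue.
    """
    key = zlib.crc32(subject_id.encode("utf8"))
    rng = np.random.default_rng(np.random.SeedSequence((config.seed % (2**31), key)))
    offset = float(rng.uniform())
    z = rng.normal(size=2 + len(BASE_AMPLITUDES))
    scale = float(np.exp(config.subject_scale_sd * z[0]))
    skew_gain = float(np.exp(config.skew_gain_sd * z[1]))
    profile = {
        ch: float(np.exp(config.channel_profile_sd * z[2 + i]))
        for i, ch in enumerate(BASE_AMPLITUDES)
    }
    expr = rng.dirichlet([config.expression_concentration] * len(PRIMARY_CHANNELS))
    expression = {
        ch: float(expr[i] * len(PRIMARY_CHANNELS)) for i, ch in enumerate(PRIMARY_CHANNELS)
    }
    baseline = float(rng.uniform(0.0, config.baseline_sharpness_max))
    return {
        "offset": offset,
        "scale": scale,
        "skew_gain": skew_gain,
        "profile": profile,
        "expression": expression,
        "baseline_sharpness": baseline,
    }


def _session_rpe_anchors(
    config: GeneratorConfig, subject_offset: float
) -> tuple[float, float]:
    """Warm-up-end and session-final true RPE for a subject."""
    w_lo, w_hi = config.warmup_rpe_range
    f_lo, f_hi = config.final_rpe_range
    w = w_lo + subject_offset * (w_hi - w_lo)
    f = f_lo + subject_offset * (f_hi - f_lo)
    return w, f


def rpe_trajectory(
    config: GeneratorConfig, set_index: int, subject_offset: float
) -> np.ndarray:
    """True Borg RPE for every repetition of one set.

    The trajectory is monotonically non-decreasing across the session from
    the warm-up range to the final range.  Most of the rise happens between
    sets (perceived exertion jumps after a completed set); a fraction
    ``within_set_rpe_fraction`` of each set's increment accrues across the
    reps inside the set, so a set straddling the fatigue threshold contains
    both non-fatigued and fatigued repetitions.
    """
    if not (0 <= set_index <= config.n_sets):
        raise ValueError(f"set_index {set_index} out of range")
    w, f = _session_rpe_anchors(config, subject_offset)
    delta = (f - w) / config.n_sets       # per-main-set RPE increment
    wsf = config.within_set_rpe_fraction
    if set_index == 0:
        n = config.warmup_reps
        end = w
        start = max(config.warmup_rpe_range[0], w - wsf * delta)
    else:
        n = config.reps_per_set
        end = w + delta * set_index
        start = end - wsf * delta
    i = np.arange(1, n + 1)
    return start + (end - start) * i / n


def _rep_pulse(n: int, hold_frac: float, skew: float) -> np.ndarray:
    """One repetition cycle of ``n`` samples on a unit-amplitude channel.

    The cycle is hold / active pulse / hold, with the two holds together
    taking ``2 * hold_frac`` of the cycle (the release-position pause split
    across adjacent repetitions).  The active pulse is a raised cosine
    sharpened by ``skew``: raising it to the power ``1 + skew`` narrows the
    contraction peak and stretches the near-zero shoulders, concentrating
    sample mass at low values, which raises the sample skewness of the
    waveform while keeping the pulse symmetric in time (so trough-to-trough
    boundaries stay well defined).
    """
    x = np.zeros(n)
    h = int(round(hold_frac * n))
    i0, i1 = h, n - h
    if i1 <= i0:
        return x
    u = (np.arange(i1 - i0) + 0.5) / (i1 - i0)
    x[i0:i1] = np.sin(np.pi * u) ** (2.0 * (1.0 + skew))
    return x


def _fatigue_skew_amount(true_rpe: float, config: GeneratorConfig) -> float:
    """Waveform skew for a repetition: ramps in over Borg 16 -> 17, then keeps
    deepening through the fatigue band (17 -> 20), so the pulse shape stays
    monotone in perceived exertion instead of saturating at the band edge."""
    onset = float(np.clip(true_rpe - 16.0, 0.0, 1.0))
    depth = float(np.clip(true_rpe - 17.0, 0.0, 3.0)) / 3.0
    return config.fatigue_skew * (onset + config.fatigue_deepening * depth)


def generate_session(
    config: GeneratorConfig,
    subject_id: str,
    arm: str,
    seed: int | None = None,
) -> tuple[SessionRecording, pd.DataFrame]:
    """Generate one subject-arm session and its per-repetition ground truth.

    Parameters
    ----------
    config
        Protocol parameters; see :class:`GeneratorConfig`.
    subject_id, arm
        Identifiers carried into the recording and the ground truth. The
        subject id also seeds the subject-level exertion offset and strength
        scale, shared by both arms.
    seed
        Session-level noise seed.  Defaults to a deterministic derivation
        from ``config.seed``, the subject id and the arm.

    Returns
    -------
    (SessionRecording, ground_truth)
        ``ground_truth`` is a DataFrame with one row per repetition
        (``GROUND_TRUTH_COLUMNS``); warm-up is ``set_index`` 0.
    """
    if arm not in ("left", "right"):
        raise ConfigurationError(f"arm must be 'left' or 'right', got {arm!r}")
    if seed is None:
        key = zlib.crc32(f"{subject_id}/{arm}".encode("utf8"))
        seed_seq = np.random.SeedSequence((config.seed % (2**31), key, 1))
    else:
        seed_seq = np.random.SeedSequence(seed % (2**31))
    rng = np.random.default_rng(seed_seq)

    traits = _subject_traits(config, subject_id)
    offset = traits["offset"]

    fs = config.sampling_rate
    hold_frac = (config.inter_rep_gap / 2.0) / config.base_rep_duration
    rest_n = int(round(config.rest_between_sets * fs))
    lead_n = int(round(config.lead_in * fs))

    set_reps = [config.warmup_reps] + [config.reps_per_set] * config.n_sets

    # ------- lay out repetition cycles -----------------------------------
    chunks: list[dict] = []         # per-rep descriptors
    set_bounds: list[tuple[int, int]] = []
    reported: list[int] = []
    cursor = lead_n
    for s, n_reps in enumerate(set_reps):
        rpe = rpe_trajectory(config, s, offset)
        if s >= 2:
            time_factor = 1.0 + config.set_time_inflation[s - 2]
            amp_factor = 1.0 + config.endurance_change[s - 2]
        else:
            time_factor = 1.0
            amp_factor = 1.0
        set_start = cursor
        for r in range(n_reps):
            jitter = float(np.exp(rng.normal(0.0, config.rep_duration_jitter)))
            n_cycle = int(round(config.base_rep_duration * time_factor * jitter * fs))
            chunks.append({
                "set_index": s,
                "rep_index": r,
                "start": cursor,
                "end": cursor + n_cycle,
                "true_rpe": float(rpe[r]),
                "amp_factor": amp_factor,
            })
            cursor += n_cycle
        set_bounds.append((set_start, cursor))
        reported.append(int(np.clip(_round_half_up(rpe[-1]), BORG_MIN, BORG_MAX)))
        cursor += rest_n
    n_total = cursor - rest_n + lead_n   # trailing rest replaced by a short tail

    # ------- synthesize channels -----------------------------------------
    t = np.arange(n_total) / fs
    noise = config.channel_noise_sd
    data = {"t": t}
    for ch in IMU_CHANNELS:
        sd = noise.get(ch, noise.get(ch[:3], 0.0))
        data[ch] = rng.normal(0.0, sd, n_total) if sd > 0 else np.zeros(n_total)

    rpe_track = np.full(n_total, _session_rpe_anchors(config, offset)[0])
    for rep in chunks:
        i0, i1 = rep["start"], rep["end"]
        n_cycle = i1 - i0
        ramp = float(np.clip(rep["true_rpe"] - 16.0, 0.0, 1.0))
        fatigue_component = traits["skew_gain"] * _fatigue_skew_amount(rep["true_rpe"], config)
        pulse_plain = _rep_pulse(n_cycle, hold_frac, 0.0)
        # mean-one lognormal: the variability knobs must not shift the mean
        # amplitude, or they would contaminate the configured endurance trend
        amp_sd = config.amplitude_jitter
        amp_jit = float(np.exp(rng.normal(-0.5 * amp_sd**2, amp_sd)))
        # rep-to-rep jitter with two components, both mean-one so the
        # configured between-set amplitude trend is never disturbed:
        # - vigor: the whole movement is a little stronger or weaker each
        #   rep (a coherent factor on every motion channel), with spread
        #   optionally growing under fatigue (fatigue_variability);
        # - incoherence: under fatigue the load is still lifted every rep,
        #   but degraded coordination redistributes amplitude within each
        #   sensor group rather than scaling the overall movement, so the
        #   per-axis log-factors are centred on the group's geometric mean.
        #   The redistribution is symmetric (two-sided), so fatigue adds a
        #   dispersion signature rather than shifting any channel's trend.
        v_sd = config.rep_vigor_sd * (1.0 + config.fatigue_variability * ramp)
        inc_sd = config.fatigue_incoherence * ramp
        vig = float(rng.normal(0.0, 1.0)) if v_sd > 0 else 0.0
        base_log = v_sd * vig - v_sd**2 / 2.0
        logs_by_channel: dict[str, float] = {ch: base_log for ch in BASE_AMPLITUDES}
        if inc_sd > 0:
            # the redistribution shows in the translation (accelerometer)
            # axes: the gyroscope axes follow the elbow joint itself and are
            # mechanically constrained by it, so the angular path of a rep
            # is what the lifter preserves even when stabilization wobbles
            group = ("acc_x", "acc_y", "acc_z")
            logs = rng.normal(0.0, inc_sd, size=len(group))
            logs -= logs.mean() + inc_sd**2 * (1.0 - 1.0 / len(group)) / 2.0
            for ch, lg in zip(group, logs):
                logs_by_channel[ch] += lg
        vigor = {ch: float(np.exp(lg)) for ch, lg in logs_by_channel.items()}
        for ch, base in BASE_AMPLITUDES.items():
            if ch in PRIMARY_CHANNELS:
                # per-channel sharpness: subject baseline + channel-weighted
                # fatigue expression + per-rep form noise, kept in [0, max]
                skew = (
                    traits["baseline_sharpness"]
                    + fatigue_component * traits["expression"][ch]
                    + rng.normal(0.0, config.shape_jitter)
                )
                pulse = _rep_pulse(n_cycle, hold_frac,
                                   float(np.clip(skew, 0.0, config.max_skew)))
            else:
                pulse = pulse_plain
            amp = (base * traits["scale"] * traits["profile"][ch] * amp_jit
                   * rep["amp_factor"] * vigor[ch])
            data[ch][i0:i1] += amp * pulse
        for ch, coupling in MAG_COUPLING.items():
            data[ch][i0:i1] += coupling * pulse_plain
        rpe_track[i0:] = rep["true_rpe"]   # hold through the following rest

    # per-session sensor mounting: the strap never sits identically twice, so
    # the accelerometer and gyroscope triads are rotated by a random session
    # orientation; vector norms (total acceleration) are unaffected
    if config.mounting_rotation_sd > 0:
        rotation = _random_rotation(rng, config.mounting_rotation_sd)
        for triad in (("acc_x", "acc_y", "acc_z"), ("gyr_x", "gyr_y", "gyr_z")):
            stacked = np.vstack([data[ch] for ch in triad])
            rotated = rotation @ stacked
            for k, ch in enumerate(triad):
                data[ch] = rotated[k]

    drift_phase = rng.uniform(0.0, 2.0 * np.pi, size=3)
    for k, ch in enumerate(("mag_x", "mag_y", "mag_z")):
        data[ch] += MAG_BASELINE[ch] + MAG_DRIFT_AMPLITUDE * np.sin(
            2.0 * np.pi * t / MAG_DRIFT_PERIOD + drift_phase[k]
        )

    hr = 10.0 * rpe_track + rng.normal(0.0, config.hr_noise_sd, n_total)
    data["heart_rate"] = np.clip(hr, HR_FLOOR, config.hr_cap)

    samples = pd.DataFrame(data)
    session = SessionRecording(
        subject_id=subject_id,
        arm=arm,
        sampling_rate=fs,
        samples=samples,
        set_boundaries=set_bounds,
        reported_rpe=reported,
        dumbbell_mass=config.dumbbell_mass,
    )
    truth = pd.DataFrame({
        "subject_id": subject_id,
        "arm": arm,
        "set_index": [c["set_index"] for c in chunks],
        "rep_index": [c["rep_index"] for c in chunks],
        "start_sample": [c["start"] for c in chunks],
        "end_sample": [c["end"] for c in chunks],
        "true_rpe": [c["true_rpe"] for c in chunks],
        "is_fatigued": [c["true_rpe"] >= 17.0 for c in chunks],
    })[GROUND_TRUTH_COLUMNS]
    return session, truth


def generate_cohort(
    config: GeneratorConfig,
) -> list[tuple[SessionRecording, pd.DataFrame]]:
    """Generate the full cohort: ``n_subjects x arms_per_subject`` sessions.

    Session seeds derive deterministically from ``config.seed`` and the
    subject/arm identity, so regenerating with more subjects leaves the
    existing sessions bit-identical.
    """
    arms = ("right", "left")[: config.arms_per_subject]
    out = []
    for i in range(config.n_subjects):
        subject_id = f"S{i + 1:02d}"
        for arm in arms:
            out.append(generate_session(config, subject_id, arm))
    return out


def cohort_ground_truth(
    cohort: list[tuple[SessionRecording, pd.DataFrame]]
) -> pd.DataFrame:
    """Concatenate per-session ground truth into one table."""
    return pd.concat([truth for _, truth in cohort], ignore_index=True)


def _random_rotation(rng: np.random.Generator, sd: float) -> np.ndarray:
    """Small random 3D rotation: rotation vector with iid N(0, sd) components."""
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(rng.normal(0.0, sd, size=3)).as_matrix()


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    """Copy of ``config`` with a different cohort seed."""
    return replace(config, seed=seed)
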