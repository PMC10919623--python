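"""Synthetic cohort, protocol, accelerometer-signal and calorimetry generator.

The laboratory study this package models collected 100 Hz triaxial
accelerometry at three wear-sites (hip, wrist, chest on a lanyard) together
with indirect calorimetry (VO2 in ml/kg/min) while adults and children
performed seven activity bouts drawn from a 17-activity catalog. No raw
dataset is available, so this module generates data with the same
statistical structure: group-specific demographics and resting metabolism,
a 3/3/1 bout-composition protocol, site-distinct gravity orientations,
intensity-scaled movement amplitude with gait harmonics for locomotor
tasks, and calorimetry that rises to a per-bout metabolic plateau.

Every public operation is deterministic given its ``seed`` argument.
Latent per-bout MET draws are returned alongside the signals so that
pipeline-level parameter-recovery tests are non-circular.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

ADULT = "adult"
CHILD = "child"
GROUPS = (ADULT, CHILD)

HIP = "hip"
WRIST = "wrist"
CHEST = "chest"
SITES = (HIP, WRIST, CHEST)

CAT_SEDENTARY_LIVING = "1_sedentary_living"
CAT_LIGHT = "2_light"
CAT_MODERATE = "3_moderate"
CAT_VIGOROUS = "4_vigorous"
CATEGORIES = (CAT_SEDENTARY_LIVING, CAT_LIGHT, CAT_MODERATE, CAT_VIGOROUS)


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParticipantProfile:
    """One subject: group membership, anthropometrics and resting VO2."""

    id: str
    group: str            # "adult" | "child"
    sex: str              # "male" | "female"
    age: float            # years
    height: float         # cm
    weight: float         # kg
    resting_vo2: float    # ml/kg/min

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if min(self.age, self.height, self.weight, self.resting_vo2) <= 0:
            raise ValueError("age, height, weight, resting_vo2 must be > 0")
        if self.group == ADULT and self.age < 18:
            raise ValueError("adult profiles require age >= 18")
        if self.group == CHILD and self.age >= 18:
            raise ValueError("child profiles require age < 18")

    @property
    def bmi(self) -> float:
        return self.weight / (self.height / 100.0) ** 2


@dataclass(frozen=True)
class ActivitySpec:
    """A catalog activity with its MET distribution and movement style."""

    name: str
    category: str
    met_mean: float
    met_sd: float
    locomotor: bool  # gait-periodic (walking/running/stairs) vs irregular

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.met_mean <= 0 or self.met_sd < 0:
            raise ValueError("met_mean must be > 0 and met_sd >= 0")


@dataclass(frozen=True)
class Bout:
    activity: ActivitySpec
    planned_duration: float  # s, in [300, 480]
    rest_after: float        # s


@dataclass(frozen=True)
class Protocol:
    participant_id: str
    bouts: tuple[Bout, ...]


@dataclass
class TriaxialRecording:
    """Timestamped triaxial acceleration (units of g) for one wear-site."""

    site: str
    sample_rate: float
    t: np.ndarray            # (n,) seconds, strictly increasing
    xyz: np.ndarray          # (n, 3) acceleration in g
    bout_annotations: list[tuple[int, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown wear-site {self.site!r}")
        self.t = np.asarray(self.t, dtype=np.float64)
        self.xyz = np.asarray(self.xyz, dtype=np.float32)
        if self.t.ndim != 1 or self.xyz.shape != (self.t.size, 3):
            raise ValueError("t must be (n,) and xyz (n, 3)")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("acceleration must be finite")

    @property
    def n_samples(self) -> int:
        return self.t.size


@dataclass
class CalorimetrySeries:
    """Binned VO2 (ml/kg/min) covering the rest period and all bouts."""

    interval: float          # s, bin width
    t: np.ndarray            # (n,) bin start times, s
    vo2: np.ndarray          # (n,) ml/kg/min, >= 0
    rest_start: float
    rest_end: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.vo2 = np.asarray(self.vo2, dtype=np.float64)
        if np.any(self.vo2 < 0):
            raise ValueError("vo2 must be non-negative")


@dataclass(frozen=True)
class BoutLatent:
    """Ground truth hidden from the pipeline, kept for recovery tests."""

    bout_index: int
    met_draw: float
    reached_steady: bool
    start_s: float
    end_s: float


@dataclass
class Session:
    """One participant's simulated visit: recordings + calorimetry + latents."""

    profile: ParticipantProfile
    protocol: Protocol
    recordings: dict[str, TriaxialRecording]
    calorimetry: CalorimetrySeries
    latents: list[BoutLatent]


# --------------------------------------------------------------------------
# Generator configuration
# --------------------------------------------------------------------------

# Published cohort statistics: (mean, sd) per group.
DEMOGRAPHIC_DEFAULTS = {
    ADULT: dict(age=(26.9, 8.7), bmi=(21.8, 2.0), resting_vo2=(4.09, 0.98),
                p_female=11 / 26, age_floor=18.0),
    CHILD: dict(age=(12.1, 2.3), bmi=(18.3, 2.5), resting_vo2=(5.71, 1.91),
                p_female=19 / 28, age_floor=6.0),
}

# Category MET distributions, (mean, sd) per group.  Categories 1 and 2 share
# the "living or light" row of the published demographics table.
MET_DEFAULTS = {
    ADULT: {CAT_SEDENTARY_LIVING: (1.7, 0.9), CAT_LIGHT: (1.7, 0.9),
            CAT_MODERATE: (5.8, 1.9), CAT_VIGOROUS: (8.2, 2.3)},
    CHILD: {CAT_SEDENTARY_LIVING: (1.8, 1.0), CAT_LIGHT: (1.8, 1.0),
            CAT_MODERATE: (4.8, 1.5), CAT_VIGOROUS: (7.7, 2.1)},
}


@dataclass(frozen=True)
class SignalConfig:
    """Free parameters of the invented signal model.

    The study describes no signal properties of its recordings, so every
    constant here is a design choice; the model carries exactly the three
    cues the downstream classifiers need: a site-specific gravity
    orientation, movement amplitude/periodicity scaling with MET, and an
    anthropometric modulation of the amplitude-to-MET mapping.
    """

    sample_rate: float = 100.0
    # Static gravity unit vectors per site (device axes, units of g).
    orientations: dict = field(default_factory=lambda: {
        HIP: (0.09, 0.98, 0.18),
        WRIST: (0.66, 0.25, 0.71),
        CHEST: (0.10, 0.88, -0.46),
    })
    orientation_wobble_g: float = 0.015   # slow postural drift amplitude
    orientation_wobble_hz: float = 0.05
    # Movement amplitude model: rms = amp_per_met * (MET-1)^amp_exponent
    #   * site_gain * (weight_ref/weight)^w_exp * (age_ref/age)^a_exp
    amp_per_met: float = 0.08             # g per (MET-1)^exponent
    amp_exponent: float = 0.8
    site_gain: dict = field(default_factory=lambda: {HIP: 1.0, WRIST: 1.45, CHEST: 0.85})
    weight_ref: float = 55.0              # kg
    age_ref: float = 18.0                 # years
    weight_exp: float = 0.4
    age_exp: float = 0.15
    # Gait model for locomotor activities.
    step_hz_base: float = 1.0
    step_hz_per_met: float = 0.28
    step_hz_min: float = 1.2
    step_hz_max: float = 3.4
    harmonic_ratios: tuple = (1.0, 0.5, 0.25)
    armswing_gain: float = 0.6            # wrist component at half step rate
    # broad low-frequency trunk-sway / stride-modulation energy present in
    # all movement, as a fraction of total movement RMS
    lowband_fraction: float = 0.35
    lowband_hz: tuple = (0.3, 1.5)
    # Non-locomotor movement: band-limited noise.
    irregular_band_hz: tuple = (0.5, 6.0)
    axis_weights: tuple = (0.8, 1.0, 0.6)
    # Chest lanyard swing.
    lanyard_hz: float = 0.7
    lanyard_gain: float = 0.25
    sensor_noise_g: float = 0.01
    sedentary_rms_ceiling: float = 0.03   # movement-band rms at rest stays below
    min_orientation_deg: float = 15.0     # guaranteed site separation


@dataclass(frozen=True)
class CalorimetryConfig:
    interval: float = 5.0            # s per bin
    rest_duration: float = 600.0     # 10 min seated rest before the bouts
    on_transient: float = 120.0      # s of first-order rise at bout onset
    tau: float = 45.0                # s, rise time constant
    rest_noise: float = 0.15         # ml/kg/min, sd at rest
    bout_noise_frac: float = 0.02    # sd = frac * plateau + floor
    bout_noise_floor: float = 0.05
    steady_failure_rate: float = 0.05  # fraction of bouts that never settle
    failure_overshoot: float = 1.4     # ramp target relative to plateau


@dataclass(frozen=True)
class ProtocolConfig:
    n_bouts_cat1: int = 3
    n_bouts_cat23: int = 3
    n_bouts_cat4: int = 1
    duration_range: tuple = (300.0, 480.0)  # 5 min, extended up to 8 min
    rest_after: float = 180.0


# --------------------------------------------------------------------------
# Activity catalog
# --------------------------------------------------------------------------

_CATALOG_NAMES = [
    # (name, category, locomotor)
    ("sitting_writing", CAT_SEDENTARY_LIVING, False),
    ("reading", CAT_SEDENTARY_LIVING, False),
    ("card_matching_game", CAT_SEDENTARY_LIVING, False),
    ("sewing", CAT_SEDENTARY_LIVING, False),
    ("light_sweeping", CAT_SEDENTARY_LIVING, False),
    ("folding_clothes", CAT_SEDENTARY_LIVING, False),
    ("tablet_seated", CAT_SEDENTARY_LIVING, False),
    ("walk_2.0_kph", CAT_LIGHT, True),
    ("walk_3.2_kph", CAT_LIGHT, True),
    ("stretching", CAT_LIGHT, False),
    ("walk_4.0_kph", CAT_MODERATE, True),
    ("walk_4.8_kph", CAT_MODERATE, True),
    ("walk_4.8_kph_incline_3pct", CAT_MODERATE, True),
    ("moderate_workout_video", CAT_MODERATE, False),
    ("run_6.4_kph", CAT_VIGOROUS, True),
    ("run_7.2_kph", CAT_VIGOROUS, True),
    ("stair_climbing", CAT_VIGOROUS, True),
]


def default_catalog(group: str = ADULT) -> list[ActivitySpec]:
    """The 17-activity catalog with group-specific MET distributions."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    mets = MET_DEFAULTS[group]
    return [ActivitySpec(name=n, category=c, met_mean=mets[c][0],
                         met_sd=mets[c][1], locomotor=loco)
            for n, c, loco in _CATALOG_NAMES]


# --------------------------------------------------------------------------
# Participants
# --------------------------------------------------------------------------

def _sym_truncnorm(rng: np.random.Generator, mean: float, sd: float,
                   lo: float, size: int) -> np.ndarray:
    """Normal truncated symmetrically about the mean, so the mean is kept."""
    hi = 2 * mean - lo
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _sample_group(rng: np.random.Generator, group: str, n: int,
                  prefix: str) -> list[ParticipantProfile]:
    d = DEMOGRAPHIC_DEFAULTS[group]
    age = _sym_truncnorm(rng, *d["age"], lo=d["age_floor"], size=n)
    if group == CHILD:
        age = np.minimum(age, 17.9)
    bmi = _sym_truncnorm(rng, *d["bmi"], lo=max(12.0, d["bmi"][0] - 3.5 * d["bmi"][1]),
                         size=n)
    if group == ADULT:
        height = _sym_truncnorm(rng, 168.0, 8.0, lo=145.0, size=n)
    else:
        # crude pediatric growth curve: ~4.8 cm per year past age 6
        height = 105.0 + 4.8 * (age - 6.0) + rng.normal(0.0, 5.0, size=n)
        height = np.clip(height, 100.0, 185.0)
    weight = bmi * (height / 100.0) ** 2
    vo2 = _sym_truncnorm(rng, *d["resting_vo2"],
                         lo=max(1.0, d["resting_vo2"][0] - 2.8 * d["resting_vo2"][1]),
                         size=n)
    sex = np.where(rng.random(n) < d["p_female"], "female", "male")
    return [ParticipantProfile(id=f"{prefix}{i + 1:03d}", group=group,
                               sex=str(sex[i]), age=float(age[i]),
                               height=float(height[i]), weight=float(weight[i]),
                               resting_vo2=float(vo2[i]))
            for i in range(n)]


def sample_participants(n_adult: int, n_child: int,
                        seed: int) -> list[ParticipantProfile]:
    """Draw a synthetic cohort matching the published group demographics.

    Ages, BMIs and resting VO2 come from truncated normal distributions with
    the published means/SDs (truncation is symmetric about the mean so the
    configured mean is preserved); child heights follow a simple growth
    curve and weights are derived from BMI and height.
    """
    if n_adult < 0 or n_child < 0:
        raise ValueError("participant counts must be non-negative")
    rng = np.random.default_rng(seed)
    out = _sample_group(rng, ADULT, n_adult, "A")
    out += _sample_group(rng, CHILD, n_child, "C")
    return out


# --------------------------------------------------------------------------
# Protocol
# --------------------------------------------------------------------------

def draw_protocol(profile: ParticipantProfile,
                  catalog: list[ActivitySpec] | None = None,
                  seed: int = 0,
                  config: ProtocolConfig = ProtocolConfig()) -> Protocol:
    """Draw a 7-bout protocol: 3 sedentary/living, 3 light-or-moderate,
    1 vigorous, sampled without replacement and performed in random order."""
    if catalog is None:
        catalog = default_catalog(profile.group)
    rng = np.random.default_rng(seed)
    cat1 = [a for a in catalog if a.category == CAT_SEDENTARY_LIVING]
    cat23 = [a for a in catalog if a.category in (CAT_LIGHT, CAT_MODERATE)]
    cat4 = [a for a in catalog if a.category == CAT_VIGOROUS]
    need = (config.n_bouts_cat1, config.n_bouts_cat23, config.n_bouts_cat4)
    if len(cat1) < need[0] or len(cat23) < need[1] or len(cat4) < need[2]:
        raise ValueError(
            "catalog too small: need >= "
            f"{need[0]} sedentary/living, {need[1]} light-or-moderate, "
            f"{need[2]} vigorous activities")
    chosen = (
        [cat1[i] for i in rng.choice(len(cat1), need[0], replace=False)]
        + [cat23[i] for i in rng.choice(len(cat23), need[1], replace=False)]
        + [cat4[i] for i in rng.choice(len(cat4), need[2], replace=False)]
    )
    order = rng.permutation(len(chosen))
    lo, hi = config.duration_range
    bouts = tuple(
        Bout(activity=chosen[i],
             planned_duration=float(np.round(rng.uniform(lo, hi))),
             rest_after=config.rest_after)
        for i in order
    )
    return Protocol(participant_id=profile.id, bouts=bouts)


# --------------------------------------------------------------------------
# Acceleration signal model
# --------------------------------------------------------------------------

def _covariate_factor(profile: ParticipantProfile, cfg: SignalConfig) -> float:
    return ((cfg.weight_ref / profile.weight) ** cfg.weight_exp
            * (cfg.age_ref / profile.age) ** cfg.age_exp)


def movement_amplitude(profile: ParticipantProfile, met: float, site: str,
                       cfg: SignalConfig = SignalConfig()) -> float:
    """Target movement-band RMS (g) for a bout at a given MET level."""
    if site not in cfg.site_gain:
        raise ValueError(f"unknown wear-site {site!r}")
    if met <= 1.0:
        return 0.0
    return (cfg.amp_per_met * (met - 1.0) ** cfg.amp_exponent
            * cfg.site_gain[site] * _covariate_factor(profile, cfg))


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       band: tuple[float, float]) -> np.ndarray:
    white = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    s = x.std()
    return x / s if s > 0 else x


def _movement_component(rng: np.random.Generator, profile: ParticipantProfile,
                        activity: ActivitySpec, site: str, met: float,
                        n: int, cfg: SignalConfig) -> np.ndarray:
    """(n, 3) zero-mean movement signal with RMS set by the MET level."""
    fs = cfg.sample_rate
    amp = movement_amplitude(profile, met, site, cfg)
    out = np.zeros((n, 3))
    if amp <= 0:
        return out
    t = np.arange(n) / fs
    w = np.asarray(cfg.axis_weights, dtype=float)
    w = w / np.linalg.norm(w)
    if activity.locomotor:
        f_step = float(np.clip(cfg.step_hz_base + cfg.step_hz_per_met * met,
                               cfg.step_hz_min, cfg.step_hz_max))
        comp = np.zeros(n)
        for k, r in enumerate(cfg.harmonic_ratios, start=1):
            comp += r * np.sin(2 * np.pi * k * f_step * t + rng.uniform(0, 2 * np.pi))
        for ax in range(3):
            phase = rng.uniform(0, 2 * np.pi)
            axsig = np.zeros(n)
            for k, r in enumerate(cfg.harmonic_ratios, start=1):
                axsig += r * np.sin(2 * np.pi * k * f_step * t + phase)
            out[:, ax] = w[ax] * axsig
        if site == WRIST:
            # arm swing: one cycle per stride (half the step rate)
            out[:, 0] += cfg.armswing_gain * np.sin(
                2 * np.pi * 0.5 * f_step * t + rng.uniform(0, 2 * np.pi))
    else:
        for ax in range(3):
            out[:, ax] = w[ax] * _bandlimited_noise(rng, n, fs, cfg.irregular_band_hz)
    if site == CHEST:
        out[:, 0] += cfg.lanyard_gain * np.sin(
            2 * np.pi * cfg.lanyard_hz * t + rng.uniform(0, 2 * np.pi))
        out[:, 2] += cfg.lanyard_gain * np.sin(
            2 * np.pi * cfg.lanyard_hz * t + rng.uniform(0, 2 * np.pi))
    rms = np.sqrt(np.mean(out ** 2))
    if rms > 0:
        out *= (1.0 - cfg.lowband_fraction) * amp / rms
    # trunk-sway / stride-modulation energy below the gait harmonics
    low = np.empty_like(out)
    for ax in range(3):
        low[:, ax] = w[ax] * _bandlimited_noise(rng, n, fs, cfg.lowband_hz)
    lrms = np.sqrt(np.mean(low ** 2))
    if lrms > 0:
        out += low * (cfg.lowband_fraction * amp / lrms)
    return out


def _gravity_component(rng: np.random.Generator, site: str, n: int,
                       cfg: SignalConfig) -> np.ndarray:
    g = np.asarray(cfg.orientations[site], dtype=float)
    g = g / np.linalg.norm(g)
    t = np.arange(n) / cfg.sample_rate
    wobble = np.empty((n, 3))
    for ax in range(3):
        wobble[:, ax] = cfg.orientation_wobble_g * np.sin(
            2 * np.pi * cfg.orientation_wobble_hz * t + rng.uniform(0, 2 * np.pi))
    return g[None, :] + wobble


def simulate_bout_signal(profile: ParticipantProfile, activity: ActivitySpec,
                         site: str, duration: float, seed: int,
                         config: SignalConfig = SignalConfig(),
                         met: float | None = None) -> TriaxialRecording:
    """Simulate one bout of triaxial acceleration at one wear-site.

    signal = gravity orientation (site-specific, with slow wobble)
           + movement component whose RMS scales with the bout MET
           + white sensor noise.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if site not in SITES:
        raise ValueError(f"unknown wear-site {site!r}")
    rng = np.random.default_rng(seed)
    if met is None:
        a, b = (0.0 - activity.met_mean) / max(activity.met_sd, 1e-9), np.inf
        met = float(stats.truncnorm.rvs(a, b, loc=activity.met_mean,
                                        scale=max(activity.met_sd, 1e-9),
                                        random_state=rng))
    n = int(round(duration * config.sample_rate))
    xyz = (_gravity_component(rng, site, n, config)
           + _movement_component(rng, profile, activity, site, met, n, config)
           + rng.normal(0.0, config.sensor_noise_g, size=(n, 3)))
    t = np.arange(n) / config.sample_rate
    return TriaxialRecording(site=site, sample_rate=config.sample_rate,
                             t=t, xyz=xyz,
                             bout_annotations=[(0, 0.0, duration)])


REST_ACTIVITY = ActivitySpec(name="seated_rest", category=CAT_SEDENTARY_LIVING,
                             met_mean=1.0, met_sd=0.0, locomotor=False)


# --------------------------------------------------------------------------
# Calorimetry + full session
# --------------------------------------------------------------------------

def _session_timeline(protocol: Protocol,
                      ccfg: CalorimetryConfig) -> tuple[list[tuple[float, float]], float]:
    spans = []
    t = ccfg.rest_duration
    for bout in protocol.bouts:
        spans.append((t, t + bout.planned_duration))
        t += bout.planned_duration + bout.rest_after
    return spans, t


def simulate_calorimetry(profile: ParticipantProfile, protocol: Protocol,
                         seed: int,
                         config: CalorimetryConfig = CalorimetryConfig()
                         ) -> tuple[CalorimetrySeries, list[BoutLatent]]:
    """Simulate binned VO2 over rest + bouts, returning latent MET draws.

    Each bout's plateau is ``met_draw * resting_vo2`` with
    ``met_draw ~ Normal(met_mean, met_sd)`` truncated above 0; VO2 rises with
    a first-order lag over a fixed on-transient and then sits at the plateau
    plus noise.  A configurable fraction of bouts never settles (the VO2
    ramps throughout), emulating participants who fail to reach steady state.
    """
    rng = np.random.default_rng(seed)
    spans, total = _session_timeline(protocol, config)
    edges = np.arange(0.0, total + config.interval, config.interval)
    t = edges[:-1]
    vo2 = np.full(t.size, profile.resting_vo2, dtype=float)
    latents: list[BoutLatent] = []
    for i, (bout, (s, e)) in enumerate(zip(protocol.bouts, spans)):
        act = bout.activity
        sd = max(act.met_sd, 1e-9)
        a = (0.0 - act.met_mean) / sd
        met = float(stats.truncnorm.rvs(a, np.inf, loc=act.met_mean, scale=sd,
                                        random_state=rng))
        plateau = met * profile.resting_vo2
        steady = bool(rng.random() >= config.steady_failure_rate)
        mask = (t >= s) & (t < e)
        tt = t[mask] - s
        if steady:
            # first-order rise normalized to hit the plateau exactly at the
            # end of the on-transient, flat thereafter
            norm = 1.0 - np.exp(-config.on_transient / config.tau)
            rise = (1.0 - np.exp(-np.minimum(tt, config.on_transient)
                                 / config.tau)) / norm
            rise[tt >= config.on_transient] = 1.0
            vo2[mask] = profile.resting_vo2 + (plateau - profile.resting_vo2) * rise
        else:
            target = config.failure_overshoot * plateau
            vo2[mask] = profile.resting_vo2 + (target - profile.resting_vo2) * (
                tt / max(e - s, 1.0))
        # recovery toward rest during the gap after the bout
        gap = (t >= e) & (t < e + bout.rest_after)
        tg = t[gap] - e
        end_val = vo2[mask][-1] if mask.any() else profile.resting_vo2
        vo2[gap] = profile.resting_vo2 + (end_val - profile.resting_vo2) * np.exp(
            -tg / config.tau)
        latents.append(BoutLatent(bout_index=i, met_draw=met,
                                  reached_steady=steady, start_s=s, end_s=e))
    noise_sd = np.where(t < config.rest_duration, config.rest_noise,
                        config.bout_noise_frac * vo2 + config.bout_noise_floor)
    vo2 = np.maximum(vo2 + rng.normal(0.0, 1.0, t.size) * noise_sd, 0.0)
    series = CalorimetrySeries(interval=config.interval, t=t, vo2=vo2,
                               rest_start=0.0, rest_end=config.rest_duration)
    return series, latents


def simulate_session(profile: ParticipantProfile, protocol: Protocol,
                     sites: tuple[str, ...] | set[str], seed: int,
                     signal_config: SignalConfig = SignalConfig(),
                     calorimetry_config: CalorimetryConfig = CalorimetryConfig()
                     ) -> Session:
    """Simulate a full visit: 10-min seated rest, then the protocol's bouts
    with rest gaps, recorded at every requested wear-site and time-aligned
    with the calorimetry.  All recordings share identical bout annotations.
    """
    sites = tuple(sites)
    if not sites:
        raise ValueError("at least one wear-site is required")
    for s in sites:
        if s not in SITES:
            raise ValueError(f"unknown wear-site {s!r}")
    ss = np.random.SeedSequence(seed)
    cal_seed, sig_seed = ss.spawn(2)
    series, latents = simulate_calorimetry(
        profile, protocol, seed=cal_seed.generate_state(1)[0] % (2 ** 31),
        config=calorimetry_config)
    spans = [(l.start_s, l.end_s) for l in latents]
    total = series.t[-1] + series.interval
    fs = signal_config.sample_rate
    n_total = int(round(total * fs))
    annotations = [(i, s, e) for i, (s, e) in enumerate(spans)]
    recordings: dict[str, TriaxialRecording] = {}
    site_seeds = sig_seed.spawn(len(sites))
    for site, site_ss in zip(sites, site_seeds):
        rng = np.random.default_rng(site_ss)
        xyz = (_gravity_component(rng, site, n_total, signal_config)
               + rng.normal(0.0, signal_config.sensor_noise_g, size=(n_total, 3)))
        for lat, bout in zip(latents, protocol.bouts):
            i0 = int(round(lat.start_s * fs))
            i1 = int(round(lat.end_s * fs))
            move = _movement_component(rng, profile, bout.activity, site,
                                       lat.met_draw, i1 - i0, signal_config)
            xyz[i0:i1] += move
        t = np.arange(n_total) / fs
        recordings[site] = TriaxialRecording(
            site=site, sample_rate=fs, t=t, xyz=xyz,
            bout_annotations=list(annotations))
    return Session(profile=profile, protocol=protocol, recordings=recordings,
                   calorimetry=series, latents=latents)


# --------------------------------------------------------------------------
# Diagnostics
# --------------------------------------------------------------------------

def movement_rms(recording: TriaxialRecording, start_s: float | None = None,
                 end_s: float | None = None, highpass_hz: float = 0.25) -> float:
    """Movement-band RMS (g): high-pass the three axes and pool their power."""
    x = recording.xyz
    if start_s is not None or end_s is not None:
        lo = 0 if start_s is None else int(round(start_s * recording.sample_rate))
        hi = x.shape[0] if end_s is None else int(round(end_s * recording.sample_rate))
        x = x[lo:hi]
    sos = sps.butter(4, highpass_hz, btype="highpass",
                     fs=recording.sample_rate, output="sos")
    hp = sps.sosfiltfilt(sos, x.astype(np.float64), axis=0)
    return float(np.sqrt(np.mean(hp ** 2) * 3.0))


def mean_orientation(recording: TriaxialRecording) -> np.ndarray:
    """Mean per-axis acceleration — the gravity direction estimate."""
    return np.asarray(recording.xyz, dtype=np.float64).mean(axis=0)


def orientation_angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    ca = float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
    return float(np.degrees(np.arccos(np.clip(ca, -1.0, 1.0))))
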