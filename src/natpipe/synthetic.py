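"""Synthetic cohort generator emulating an early-Parkinson's imaging study.

Because the clinical data behind this pipeline are not public, every input
the analysis consumes can be synthesized here with the statistical structure
the downstream stages assume: a cohort of 22 PD patients and 39 healthy
controls (HC) with realistic covariate distributions, per-participant ROI
time series with subnetwork block correlation, activity diaries whose
Formula-based weekly energy expenditure (WEE) reproduces each participant's
physical-activity score, and motor/cognitive test batteries with a planted
dependence of motor ability on network attack tolerance (NAT).

Planted structure (all magnitudes are free parameters of the generator, not
estimates from any real cohort):

* each subnetwork has a two-tier block structure — a tightly coupled core
  (half of its ROIs) and a more loosely coupled periphery. Covariate
  effects raise the periphery coupling toward the fixed core level:
  within-SMN periphery coupling increases with putaminal DaT integrity
  (``dat_to_smn_coupling`` per z-unit) and within-ATN periphery coupling
  with education (``edu_to_atn_coupling`` per year). Mean within-block
  correlation therefore rises with the covariate, and because proportional
  thresholding is invariant to level shifts of a whole submatrix, it is
  this core/periphery *homogenization* — not the level itself — that
  carries the effect into the binarized graphs: a more homogeneous graph
  has no dominant hubs and tolerates degree-targeted attack better,
* latent motor ability = intercept + ``nat_to_gmp_slope`` * NAT
  + ``pa_moderation_slope`` * NAT * min(PA, knot) + noise; the default
  moderation slope is negative, so the conditional NAT effect is strongest
  in sedentary participants, shrinks as PA rises and freezes at the knot —
  reproducing a significance region confined to low moderator values and a
  negative interaction coefficient,
* cognitive scores are independent of NAT (null cognitive finding).

HC participants receive time series and behavior but carry no DaT score and
no NAT-behavior coupling: they serve only as the z-score reference sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import ROIAtlas, SUBNETWORKS
from .behavior import TestBatteryResult
from .errors import ConfigurationError, DomainError

#: Number of fMRI volumes acquired under each scanning sequence.
SEQUENCE_VOLUMES = {1: 740, 2: 500, 3: 740}


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults reproduce the study conditions.

    Distribution parameters are (mean, sd) pairs except ``pa_location_scale``
    which parameterizes a log-normal on the WEE scale (location = log median).
    """

    n_pd: int = 22
    n_hc: int = 39
    age_pd: tuple = (62.1, 8.0)          # years
    age_hc: tuple = (63.5, 6.5)
    male_frac_pd: float = 15 / 22
    male_frac_hc: float = 26 / 39
    education_pd: tuple = (15.8, 2.7)    # years
    education_hc: tuple = (16.7, 2.8)
    dat_pd: tuple = (-3.6, 0.7)          # putaminal DaT z-score (PD only)
    pa_location_scale: tuple = (math.log(58.3), 0.85)  # log-normal WEE
    sequence_probs: tuple = (4 / 22, 17 / 22, 1 / 22)

    # block-correlation structure of the synthetic time series
    within_base: float = 0.30            # centre of the within-subnetwork r tiers
    between_base: float = 0.05           # baseline between/unlabelled r
    tier_gap: float = 0.10               # core minus periphery coupling
    dat_to_smn_coupling: float = 0.08    # d r_periphery / d DaT-z within SMN
    edu_to_atn_coupling: float = 0.02    # d r_periphery / d education-year, ATN

    # planted NAT -> motor-behavior structure. Between-participant spread of
    # mean NAT is small (~0.01), so the ability slope per unit NAT is large,
    # exactly as in empirical NAT-behavior regressions.
    ability_intercept: float = -109.0
    nat_to_gmp_slope: float = 250.0      # latent ability per unit NAT
    pa_moderation_knot: float = 45.0     # WEE value where moderation saturates
    pa_moderation_slope: float = -0.15   # per WEE unit per unit NAT
    noise_sd: float = 1.0
    n_gcp_missing: int = 1               # PD participants with missing cognition
    seed: int = 0

    def __post_init__(self):
        if self.n_pd <= 0 or self.n_hc <= 0:
            raise ConfigurationError("group sizes must be positive")
        for name in ("age_pd", "age_hc", "education_pd", "education_hc", "dat_pd"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ConfigurationError(f"{name} spread must be nonnegative")
        if self.pa_location_scale[1] < 0 or self.noise_sd < 0:
            raise ConfigurationError("scale parameters must be nonnegative")
        for frac in (self.male_frac_pd, self.male_frac_hc):
            if not 0 <= frac <= 1:
                raise ConfigurationError("sex fractions must lie in [0, 1]")
        if len(self.sequence_probs) != 3 or abs(sum(self.sequence_probs) - 1) > 1e-9:
            raise ConfigurationError("sequence_probs must be 3 probabilities summing to 1")
        if not 0 <= self.between_base <= self.within_base <= 0.9:
            raise ConfigurationError("require 0 <= between_base <= within_base <= 0.9")
        if not 0 <= self.tier_gap <= self.within_base:
            raise ConfigurationError("tier_gap must lie in [0, within_base]")
        if not 0 <= self.n_gcp_missing <= self.n_pd:
            raise ConfigurationError("n_gcp_missing out of range")


@dataclass(frozen=True)
class ParticipantProfile:
    """Covariates for one participant; PD profiles carry a DaT z-score."""

    id: str
    index: int                 # stable 0-based cohort position (seeds sub-streams)
    group: str                 # "PD" or "HC"
    age: float
    sex: str                   # "f" or "m"
    education: float
    pa: float                  # lifetime PA, WEE units
    sequence: int              # fMRI sequence id in {1, 2, 3}
    putaminal_dat: float | None = None

    def __post_init__(self):
        if self.group not in ("PD", "HC"):
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.group == "PD" and self.putaminal_dat is None:
            raise ConfigurationError("PD profiles require a DaT z-score")
        if self.group == "HC" and self.putaminal_dat is not None:
            raise ConfigurationError("HC profiles carry no DaT z-score")
        if self.sequence not in SEQUENCE_VOLUMES:
            raise ConfigurationError(f"unknown sequence id {self.sequence}")

    @property
    def n_volumes(self) -> int:
        return SEQUENCE_VOLUMES[self.sequence]


def _profile_rng(config: CohortConfig, profile_index: int, stream: int):
    """Independent, order-insensitive random stream per profile and stage."""
    return np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, stream, profile_index])
    )


def _allocate_sequences(n: int, probs, rng) -> np.ndarray:
    """Sequence ids hitting the target proportions as exactly as possible.

    Counts are the largest-remainder apportionment of ``n * probs`` (so the
    study's 4/17/1 split is reproduced exactly at n = 22), then randomly
    permuted across participants.
    """
    probs = np.asarray(probs, float)
    counts = np.floor(n * probs).astype(int)
    remainder = n * probs - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    seqs = np.repeat([1, 2, 3], counts)
    return rng.permutation(seqs)


def generate_cohort(config: CohortConfig) -> list:
    """Draw the participant table: n_pd PD + n_hc HC profiles.

    Reproducible under a fixed ``config.seed``; zero spreads produce
    degenerate (constant) covariates.
    """
    rng = np.random.default_rng(config.seed)
    profiles = []
    idx = 0
    for group, n in (("PD", config.n_pd), ("HC", config.n_hc)):
        sequences = _allocate_sequences(n, config.sequence_probs, rng)
        age_m, age_s = config.age_pd if group == "PD" else config.age_hc
        edu_m, edu_s = config.education_pd if group == "PD" else config.education_hc
        male_frac = config.male_frac_pd if group == "PD" else config.male_frac_hc
        for i in range(n):
            dat = None
            if group == "PD":
                dat = float(rng.normal(*config.dat_pd)) if config.dat_pd[1] > 0 \
                    else config.dat_pd[0]
            loc, scale = config.pa_location_scale
            pa = float(rng.lognormal(loc, scale)) if scale > 0 else math.exp(loc)
            profiles.append(
                ParticipantProfile(
                    id=f"{group}{i + 1:02d}",
                    index=idx,
                    group=group,
                    age=float(rng.normal(age_m, age_s)) if age_s > 0 else age_m,
                    sex="m" if rng.random() < male_frac else "f",
                    education=float(rng.normal(edu_m, edu_s)) if edu_s > 0 else edu_m,
                    pa=pa,
                    sequence=int(sequences[i]),
                    putaminal_dat=dat,
                )
            )
            idx += 1
    return profiles


def profiles_frame(profiles) -> pd.DataFrame:
    """Tabulate profiles as a DataFrame (HC rows carry NaN DaT)."""
    return pd.DataFrame(
        {
            "participant": [p.id for p in profiles],
            "group": [p.group for p in profiles],
            "age": [p.age for p in profiles],
            "sex": [p.sex for p in profiles],
            "education": [p.education for p in profiles],
            "dat": [np.nan if p.putaminal_dat is None else p.putaminal_dat
                    for p in profiles],
            "pa": [p.pa for p in profiles],
            "sequence": [p.sequence for p in profiles],
            "n_volumes": [p.n_volumes for p in profiles],
        }
    )


# ---------------------------------------------------------------------------
# ROI time series
# ---------------------------------------------------------------------------

def _block_correlation(profile: ParticipantProfile, atlas: ROIAtlas,
                       config: CohortConfig) -> np.ndarray:
    """Target ROI correlation matrix with two-tier subnetwork blocks.

    Each subnetwork splits into a core (first half of its members, coupling
    ``within_base + tier_gap/2``) and a periphery whose coupling starts at
    ``within_base - tier_gap/2`` and rises with the planted covariate
    effect, clipped to [between_base, core level]. The matrix equals a
    factor-model covariance (global factor + block factor + core factor +
    diagonal residual), so it is positive semi-definite by construction and
    Cholesky sampling always succeeds.
    """
    n = atlas.n_rois
    r0 = config.between_base
    corr = np.full((n, n), r0)
    r_core = float(np.clip(config.within_base + config.tier_gap / 2, r0, 0.9))
    for net in SUBNETWORKS:
        members = atlas.members(net)
        if len(members) == 0:
            continue
        effect = 0.0
        if net == "SMN" and profile.putaminal_dat is not None:
            effect = config.dat_to_smn_coupling * (
                profile.putaminal_dat - config.dat_pd[0])
        if net == "ATN":
            effect = config.edu_to_atn_coupling * (
                profile.education - config.education_pd[0])
        r_periph = float(np.clip(
            config.within_base - config.tier_gap / 2 + effect, r0, r_core))
        corr[np.ix_(members, members)] = r_periph
        core = members[: (len(members) + 1) // 2]
        corr[np.ix_(core, core)] = r_core
    np.fill_diagonal(corr, 1.0)
    return corr


def generate_timeseries(profile: ParticipantProfile, atlas: ROIAtlas,
                        config: CohortConfig, rng=None) -> np.ndarray:
    """Sample an (n_rois, n_volumes) BOLD-like series for one participant.

    Multivariate normal draws with the block correlation structure of
    :func:`_block_correlation`, riding on a baseline level of 100 so the
    temporal signal-to-noise ratio is on a realistic scale. Series length
    follows the profile's fMRI sequence (740/500/740 volumes).
    """
    if len(set(atlas.roi_ids)) != atlas.n_rois:
        raise DomainError("atlas with duplicate ROIs")
    if rng is None:
        rng = _profile_rng(config, profile.index, stream=1)
    corr = _block_correlation(profile, atlas, config)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((profile.n_volumes, atlas.n_rois))
    series = 100.0 + z @ chol.T
    return np.ascontiguousarray(series.T)


# ---------------------------------------------------------------------------
# Behavior: test batteries and activity diaries
# ---------------------------------------------------------------------------

#: (name, kind, direction, HC mean, HC sd, ability loading in sd units)
TEST_BATTERY = (
    ("grip_strength", "motor", "higher_better", 32.0, 8.0, 0.5),
    ("finger_tapping", "motor", "higher_better", 55.0, 8.0, 0.5),
    ("pegboard", "motor", "higher_better", 12.0, 2.0, 0.5),
    ("hand_function_time", "motor", "lower_better", 35.0, 6.0, 0.5),
    ("timed_up_and_go", "motor", "lower_better", 9.0, 2.0, 0.5),
    ("cognitive_screening", "cognitive", "higher_better", 50.0, 5.0, 0.5),
    ("demtect", "cognitive", "higher_better", 15.0, 2.5, 0.5),
    ("trails_a_time", "cognitive", "lower_better", 35.0, 10.0, 0.5),
    ("trails_b_time", "cognitive", "lower_better", 80.0, 25.0, 0.5),
)

_DIRECTIONS = {t[0]: t[2] for t in TEST_BATTERY}
_KINDS = {t[0]: t[1] for t in TEST_BATTERY}


def motor_ability(profile: ParticipantProfile, nat_global: float,
                  config: CohortConfig) -> float:
    """Noise-free latent motor ability under the planted model.

    PD only: intercept + slope * NAT + moderation * NAT * min(PA, knot).
    The moderation term is frozen at its knot value for PA above the knot.
    HC ability is centred at zero (no NAT coupling).
    """
    if profile.group == "HC":
        return 0.0
    return (
        config.ability_intercept
        + config.nat_to_gmp_slope * nat_global
        + config.pa_moderation_slope * nat_global * min(profile.pa, config.pa_moderation_knot)
    )


def generate_behavior(profile: ParticipantProfile, nat_global: float,
                      config: CohortConfig, rng=None) -> TestBatteryResult:
    """Raw motor/cognitive test scores for one participant.

    Motor scores load on the latent ability of :func:`motor_ability`
    (duration tests decrease as ability increases); cognitive scores are
    generated independently of NAT. All noise scales with
    ``config.noise_sd``, so a zero setting yields deterministic scores.
    """
    if not 0.0 < nat_global < 1.0:
        raise DomainError(f"nat_global must lie strictly in (0, 1), got {nat_global}")
    if rng is None:
        rng = _profile_rng(config, profile.index, stream=2)
    a_motor = motor_ability(profile, nat_global, config) + \
        config.noise_sd * rng.standard_normal()
    a_cog = config.noise_sd * rng.standard_normal()
    scores = {}
    for name, kind, direction, mean, sd, loading in TEST_BATTERY:
        a = a_motor if kind == "motor" else a_cog
        delta = sd * (loading * a + 0.8 * config.noise_sd * rng.standard_normal())
        scores[name] = mean + (-delta if direction == "lower_better" else delta)
    return TestBatteryResult(
        participant=profile.id, scores=scores,
        directions=dict(_DIRECTIONS), kinds=dict(_KINDS),
    )


def generate_batteries(profiles, nat_by_participant: dict,
                       config: CohortConfig) -> list:
    """Batteries for a whole cohort, marking the first ``n_gcp_missing`` PD
    participants' cognitive tests as missing (emulating incomplete testing)."""
    out = []
    n_missing = 0
    for p in profiles:
        batt = generate_behavior(p, nat_by_participant[p.id], config)
        if p.group == "PD" and n_missing < config.n_gcp_missing:
            scores = dict(batt.scores)
            for t, kind in _KINDS.items():
                if kind == "cognitive":
                    scores[t] = np.nan
            batt = replace(batt, scores=scores)
            n_missing += 1
        out.append(batt)
    return out


def batteries_frame(batteries) -> pd.DataFrame:
    rows = [{"participant": b.participant, **b.scores} for b in batteries]
    return pd.DataFrame(rows)


def generate_diary(profile: ParticipantProfile, config: CohortConfig,
                   rng=None) -> pd.DataFrame:
    """Long-format activity diary whose lifetime PA equals ``profile.pa``.

    The two scored periods (19-35 and 35-50) each carry one year-round
    activity at MET 4 with weekly hours chosen so the period WEE equals the
    profile's PA score; the unscored periods (12-19 and 50+) get decorative
    entries that the scoring stage must ignore.
    """
    if rng is None:
        rng = _profile_rng(config, profile.index, stream=3)
    rows = []
    for period, span in (("19-35", 16.0), ("35-50", 15.0)):
        rows.append(
            dict(participant=profile.id, period=period, activity="cycling",
                 met=4.0, years=span, months_per_year=12.0,
                 hours_per_week=profile.pa / 4.0)
        )
    rows.append(
        dict(participant=profile.id, period="12-19", activity="school_sports",
             met=6.0, years=7.0, months_per_year=9.0,
             hours_per_week=float(rng.uniform(0, 4)))
    )
    rows.append(
        dict(participant=profile.id, period="50+", activity="walking",
             met=3.0, years=2.0, months_per_year=12.0,
             hours_per_week=float(rng.uniform(0, 3)))
    )
    return pd.DataFrame(rows)
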