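"""Lifestyle and performance scores: lifetime physical activity and composites.

Lifetime physical activity (PA) is quantified from a historical leisure
activity diary as a weekly energy expenditure (WEE) score per life period:

    WEE_period = sum_i  (years_i * months_i * weekly_hours_i)
                        / (12 * years_period)  * MET_i

i.e. the MET-weighted average weekly hours over all activities reported in
that period. Lifetime PA is the mean of the WEE scores for the 19-35 and
35-50 year periods; the earliest (12-19, recall bias) and latest (50+,
post-diagnosis) periods are recorded but never enter the score.

Motor and cognitive test batteries are reduced to composite z-scores (GMP,
general motor performance; GCP, general cognitive performance) referenced
to the healthy-control sample: per test, patient raw scores are
z-standardized against the HC mean and (n-1) SD; duration-type tests, where
longer times mean poorer performance, are sign-inverted before
standardization; the per-test z-scores are then summed within domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, DomainError

#: Life periods of the activity diary and their spans in years.
PERIOD_SPANS = {"12-19": 7.0, "19-35": 16.0, "35-50": 15.0, "50+": None}

#: Periods that enter the lifetime PA score.
SCORED_PERIODS = ("19-35", "35-50")


@dataclass(frozen=True)
class ActivityEntry:
    """One diary line: an activity performed regularly within a life period."""

    activity: str
    met: float               # metabolic-equivalent intensity weight
    years: float             # years active within the period
    months_per_year: float
    hours_per_week: float
    period: str = "19-35"

    def __post_init__(self):
        if self.period not in PERIOD_SPANS:
            raise DomainError(f"unknown diary period: {self.period!r}")
        for name in ("met", "years", "months_per_year", "hours_per_week"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be nonnegative")
        if self.months_per_year > 12:
            raise DomainError("months_per_year cannot exceed 12")
        span = PERIOD_SPANS[self.period]
        if span is not None and self.years > span + 1e-9:
            raise DomainError(
                f"years active ({self.years}) exceeds the {self.period} span ({span})"
            )


@dataclass(frozen=True)
class PeriodWEE:
    """Weekly energy expenditure (MET-hours/week) for one life period."""

    period: str
    years_period: float
    wee: float

    def __post_init__(self):
        if self.wee < 0:
            raise DomainError("WEE cannot be negative")


def period_wee(entries, years_period: float, period: str = "19-35") -> PeriodWEE:
    """Weekly energy expenditure over all activities of one period.

    Each activity contributes its MET score times its average weekly hours,
    where the average spreads ``years * months_per_year * hours_per_week``
    over the whole period (``12 * years_period`` months). An empty diary
    scores zero.
    """
    if years_period <= 0:
        raise DomainError("years_period must be positive")
    total = 0.0
    for e in entries:
        if e.period != period:
            raise ContractError(
                f"entry for period {e.period!r} passed to period_wee({period!r})"
            )
        total += (e.years * e.months_per_year * e.hours_per_week) / (
            12.0 * years_period
        ) * e.met
    return PeriodWEE(period=period, years_period=years_period, wee=total)


def lifetime_pa(wee_19_35: PeriodWEE | None, wee_35_50: PeriodWEE | None) -> float:
    """Lifetime physical activity: mean WEE of the 19-35 and 35-50 periods."""
    if wee_19_35 is None or wee_35_50 is None:
        raise ContractError("both the 19-35 and 35-50 period WEE scores are required")
    return 0.5 * (wee_19_35.wee + wee_35_50.wee)


def lifetime_pa_from_diary(diary: pd.DataFrame) -> pd.Series:
    """Lifetime PA per participant from a long-format diary table.

    Expects columns participant, period, activity, met, years,
    months_per_year, hours_per_week. Periods outside 19-35/35-50 are parsed
    (validated) but excluded from the score, matching the diary protocol.
    """
    scores = {}
    for pid, sub in diary.groupby("participant", sort=True):
        per_period = {}
        for per in SCORED_PERIODS:
            rows = sub[sub["period"] == per]
            entries = [
                ActivityEntry(
                    activity=str(r.activity), met=float(r.met), years=float(r.years),
                    months_per_year=float(r.months_per_year),
                    hours_per_week=float(r.hours_per_week), period=per,
                )
                for r in rows.itertuples()
            ]
            per_period[per] = period_wee(entries, PERIOD_SPANS[per], period=per)
        scores[pid] = lifetime_pa(per_period["19-35"], per_period["35-50"])
    return pd.Series(scores, name="pa")


# ---------------------------------------------------------------------------
# Test batteries and composite scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestBatteryResult:
    """Raw motor/cognitive test scores for one participant.

    ``directions`` flags each test ``higher_better`` or ``lower_better``
    (durations); ``kinds`` assigns each test to the ``motor`` or
    ``cognitive`` composite.
    """

    __test__ = False  # despite the name, not a pytest class

    participant: str
    scores: dict = field(default_factory=dict)
    directions: dict = field(default_factory=dict)
    kinds: dict = field(default_factory=dict)

    def __post_init__(self):
        for t in self.scores:
            if self.directions.get(t) not in ("higher_better", "lower_better"):
                raise ContractError(f"test {t!r} lacks a valid direction flag")
            if self.kinds.get(t) not in ("motor", "cognitive"):
                raise ContractError(f"test {t!r} lacks a valid kind")


@dataclass(frozen=True)
class CompositeScore:
    """Composite z-scores for one participant, referenced to the HC sample."""

    participant: str
    gmp: float
    gcp: float
    per_test_z: dict


def composite_scores(target_batteries, hc_batteries, mode: str = "sum"):
    """Composite motor/cognitive performance z-scores against an HC reference.

    Per test, raw scores (sign-inverted first for ``lower_better`` tests)
    are standardized by the HC mean and unbiased SD; per-participant
    z-scores are then combined (summed by default) into GMP over motor
    tests and GCP over cognitive tests. Tests with zero HC variance are
    excluded with a warning. Missing raw scores propagate to NaN
    composites.

    Parameters
    ----------
    target_batteries, hc_batteries : iterable of TestBatteryResult
        Scored participants and the healthy-control reference sample.
    mode : {"sum", "mean"}
        How per-test z-scores are combined within a domain.
    """
    if mode not in ("sum", "mean"):
        raise ContractError(f"unknown composite mode: {mode!r}")
    hc_batteries = list(hc_batteries)
    target_batteries = list(target_batteries)
    if not hc_batteries:
        raise ContractError("HC reference sample is empty")

    tests = dict(hc_batteries[0].directions)
    kinds = dict(hc_batteries[0].kinds)

    def signed(batt, t):
        raw = batt.scores.get(t, np.nan)
        return -raw if tests[t] == "lower_better" else raw

    ref = {}
    for t in tests:
        vals = np.array([signed(b, t) for b in hc_batteries], float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2 or np.std(vals, ddof=1) == 0:
            warnings.warn(
                f"test {t!r} has zero variance in the HC reference; excluded",
                stacklevel=2,
            )
            continue
        ref[t] = (vals.mean(), np.std(vals, ddof=1))

    out = []
    for b in target_batteries:
        z = {t: (signed(b, t) - m) / s for t, (m, s) in ref.items()}
        combine = np.sum if mode == "sum" else np.mean
        motor = [z[t] for t in ref if kinds[t] == "motor"]
        cog = [z[t] for t in ref if kinds[t] == "cognitive"]
        out.append(
            CompositeScore(
                participant=b.participant,
                gmp=float(combine(motor)) if motor else np.nan,
                gcp=float(combine(cog)) if cog else np.nan,
                per_test_z=z,
            )
        )
    return out


def composites_frame(composites) -> pd.DataFrame:
    """Tabulate CompositeScores as a DataFrame indexed by participant."""
    return pd.DataFrame(
        {
            "participant": [c.participant for c in composites],
            "gmp": [c.gmp for c in composites],
            "gcp": [c.gcp for c in composites],
        }
    ).set_index("participant")
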