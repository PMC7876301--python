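"""End-tidal stimulus traces for the three respiratory challenge designs.

Three gas-challenge paradigms are modelled, each defined by its end-tidal
partial-pressure targets (mmHg) and block timing:

* ``BLOCK_HC`` — a boxcar hypercapnic step: pre-baseline, a 90 s CO2 step of
  about +8 mmHg, post-baseline.
* ``RAMP_HC`` — 60 s of mild hypocapnia followed by a 5-minute linear rise of
  end-tidal CO2 up to roughly +16 mmHg above baseline, then back to baseline.
* ``BLOCK_BOOST`` — the hypercapnic boxcar with a simultaneous large hyperoxic
  step (about +159 mmHg O2) acting as an endogenous bolus-arrival contrast.

Traces are emitted as per-breath samples. Transitions are idealized as
single-breath steps: a prospective gas-targeting system reaches its end-tidal
targets within a few breaths, and this generator treats that as instantaneous,
leaving physiological smoothing to the phantom's dispersion kernel.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .errors import InvalidSpecError


class Paradigm(enum.Enum):
    BLOCK_HC = "block"
    RAMP_HC = "ramp"
    BLOCK_BOOST = "boost"


#: Duration of the initial hypocapnic plateau inside the RAMP stimulus window.
RAMP_HYPO_S = 60.0


@dataclass(frozen=True)
class ParadigmSpec:
    """Timing and end-tidal targets of one respiratory challenge.

    Pressures are mmHg, durations seconds. ``delta_co2`` is the excursion of
    the stimulus plateau (BLOCK) or ramp end point (RAMP) above baseline;
    ``hypo_delta_co2`` (RAMP only, <= 0) is the hypocapnic excursion;
    ``delta_o2`` (BOOST only) is the hyperoxic step.
    """

    kind: Paradigm
    baseline_co2: float = 36.0
    delta_co2: float = 8.0
    hypo_delta_co2: float = 0.0
    baseline_o2: float = 113.0
    delta_o2: float = 0.0
    pre_baseline_s: float = 120.0
    stimulus_s: float = 90.0
    post_baseline_s: float = 120.0
    breath_period_s: float = 3.0

    def __post_init__(self) -> None:
        for name in ("pre_baseline_s", "stimulus_s", "post_baseline_s", "breath_period_s"):
            if not getattr(self, name) > 0:
                raise InvalidSpecError(f"{name} must be positive")
        if self.baseline_co2 <= 0 or self.baseline_o2 <= 0:
            raise InvalidSpecError("baseline pressures must be positive")
        if self.kind is not Paradigm.BLOCK_BOOST and self.delta_o2 != 0:
            raise InvalidSpecError("delta_o2 is only meaningful for BLOCK_BOOST")
        if self.kind is Paradigm.RAMP_HC:
            if self.hypo_delta_co2 > 0:
                raise InvalidSpecError("hypo_delta_co2 must be <= 0")
            if self.stimulus_s <= RAMP_HYPO_S:
                raise InvalidSpecError(
                    f"RAMP stimulus must exceed the {RAMP_HYPO_S:.0f} s hypocapnic plateau"
                )
        elif self.hypo_delta_co2 != 0:
            raise InvalidSpecError("hypo_delta_co2 is only meaningful for RAMP_HC")

    @property
    def total_s(self) -> float:
        return self.pre_baseline_s + self.stimulus_s + self.post_baseline_s


def block_hc(**overrides) -> ParadigmSpec:
    """Boxcar hypercapnia: +8 mmHg CO2 for 90 s, ~330 s total scan."""
    kw = dict(kind=Paradigm.BLOCK_HC, baseline_co2=36.0, delta_co2=8.0,
              pre_baseline_s=120.0, stimulus_s=90.0, post_baseline_s=120.0)
    kw.update(overrides)
    return ParadigmSpec(**kw)


def ramp_hc(**overrides) -> ParadigmSpec:
    """Hypocapnia then progressive hypercapnia: 60 s at -4 mmHg, 300 s linear
    rise to +16 mmHg; 507 s total scan."""
    kw = dict(kind=Paradigm.RAMP_HC, baseline_co2=35.0, delta_co2=16.0,
              hypo_delta_co2=-4.0, pre_baseline_s=87.0, stimulus_s=360.0,
              post_baseline_s=60.0)
    kw.update(overrides)
    return ParadigmSpec(**kw)


def block_boost(**overrides) -> ParadigmSpec:
    """Hypercapnic boxcar with a simultaneous +159 mmHg hyperoxic step."""
    kw = dict(kind=Paradigm.BLOCK_BOOST, baseline_co2=39.0, delta_co2=8.0,
              baseline_o2=111.0, delta_o2=159.0,
              pre_baseline_s=120.0, stimulus_s=90.0, post_baseline_s=120.0)
    kw.update(overrides)
    return ParadigmSpec(**kw)


PARADIGM_FACTORIES = {
    Paradigm.BLOCK_HC: block_hc,
    Paradigm.RAMP_HC: ramp_hc,
    Paradigm.BLOCK_BOOST: block_boost,
}


@dataclass
class EndTidalTrace:
    """Per-breath end-tidal CO2/O2 partial pressures (mmHg) over time (s)."""

    breath_times: np.ndarray
    petco2: np.ndarray
    peto2: np.ndarray

    def __post_init__(self) -> None:
        self.breath_times = np.asarray(self.breath_times, dtype=float)
        self.petco2 = np.asarray(self.petco2, dtype=float)
        self.peto2 = np.asarray(self.peto2, dtype=float)
        if not (len(self.breath_times) == len(self.petco2) == len(self.peto2)):
            raise InvalidSpecError("trace arrays must have equal length")
        if len(self.breath_times) < 2:
            raise InvalidSpecError("trace needs at least two breaths")
        if not np.all(np.diff(self.breath_times) > 0):
            raise InvalidSpecError("breath times must be strictly increasing")
        for arr, name in ((self.petco2, "petco2"), (self.peto2, "peto2")):
            if not np.all(np.isfinite(arr)) or not np.all(arr > 0):
                raise InvalidSpecError(f"{name} must be finite and positive")

    @property
    def span_s(self) -> float:
        return float(self.breath_times[-1])

    def __len__(self) -> int:
        return len(self.breath_times)


def make_trace(spec: ParadigmSpec) -> EndTidalTrace:
    """Generate the per-breath end-tidal trace for a paradigm.

    Samples are placed every ``breath_period_s`` from 0 through the end of the
    post-baseline. The stimulus occupies the half-open window
    ``[pre_baseline_s, pre_baseline_s + stimulus_s)``; a RAMP stimulus starts
    with a hypocapnic plateau and then rises linearly to its peak excursion,
    returning to baseline in a single breath.
    """
    t = np.arange(0.0, spec.total_s + spec.breath_period_s / 2, spec.breath_period_s)
    co2 = np.full_like(t, spec.baseline_co2)
    o2 = np.full_like(t, spec.baseline_o2)
    t0, t1 = spec.pre_baseline_s, spec.pre_baseline_s + spec.stimulus_s
    in_stim = (t >= t0) & (t < t1)

    if spec.kind in (Paradigm.BLOCK_HC, Paradigm.BLOCK_BOOST):
        co2[in_stim] = spec.baseline_co2 + spec.delta_co2
        if spec.kind is Paradigm.BLOCK_BOOST:
            o2[in_stim] = spec.baseline_o2 + spec.delta_o2
    else:  # RAMP_HC
        hypo = in_stim & (t < t0 + RAMP_HYPO_S)
        ramp = in_stim & ~hypo
        co2[hypo] = spec.baseline_co2 + spec.hypo_delta_co2
        frac = (t[ramp] - (t0 + RAMP_HYPO_S)) / (spec.stimulus_s - RAMP_HYPO_S)
        co2[ramp] = spec.baseline_co2 + spec.hypo_delta_co2 + frac * (
            spec.delta_co2 - spec.hypo_delta_co2
        )

    return EndTidalTrace(breath_times=t, petco2=co2, peto2=o2)
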