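"""Behavioral scalar scores: PTZ seizure susceptibility and prepulse inhibition.

Seizure staging after pentylenetetrazole (a GABA_A antagonist): stage 1,
behavioral arrest; stage 2, myoclonic (jerk) seizures; stage 3, generalized
tonic-clonic seizures; an optional stage-4 death category carries no latency
arithmetic.  The susceptibility score weights the reciprocal latencies
0.2 / 0.3 / 0.5 for stages 1–3; a stage never reached contributes 0 (the
limit of 1/latency as latency grows without bound).

Prepulse inhibition: 100 − (mean prepulse response / mean pulse response) × 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SeizureRecord",
    "StartleBlock",
    "seizure_susceptibility_score",
    "stage_summary",
    "ppi_percent",
]

STAGE_WEIGHTS = {1: 0.2, 2: 0.3, 3: 0.5}


@dataclass(frozen=True)
class SeizureRecord:
    """Per-animal staged-seizure observations over a 30-min session."""

    latency_s: Mapping[int, float]  # stage -> latency; absent = never reached
    stage2_events: tuple[tuple[float, float], ...] = ()  # (onset_s, duration_s)
    observation_s: float = 1800.0
    animal_id: Optional[str] = None
    group: Optional[str] = None
    died: bool = False  # stage-4 category; no latency arithmetic

    def __post_init__(self) -> None:
        lat = dict(self.latency_s)
        for stage, t in lat.items():
            if stage not in STAGE_WEIGHTS:
                raise ValueError(f"unknown seizure stage {stage}")
            if not 0 < t <= self.observation_s:
                raise ValueError(f"latency {t}s for stage {stage} outside (0, {self.observation_s}]")
        present = sorted(lat)
        if any(lat[a] > lat[b] for a, b in zip(present, present[1:])):
            raise ValueError("stage latencies must be non-decreasing with stage")
        object.__setattr__(self, "latency_s", lat)
        object.__setattr__(self, "stage2_events", tuple(tuple(e) for e in self.stage2_events))

    @property
    def final_stage(self) -> int:
        if self.died:
            return 4
        return max(self.latency_s, default=0)


@dataclass(frozen=True)
class StartleBlock:
    """Startle-chamber responses: pulse-alone trials and per-level prepulse trials."""

    pulse_responses: tuple[float, ...]
    prepulse_responses: Mapping[float, tuple[float, ...]]

    def __post_init__(self) -> None:
        if not self.pulse_responses:
            raise ValueError("pulse_responses must be non-empty")
        pp = {k: tuple(v) for k, v in self.prepulse_responses.items()}
        if any(not v for v in pp.values()):
            raise ValueError("each reported prepulse level needs at least one trial")
        object.__setattr__(self, "pulse_responses", tuple(self.pulse_responses))
        object.__setattr__(self, "prepulse_responses", pp)


def seizure_susceptibility_score(rec: SeizureRecord) -> float:
    """0.2/latency(stage1) + 0.3/latency(stage2) + 0.5/latency(stage3).

    Stages never reached contribute 0.  Latencies are in seconds; at least
    one stage must have been reached.
    """
    if not rec.latency_s:
        raise ValueError("at least one stage must be reached to score")
    return sum(w / rec.latency_s[s] for s, w in STAGE_WEIGHTS.items() if s in rec.latency_s)


def stage_summary(records: Sequence[SeizureRecord]) -> pd.DataFrame:
    """Per-animal staging table: final stage, stage-2 latency, event frequency
    (events per observation period) and total stage-2 duration, plus the
    susceptibility score."""
    rows = []
    for i, r in enumerate(records):
        rows.append(
            {
                "animal_id": r.animal_id if r.animal_id is not None else str(i),
                "group": r.group,
                "final_stage": r.final_stage,
                "reached_stage2": 2 in r.latency_s,
                "stage2_latency_s": r.latency_s.get(2, np.nan),
                "stage2_frequency": float(len(r.stage2_events)),
                "stage2_total_duration_s": float(sum(d for _, d in r.stage2_events)),
                "susceptibility_score": (
                    seizure_susceptibility_score(r) if r.latency_s else np.nan
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "animal_id",
            "group",
            "final_stage",
            "reached_stage2",
            "stage2_latency_s",
            "stage2_frequency",
            "stage2_total_duration_s",
            "susceptibility_score",
        ],
    )


def ppi_percent(block: StartleBlock, prepulse_db: float) -> float:
    """Prepulse inhibition at one prepulse level, in percent."""
    if prepulse_db not in block.prepulse_responses:
        raise KeyError(f"no prepulse trials at {prepulse_db} dB")
    pulse_mean = float(np.mean(block.pulse_responses))
    if pulse_mean <= 0:
        raise ValueError("mean pulse response must be positive")
    pp_mean = float(np.mean(block.prepulse_responses[prepulse_db]))
    return 100.0 - (pp_mean / pulse_mean) * 100.0
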