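"""Experimental designs: stimulus sets and trial schedules.

Two Pavlovian fear-conditioning designs are encoded here.  Experiment 1 is
simple conditioning over seven circles (S4..S10) with the middle circle S7
(96.54 mm) as CS+; Experiment 2 is differential conditioning over all ten
circles with the smallest/largest circle (50.80 / 119.42 mm) as CS+ and CS-,
counterbalanced.  Circle diameters run from 50.80 to 119.42 mm in constant
steps of 7.624 mm.

Only trial counts and the consecutive CS+ runs that open each generalization
block are fixed by the designs; the interleaving of the remaining trials and
the placement of reinforced CS+ trials are seeded permutations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DIAMETER_MIN_MM = 50.80
DIAMETER_STEP_MM = 7.624
N_STIMULI = 10

#: CS+ reinforcement rate during acquisition, per experiment.
REINFORCEMENT_RATE = {1: 0.50, 2: 0.83}


class Role(str, enum.Enum):
    CS_PLUS = "CS_PLUS"
    CS_MINUS = "CS_MINUS"
    TS = "TS"
    UNUSED = "UNUSED"


class Phase(str, enum.Enum):
    ACQUISITION = "ACQUISITION"
    GENERALIZATION = "GENERALIZATION"


@dataclass(frozen=True)
class StimulusSet:
    """The circle stimuli of one experiment: labels, diameters, CS roles."""

    experiment: int
    labels: tuple[str, ...]
    diameters_mm: dict[str, float]
    roles: dict[str, Role]

    @property
    def cs_plus(self) -> str:
        return next(s for s, r in self.roles.items() if r is Role.CS_PLUS)

    @property
    def cs_minus(self) -> str | None:
        return next((s for s, r in self.roles.items() if r is Role.CS_MINUS), None)

    @property
    def ts_labels(self) -> tuple[str, ...]:
        return tuple(s for s in self.labels if self.roles[s] is Role.TS)

    def diameter(self, label: str) -> float:
        return self.diameters_mm[label]


@dataclass(frozen=True)
class TrialEntry:
    phase: Phase
    block: int
    stimulus: str
    reinforced: bool
    k: int  # learning-update indicator: 1 on CS trials, 0 on TS trials
    r: int  # outcome: CS+ 1/0 (US present/absent); CS- always -1; TS 0


@dataclass
class TrialSchedule:
    """Ordered trial list for one participant of one experiment."""

    experiment: int
    stimuli: StimulusSet
    entries: list[TrialEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self, participant: int = 0) -> pd.DataFrame:
        """Long-format trial table (one row per trial)."""
        rows = []
        for j, e in enumerate(self.entries):
            rows.append(
                {
                    "participant": participant,
                    "trial": j,
                    "phase": e.phase.value,
                    "block": e.block,
                    "stimulus": e.stimulus,
                    "diameter_mm": self.stimuli.diameter(e.stimulus),
                    "role": self.stimuli.roles[e.stimulus].value,
                    "reinforced": int(e.reinforced),
                    "k": e.k,
                    "r": e.r,
                }
            )
        return pd.DataFrame(rows)


def stimulus_labels() -> list[str]:
    return [f"S{i}" for i in range(1, N_STIMULI + 1)]


def stimulus_diameters() -> dict[str, float]:
    return {
        f"S{i}": DIAMETER_MIN_MM + (i - 1) * DIAMETER_STEP_MM
        for i in range(1, N_STIMULI + 1)
    }


def make_stimulus_set(experiment: int, counterbalance: str = "A") -> StimulusSet:
    """Build the stimulus set for an experiment.

    Parameters
    ----------
    experiment:
        1 (simple conditioning, S4..S10, CS+ = S7) or 2 (differential
        conditioning, S1..S10, CS+/CS- at the extremes).
    counterbalance:
        'A' (S1 = CS+, S10 = CS-) or 'B' (reversed); ignored for experiment 1.
    """
    if experiment not in (1, 2):
        raise ValueError(f"experiment must be 1 or 2, got {experiment!r}")
    if counterbalance not in ("A", "B"):
        raise ValueError(f"counterbalance must be 'A' or 'B', got {counterbalance!r}")
    labels = tuple(stimulus_labels())
    diam = stimulus_diameters()
    roles: dict[str, Role] = {}
    if experiment == 1:
        for s in labels:
            i = int(s[1:])
            if i < 4:
                roles[s] = Role.UNUSED
            elif s == "S7":
                roles[s] = Role.CS_PLUS
            else:
                roles[s] = Role.TS
    else:
        plus, minus = ("S1", "S10") if counterbalance == "A" else ("S10", "S1")
        for s in labels:
            if s == plus:
                roles[s] = Role.CS_PLUS
            elif s == minus:
                roles[s] = Role.CS_MINUS
            else:
                roles[s] = Role.TS
    return StimulusSet(experiment, labels, diam, roles)


def _reinforced_positions(rng: np.random.Generator, n: int, n_reinforced: int) -> set[int]:
    return set(rng.choice(n, size=n_reinforced, replace=False).tolist())


def _cs_entry(phase: Phase, block: int, label: str, role: Role, reinforced: bool) -> TrialEntry:
    if role is Role.CS_PLUS:
        return TrialEntry(phase, block, label, reinforced, k=1, r=int(reinforced))
    if role is Role.CS_MINUS:
        # the no-US outcome on CS- trials carries the inhibitory signal
        return TrialEntry(phase, block, label, False, k=1, r=-1)
    return TrialEntry(phase, block, label, False, k=0, r=0)


def make_schedule(
    experiment: int, seed: int, counterbalance: str = "A"
) -> TrialSchedule:
    """Build a seeded trial schedule honoring the printed design counts.

    Experiment 1: 14 acquisition CS+ trials (7 reinforced), then 4 blocks of
    22 CS+ (11 reinforced) + 24 TS, each opening with 10 consecutive CS+.
    Experiment 2: 12 CS+ (10 reinforced) + 12 CS- acquisition trials, then
    3 blocks of 14 CS+ (12 reinforced) + 8 CS- + 32 TS opening with 6 CS+.
    TS trials are balanced over TS labels within each block.
    """
    stimset = make_stimulus_set(experiment, counterbalance)
    rng = np.random.default_rng(seed)
    cs_plus = stimset.cs_plus
    cs_minus = stimset.cs_minus
    ts = stimset.ts_labels
    entries: list[TrialEntry] = []

    if experiment == 1:
        n_acq, n_acq_reinf = 14, 7
        blocks, n_csp, n_csp_reinf, n_open = 4, 22, 11, 10
        per_label = 24 // len(ts)
        reinf = _reinforced_positions(rng, n_acq, n_acq_reinf)
        for j in range(n_acq):
            entries.append(_cs_entry(Phase.ACQUISITION, 0, cs_plus, Role.CS_PLUS, j in reinf))
        for b in range(1, blocks + 1):
            reinf = _reinforced_positions(rng, n_csp, n_csp_reinf)
            csp_flags = [j in reinf for j in range(n_csp)]
            opening = [(cs_plus, csp_flags[j]) for j in range(n_open)]
            rest = [(cs_plus, csp_flags[j]) for j in range(n_open, n_csp)]
            rest += [(t, False) for t in ts for _ in range(per_label)]
            order = rng.permutation(len(rest))
            for lab, flag in opening + [rest[i] for i in order]:
                role = stimset.roles[lab]
                entries.append(_cs_entry(Phase.GENERALIZATION, b, lab, role, flag))
    else:
        n_csp_acq, n_csp_acq_reinf, n_csm_acq = 12, round(0.83 * 12), 12
        blocks, n_csp, n_csp_reinf, n_csm, n_open = 3, 14, round(0.83 * 14), 8, 6
        per_label = 32 // len(ts)
        reinf = _reinforced_positions(rng, n_csp_acq, n_csp_acq_reinf)
        acq = [(cs_plus, j in reinf) for j in range(n_csp_acq)]
        acq += [(cs_minus, False) for _ in range(n_csm_acq)]
        order = rng.permutation(len(acq))
        for i in order:
            lab, flag = acq[i]
            entries.append(_cs_entry(Phase.ACQUISITION, 0, lab, stimset.roles[lab], flag))
        for b in range(1, blocks + 1):
            reinf = _reinforced_positions(rng, n_csp, n_csp_reinf)
            csp_flags = [j in reinf for j in range(n_csp)]
            opening = [(cs_plus, csp_flags[j]) for j in range(n_open)]
            rest = [(cs_plus, csp_flags[j]) for j in range(n_open, n_csp)]
            rest += [(cs_minus, False) for _ in range(n_csm)]
            rest += [(t, False) for t in ts for _ in range(per_label)]
            order = rng.permutation(len(rest))
            for lab, flag in opening + [rest[i] for i in order]:
                entries.append(
                    _cs_entry(Phase.GENERALIZATION, b, lab, stimset.roles[lab], flag)
                )

    return TrialSchedule(experiment, stimset, entries)
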