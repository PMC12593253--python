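"""Probabilistic cue-target task structure.

The task presents 16 sequences of 15 trials each. Within a sequence a
stimulus reappears at one of four screen quadrants (labelled ``A``-``D``);
one quadrant is the *modal* (most likely) location, realized at a fixed
predictability level (100%, 80% or 60% of trials). Deviant trials land
uniformly on one of the three non-modal quadrants. The design is balanced:
each quadrant is modal in exactly a quarter of the sequences, no two
consecutive sequences share a modal location, and each of eight stimuli
is shown in exactly two sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

QUADRANTS: tuple[str, ...] = ("A", "B", "C", "D")

#: Trial phase durations in ms, carried as metadata only.
PHASE_DURATIONS_MS = {"cue": 1000, "isi": 750, "target": 1500, "iti": 750}


class DesignConstraintError(ValueError):
    """A requested design configuration cannot be satisfied."""


@dataclass(frozen=True)
class DesignConfig:
    """Counts and sizes defining the task structure.

    ``predictability_counts`` maps each predictability level to the number
    of sequences realized at that level; values must sum to ``n_sequences``.
    """

    n_trials: int = 15
    predictability_counts: dict[float, int] = field(
        default_factory=lambda: {1.00: 4, 0.80: 6, 0.60: 6}
    )
    n_stimuli: int = 8
    quadrants: tuple[str, ...] = QUADRANTS
    max_order_retries: int = 10_000

    @property
    def n_sequences(self) -> int:
        return sum(self.predictability_counts.values())


@dataclass(frozen=True)
class SequenceDesign:
    sequence_index: int
    stimulus_id: int
    predictability_level: float
    modal_location: str
    trial_locations: tuple[str, ...]

    @property
    def n_modal_trials(self) -> int:
        return sum(loc == self.modal_location for loc in self.trial_locations)


@dataclass(frozen=True)
class TaskDesign:
    sequences: tuple[SequenceDesign, ...]
    seed: int
    config: DesignConfig = field(default_factory=DesignConfig)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "sequences": [
                {
                    "index": s.sequence_index,
                    "stimulus_id": s.stimulus_id,
                    "predictability": s.predictability_level,
                    "modal_location": s.modal_location,
                    "trial_locations": list(s.trial_locations),
                }
                for s in self.sequences
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TaskDesign":
        payload = json.loads(text)
        seqs = tuple(
            SequenceDesign(
                sequence_index=s["index"],
                stimulus_id=s["stimulus_id"],
                predictability_level=s["predictability"],
                modal_location=s["modal_location"],
                trial_locations=tuple(s["trial_locations"]),
            )
            for s in payload["sequences"]
        )
        counts: dict[float, int] = {}
        for s in seqs:
            counts[s.predictability_level] = counts.get(s.predictability_level, 0) + 1
        n_stim = len({s.stimulus_id for s in seqs})
        n_trials = len(seqs[0].trial_locations) if seqs else 0
        cfg = DesignConfig(
            n_trials=n_trials, predictability_counts=counts, n_stimuli=n_stim
        )
        return cls(sequences=seqs, seed=payload["seed"], config=cfg)


def _modal_order(rng: np.random.Generator, config: DesignConfig) -> list[str]:
    """Shuffle the balanced modal-location multiset until no two adjacent
    entries repeat; rejection sampling is unbiased among feasible orders."""
    n_per = config.n_sequences // len(config.quadrants)
    if n_per * len(config.quadrants) != config.n_sequences:
        raise DesignConstraintError(
            "quadrant balance impossible: "
            f"{config.n_sequences} sequences over {len(config.quadrants)} quadrants"
        )
    pool = np.repeat(np.array(config.quadrants, dtype=object), n_per)
    for _ in range(config.max_order_retries):
        order = rng.permutation(pool)
        if all(order[i] != order[i + 1] for i in range(len(order) - 1)):
            return list(order)
    raise DesignConstraintError(
        "could not order modal locations without adjacent repeats "
        f"within {config.max_order_retries} retries"
    )


def generate_design(config: DesignConfig | None = None, seed: int = 0) -> TaskDesign:
    """Generate a balanced task design.

    Predictability levels are realized as exact proportions: a sequence at
    level p has exactly round(n_trials * p) modal trials. Deviant trial
    positions and locations are uniform, with no positional exemption.
    Identical (config, seed) pairs produce identical designs.
    """
    config = config or DesignConfig()
    for level, count in config.predictability_counts.items():
        if not (0.0 < level <= 1.0):
            raise DesignConstraintError(f"predictability level {level} outside (0, 1]")
        if count < 0:
            raise DesignConstraintError(f"negative count for level {level}")
    if 2 * config.n_stimuli != config.n_sequences:
        raise DesignConstraintError(
            f"{config.n_stimuli} stimuli x 2 presentations != "
            f"{config.n_sequences} sequences"
        )
    rng = np.random.default_rng(seed)

    modal = _modal_order(rng, config)
    levels = np.repeat(
        list(config.predictability_counts.keys()),
        list(config.predictability_counts.values()),
    )
    levels = rng.permutation(levels)
    stimuli = rng.permutation(np.repeat(np.arange(config.n_stimuli), 2))

    sequences = []
    for i in range(config.n_sequences):
        level = float(levels[i])
        m = modal[i]
        n_modal = round(config.n_trials * level)
        locs = np.array([m] * config.n_trials, dtype=object)
        n_dev = config.n_trials - n_modal
        if n_dev:
            dev_pos = rng.choice(config.n_trials, size=n_dev, replace=False)
            others = [q for q in config.quadrants if q != m]
            locs[dev_pos] = rng.choice(others, size=n_dev, replace=True)
        sequences.append(
            SequenceDesign(
                sequence_index=i,
                stimulus_id=int(stimuli[i]),
                predictability_level=level,
                modal_location=m,
                trial_locations=tuple(locs),
            )
        )
    return TaskDesign(sequences=tuple(sequences), seed=seed, config=config)


def validate_design(design: TaskDesign) -> list[str]:
    """Check every design invariant; return the violations (empty if valid)."""
    cfg = design.config
    report: list[str] = []
    for s in design.sequences:
        tag = f"sequence {s.sequence_index}"
        if len(s.trial_locations) != cfg.n_trials:
            report.append(
                f"{tag}: trial count {len(s.trial_locations)} != {cfg.n_trials}"
            )
            continue
        expect = round(cfg.n_trials * s.predictability_level)
        if s.n_modal_trials != expect:
            report.append(
                f"{tag}: modal-location trials {s.n_modal_trials} != {expect} "
                f"required at predictability {s.predictability_level}"
            )
        bad = [q for q in s.trial_locations if q not in cfg.quadrants]
        if bad:
            report.append(f"{tag}: unknown quadrant labels {sorted(set(bad))}")

    level_counts: dict[float, int] = {}
    for s in design.sequences:
        level_counts[s.predictability_level] = (
            level_counts.get(s.predictability_level, 0) + 1
        )
    if level_counts != cfg.predictability_counts:
        report.append(
            f"predictability split {level_counts} != configured "
            f"{cfg.predictability_counts}"
        )

    modal_counts = {q: 0 for q in cfg.quadrants}
    for s in design.sequences:
        modal_counts[s.modal_location] = modal_counts.get(s.modal_location, 0) + 1
    n_per = cfg.n_sequences // len(cfg.quadrants)
    if any(v != n_per for v in modal_counts.values()):
        report.append(f"modal-location balance violated: {modal_counts}")

    for a, b in zip(design.sequences, design.sequences[1:]):
        if a.modal_location == b.modal_location:
            report.append(
                "adjacency rule violated: sequences "
                f"{a.sequence_index} and {b.sequence_index} share modal location "
                f"{a.modal_location}"
            )

    stim_counts: dict[int, int] = {}
    for s in design.sequences:
        stim_counts[s.stimulus_id] = stim_counts.get(s.stimulus_id, 0) + 1
    if any(v != 2 for v in stim_counts.values()) or len(stim_counts) != cfg.n_stimuli:
        report.append(f"stimulus assignment violated: {stim_counts}")

    return report
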