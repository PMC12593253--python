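"""Ideal-learner belief updating and information-theoretic trial metrics.

The learner maintains a Dirichlet-categorical belief over target locations.
With a symmetric add-one (Laplace) prior over four locations, the predictive
distribution starts uniform at 25%; a single observation raises the observed
location's predictive probability to 40% and lowers each other location to
20%. Three trial-level quantities are derived from the belief:

* **information gain** — KL divergence of the post-update predictive
  distribution from the pre-update one (nats): how much the event moves
  the learner's beliefs;
* **surprise** — negative log predictive probability of the observed
  location under the pre-update belief (nats);
* **predictability** — negentropy ``ln(n) - H`` of the pre-update
  predictive distribution (nats): how concentrated beliefs about the
  sequence have become.

Beliefs reset at every sequence boundary; there is no forgetting within a
sequence and no carry-over between the two presentations of a stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import rel_entr
from scipy.stats import entropy

from .task import TaskDesign


@dataclass(frozen=True)
class BeliefState:
    """Pseudo-count belief over a fixed set of locations.

    ``counts[loc] = prior_count + number of times loc was observed``; the
    predictive distribution is the normalized count vector.
    """

    locations: tuple[str, ...]
    counts: tuple[float, ...]
    prior_count: float

    def predictive(self) -> np.ndarray:
        c = np.asarray(self.counts, dtype=float)
        return c / c.sum()

    def predictive_prob(self, location: str) -> float:
        return float(self.predictive()[self._index(location)])

    def _index(self, location: str) -> int:
        try:
            return self.locations.index(location)
        except ValueError:
            raise KeyError(
                f"unknown location {location!r}; belief covers {self.locations}"
            ) from None


def init_belief(
    n_locations: int = 4,
    prior_count: float = 1.0,
    locations: tuple[str, ...] | None = None,
) -> BeliefState:
    """Symmetric initial belief; the predictive distribution is uniform."""
    if prior_count <= 0:
        raise ValueError(f"prior_count must be positive, got {prior_count}")
    if n_locations < 1:
        raise ValueError(f"need at least one location, got {n_locations}")
    if locations is None:
        locations = tuple(chr(ord("A") + i) for i in range(n_locations))
    elif len(locations) != n_locations:
        raise ValueError("locations length does not match n_locations")
    return BeliefState(
        locations=locations,
        counts=(float(prior_count),) * n_locations,
        prior_count=float(prior_count),
    )


def update_belief(belief: BeliefState, observed: str) -> BeliefState:
    """Add-one update of the observed location's pseudo-count (pure)."""
    i = belief._index(observed)
    counts = list(belief.counts)
    counts[i] += 1.0
    return BeliefState(
        locations=belief.locations,
        counts=tuple(counts),
        prior_count=belief.prior_count,
    )


def information_gain(prior_belief: BeliefState, posterior_belief: BeliefState) -> float:
    """KL divergence D(posterior predictive || prior predictive) in nats."""
    if prior_belief.locations != posterior_belief.locations:
        raise ValueError(
            "belief location sets differ: "
            f"{prior_belief.locations} vs {posterior_belief.locations}"
        )
    p = prior_belief.predictive()
    q = posterior_belief.predictive()
    return float(rel_entr(q, p).sum())


def surprise(belief: BeliefState, observed: str) -> float:
    """Negative log predictive probability of the observed location (nats)."""
    return float(-np.log(belief.predictive_prob(observed)))


def predictability(belief: BeliefState) -> float:
    """Negentropy ln(n) - H of the predictive distribution (nats)."""
    p = belief.predictive()
    return float(np.log(len(p)) - entropy(p))


@dataclass(frozen=True)
class TrialMetrics:
    sequence_index: int
    trial_index: int
    observed_location: str
    information_gain: float
    surprise: float
    predictability: float


def compute_sequence_metrics(
    trial_locations: tuple[str, ...] | list[str],
    prior_count: float = 1.0,
    sequence_index: int = 0,
    locations: tuple[str, ...] | None = None,
) -> list[TrialMetrics]:
    """Run the learner over one sequence and return per-trial metrics.

    Surprise and predictability use the pre-update belief of each trial;
    information gain compares the pre- and post-update beliefs. Metrics
    for trial t therefore never depend on later trials.
    """
    if len(trial_locations) == 0:
        raise ValueError("trial_locations is empty")
    n_loc = len(locations) if locations is not None else 4
    belief = init_belief(n_loc, prior_count, locations=locations)
    out = []
    for t, loc in enumerate(trial_locations):
        s = surprise(belief, loc)
        pred = predictability(belief)
        updated = update_belief(belief, loc)
        out.append(
            TrialMetrics(
                sequence_index=sequence_index,
                trial_index=t,
                observed_location=loc,
                information_gain=information_gain(belief, updated),
                surprise=s,
                predictability=pred,
            )
        )
        belief = updated
    return out


def compute_design_metrics(design: TaskDesign, prior_count: float = 1.0) -> pd.DataFrame:
    """Trial metrics for every sequence of a design, as a tidy table.

    Columns: sequence_index, trial_index, observed_location,
    information_gain, surprise, predictability. The belief resets at each
    sequence start.
    """
    rows = []
    for seq in design.sequences:
        rows.extend(
            compute_sequence_metrics(
                seq.trial_locations,
                prior_count=prior_count,
                sequence_index=seq.sequence_index,
                locations=design.config.quadrants,
            )
        )
    return pd.DataFrame(
        {
            "sequence_index": [m.sequence_index for m in rows],
            "trial_index": [m.trial_index for m in rows],
            "observed_location": [m.observed_location for m in rows],
            "information_gain": [m.information_gain for m in rows],
            "surprise": [m.surprise for m in rows],
            "predictability": [m.predictability for m in rows],
        }
    )
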