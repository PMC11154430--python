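"""Per-person gait baselines and centroid-based walker identification.

A person's baseline for one foot and walking speed is, per mode rank k,
the centroid of their step feature triplets, ``<F_k> = mean_c F_{k,c}``,
together with a spread vector

    S_k = [ (1/(C-1)) sum_c (F_{k,c} - <F_k>)^2 ]^(-1/2)     (componentwise),

the inverse sample standard deviation of each component over the person's
C enrolled steps.  A probe — a subset of C_s steps from an unknown walker
— is scored against candidate x_i by the spread-weighted squared
deviation

    l(x_i) = sum_k (1/C_s) sum_c  S_k(x_i) . (F_{k,c} - <F_k(x_i)>)^2 ,

a Mahalanobis-style cost (note the *inverse standard deviation* weight as
printed in the source method; ``standardized=True`` switches to the
inverse-variance weight of a textbook Mahalanobis distance).  The walker
is identified as the argmin over the gallery.

`evaluate_identification` runs the Monte-Carlo protocol: repeatedly draw
a person uniformly, draw 30% of their steps without replacement, and
score whether the argmin is correct.  With ``holdout=True`` the probe
person's baseline is recomputed without the drawn steps, removing the
optimistic leakage of probing a centroid that contains the probe.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .features import StepFeatureSet

_log = logging.getLogger(__name__)

#: Replacement inverse-spread when a component has zero within-person variance
#: (degenerate in jitter-free synthetic cohorts).
SPREAD_CAP = 1e6


def _steps_array(steps: Sequence[StepFeatureSet]) -> NDArray:
    """(C, K, 3) stack of (alpha, freq, s0) triplets."""
    arr = np.stack([fs.as_array() for fs in steps])
    if np.isnan(arr).any():
        raise ValueError("feature sets contain missing modes; cannot build baseline")
    return arr


@dataclass
class Baseline:
    """One person's per-mode centroids and inverse-spread vectors."""

    person: str
    centroids: NDArray          # (K, 3)
    spreads: NDArray            # (K, 3) inverse standard deviations
    n_steps: int
    foot: str | None = None
    speed: str | None = None

    def to_dict(self) -> dict:
        return {"person": self.person, "foot": self.foot, "speed": self.speed,
                "n_steps": self.n_steps, "centroids": self.centroids.tolist(),
                "spreads": self.spreads.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Baseline":
        return cls(person=d["person"], centroids=np.asarray(d["centroids"]),
                   spreads=np.asarray(d["spreads"]), n_steps=int(d["n_steps"]),
                   foot=d.get("foot"), speed=d.get("speed"))


@dataclass
class Gallery:
    """Enrolled baselines for one foot/speed condition (unique person labels)."""

    baselines: list[Baseline]

    def __post_init__(self) -> None:
        labels = [b.person for b in self.baselines]
        if len(set(labels)) != len(labels):
            raise ValueError("gallery contains duplicate person labels")

    def __len__(self) -> int:
        return len(self.baselines)

    @property
    def labels(self) -> list[str]:
        return [b.person for b in self.baselines]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([b.to_dict() for b in self.baselines], fh, indent=1,
                      sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "Gallery":
        with open(path) as fh:
            return cls([Baseline.from_dict(d) for d in json.load(fh)])


@dataclass
class EvalReport:
    """Monte-Carlo identification accuracy and confusion counts."""

    accuracy: float
    n_repeats: int
    fraction: float
    seed: int
    holdout: bool
    confusion: dict             # (true person) -> {predicted person: count}
    foot: str | None = None
    speed: str | None = None

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "n_repeats": self.n_repeats,
                "fraction": self.fraction, "seed": self.seed,
                "holdout": self.holdout, "foot": self.foot, "speed": self.speed,
                "confusion": self.confusion}

    def confusion_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.confusion).T.fillna(0).astype(int)
        return df.reindex(sorted(df.index), columns=sorted(df.columns), fill_value=0)


def compute_baseline(steps: Sequence[StepFeatureSet], foot: str | None = None,
                     speed: str | None = None,
                     spread_cap: float = SPREAD_CAP) -> Baseline:
    """Centroid and inverse-spread of one person's step features.

    Requires at least two steps (the spread is a sample standard deviation).
    A component with zero within-person variance gets its inverse spread
    floored at ``spread_cap`` with a warning.
    """
    if len(steps) < 2:
        raise ValueError(f"need >= 2 steps to build a baseline, got {len(steps)}")
    persons = {fs.person for fs in steps if fs.person is not None}
    if len(persons) > 1:
        raise ValueError(f"steps from multiple persons in one baseline: {persons}")
    arr = _steps_array(steps)
    centroids = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    zero = sd <= 0
    if zero.any():
        _log.warning("zero within-person variance in %d component(s); capping spread",
                     int(zero.sum()))
    spreads = np.empty_like(sd)
    spreads[~zero] = 1.0 / sd[~zero]
    spreads[zero] = spread_cap
    spreads = np.minimum(spreads, spread_cap)
    person = persons.pop() if persons else ""
    return Baseline(person=person, centroids=centroids, spreads=spreads,
                    n_steps=arr.shape[0], foot=foot, speed=speed)


def identification_cost(probe_steps: Sequence[StepFeatureSet], baseline: Baseline,
                        standardized: bool = False) -> float:
    """Spread-weighted squared deviation of probe features from a candidate.

    Non-negative; zero iff every probe step matches the centroids exactly.
    ``standardized=True`` squares the inverse-spread weight (inverse
    variance), the textbook Mahalanobis form.
    """
    if not probe_steps:
        raise ValueError("probe_steps must be non-empty")
    arr = _steps_array(probe_steps)                     # (Cs, K, 3)
    if arr.shape[1:] != baseline.centroids.shape:
        raise ValueError(
            f"mode-count mismatch: probe {arr.shape[1:]} vs baseline "
            f"{baseline.centroids.shape}")
    w = baseline.spreads**2 if standardized else baseline.spreads
    dev2 = (arr - baseline.centroids) ** 2
    return float((dev2 * w).sum(axis=(1, 2)).mean())


def identify(probe_steps: Sequence[StepFeatureSet], gallery: Gallery,
             standardized: bool = False) -> tuple[str, NDArray]:
    """Argmin-cost person label and the full cost vector (enrollment order)."""
    if len(gallery) == 0:
        raise ValueError("empty gallery")
    costs = np.array([identification_cost(probe_steps, b, standardized=standardized)
                      for b in gallery.baselines])
    imin = int(np.argmin(costs))    # ties resolve to earliest enrollment
    if np.count_nonzero(costs == costs[imin]) > 1:
        _log.info("cost tie; resolved by enrollment order")
    return gallery.labels[imin], costs


def evaluate_identification(steps_by_person: dict[str, Sequence[StepFeatureSet]],
                            fraction: float = 0.3, n_repeats: int = 1000,
                            seed: int = 0, holdout: bool | str = False,
                            standardized: bool = False,
                            foot: str | None = None,
                            speed: str | None = None) -> EvalReport:
    """Monte-Carlo identification accuracy over random probe subsets.

    Per repeat: a person is drawn uniformly, ``ceil(fraction * C)`` of their
    steps are drawn uniformly without replacement, costs are computed against
    every enrolled baseline, and the argmin scored.  Person and step draws
    use independent RNG substreams, so extending ``n_repeats`` never changes
    earlier draws.

    ``holdout`` controls probe/baseline leakage:

    ``False``
        baselines use all enrolled steps, probe steps included (the
        optimistic protocol);
    ``True``
        the probe person's baseline is recomputed without the drawn steps;
    ``"matched"``
        as ``True``, but every other candidate's baseline is also
        recomputed each repeat from an equal-size random subset of their
        steps.  This removes the argmin advantage a smaller (noisier)
        baseline enjoys, making every candidate statistically exchangeable
        — the protocol for chance-level null experiments.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if holdout not in (False, True, "matched"):
        raise ValueError(f"holdout must be False, True or 'matched', got {holdout!r}")
    labels = sorted(steps_by_person)
    for lab in labels:
        C = len(steps_by_person[lab])
        need = max(2, math.ceil(1.0 / fraction))
        if C < need:
            raise ValueError(f"person {lab} has {C} steps; needs >= {need}")
    gallery = Gallery([compute_baseline(steps_by_person[lab], foot=foot, speed=speed)
                       for lab in labels])
    person_rng, step_rng = np.random.default_rng(seed).spawn(2)

    correct = 0
    confusion: dict[str, dict[str, int]] = {lab: {} for lab in labels}
    for _ in range(n_repeats):
        true = labels[int(person_rng.integers(len(labels)))]
        steps = steps_by_person[true]
        C = len(steps)
        n_probe = math.ceil(fraction * C)
        idx = step_rng.choice(C, size=n_probe, replace=False)
        taken = set(idx.tolist())
        probe = [steps[i] for i in idx]
        if holdout is False:
            g = gallery
        else:
            baselines = []
            for b in gallery.baselines:
                own = steps_by_person[b.person]
                if b.person == true:
                    sub = [own[i] for i in range(C) if i not in taken]
                elif holdout == "matched":
                    m = len(own) - math.ceil(fraction * len(own))
                    pick = step_rng.choice(len(own), size=m, replace=False)
                    sub = [own[i] for i in pick]
                else:
                    baselines.append(b)
                    continue
                baselines.append(compute_baseline(sub, foot=foot, speed=speed))
            g = Gallery(baselines)
        pred, _ = identify(probe, g, standardized=standardized)
        confusion[true][pred] = confusion[true].get(pred, 0) + 1
        if pred == true:
            correct += 1
    return EvalReport(accuracy=correct / n_repeats, n_repeats=n_repeats,
                      fraction=fraction, seed=seed, holdout=holdout,
                      confusion=confusion, foot=foot, speed=speed)
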