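"""Per-step gait feature triplets from DMD spectra.

Each retained DMD eigenvalue ``mu_k`` (a per-frame multiplier) converts to
physical units through the principal logarithm:

* decay rate  ``alpha_k = Re ln(mu_k) / dt``  (1/s, negative for a decaying
  stance signal),
* frequency   ``f_k = Im ln(mu_k) / (2 pi dt)``  (Hz),
* initial condition  ``s0_k = v_k b_k``  (complex, force units), the mode's
  contribution to the signal at first contact.

Real input signals give conjugate-symmetric spectra, so modes are matched
into (mu, mu*) pairs and each pair is represented once by its member with
non-negative frequency.  The scalar clustered downstream is the *modulus*
|s0| — the conjugation-invariant choice — while the complex value is kept
for reconstruction.  A step's feature set is a fixed-length, frequency-
sorted list of K such representatives, which is what makes mode k of one
step comparable with mode k of another.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dmd import DMDModel

_log = logging.getLogger(__name__)


@dataclass
class ModeFeature:
    """One mode's (decay rate, frequency, initial condition) triplet."""

    alpha: float            # 1/s
    freq: float             # Hz, >= 0 for pair representatives
    s0_complex: complex     # v_k * b_k, force units
    pair: bool = True       # True: represents a conjugate pair; False: lone real mode
    missing: bool = False   # padding entry for a model with fewer modes than requested

    @property
    def s0(self) -> float:
        """Modulus of the initial condition (the clustered scalar)."""
        return abs(self.s0_complex)

    def as_vector(self) -> np.ndarray:
        return np.array([self.alpha, self.freq, self.s0])


@dataclass
class StepFeatureSet:
    """Fixed-length frequency-sorted feature triplets of one step."""

    features: list[ModeFeature]
    dt: float
    foot: str | None = None          # 'l' | 'r'
    speed: str | None = None         # 'normal' | 'fast'
    cycle: int | None = None
    person: str | None = None
    eligible: bool = True            # has the full complement of conjugate pairs

    def __len__(self) -> int:
        return len(self.features)

    def as_array(self) -> np.ndarray:
        """(K, 3) array of (alpha, freq, s0-modulus) rows; NaN for missing."""
        out = np.full((len(self.features), 3), np.nan)
        for i, f in enumerate(self.features):
            if not f.missing:
                out[i] = f.as_vector()
        return out

    def to_records(self) -> list[dict]:
        recs = []
        for k, f in enumerate(self.features):
            recs.append({
                "person": self.person, "foot": self.foot, "speed": self.speed,
                "cycle": self.cycle, "mode_rank": k,
                "alpha": f.alpha, "freq": f.freq, "s0": f.s0,
                "s0_re": f.s0_complex.real, "s0_im": f.s0_complex.imag,
                "missing": f.missing,
            })
        return recs


def eig_to_feature(mu: complex, v: complex, b: complex, dt: float) -> ModeFeature:
    """Convert one eigenvalue/mode/amplitude triple to physical units.

    Uses the principal branch of the logarithm, so a real negative eigenvalue
    maps to the Nyquist frequency ``1/(2 dt)``.
    """
    if mu == 0:
        raise ValueError("eigenvalue 0 has no logarithm; mode cannot be featurized")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    ln = np.log(complex(mu))
    return ModeFeature(
        alpha=ln.real / dt,
        freq=ln.imag / (2.0 * np.pi * dt),
        s0_complex=complex(v) * complex(b),
        pair=abs(complex(mu).imag) > 0,
    )


def pair_conjugates(model: DMDModel, tol: float = 1e-8) -> list[ModeFeature]:
    """Match a real signal's modes into conjugate pairs; one representative each.

    Eigenvalues ``mu_i, mu_j`` with ``|mu_i - conj(mu_j)| <= tol`` (relative to
    the spectral radius) form a pair, represented by the member with
    non-negative imaginary part (frequency >= 0).  Real eigenvalues pass
    through as singletons with ``pair=False``.  A complex eigenvalue with no
    partner within tolerance is kept as a singleton with a warning.
    """
    mu = np.asarray(model.eigvals)
    v = np.asarray(model.mode_scalars)
    b = np.asarray(model.amplitudes)
    scale = np.max(np.abs(mu)) or 1.0
    atol = tol * scale
    used = np.zeros(mu.size, dtype=bool)
    reps: list[ModeFeature] = []
    for i in range(mu.size):
        if used[i]:
            continue
        used[i] = True
        if abs(mu[i].imag) <= atol:
            f = eig_to_feature(complex(mu[i].real), v[i], b[i], model.dt)
            f.pair = False
            reps.append(f)
            continue
        partner = None
        for j in range(i + 1, mu.size):
            if not used[j] and abs(mu[j] - np.conj(mu[i])) <= atol:
                partner = j
                break
        if partner is None:
            _log.warning("complex eigenvalue %s has no conjugate partner within tol", mu[i])
            f = eig_to_feature(mu[i], v[i], b[i], model.dt)
            f.pair = False
            reps.append(f)
            continue
        used[partner] = True
        k = i if mu[i].imag >= 0 else partner
        f = eig_to_feature(mu[k], v[k], b[k], model.dt)
        reps.append(f)
    return reps


def _sort_key(f: ModeFeature) -> tuple:
    # ascending frequency; ties: more negative alpha first, then larger s0
    return (f.freq, f.alpha, -f.s0)


def featurize_step(model: DMDModel, n_modes: int = 6, tol: float = 1e-8,
                   foot: str | None = None, speed: str | None = None,
                   cycle: int | None = None, person: str | None = None) -> StepFeatureSet:
    """Fixed-length frequency-sorted feature set of one step's DMD model.

    Pairs conjugate modes, sorts representatives by ascending frequency
    (ties broken by more negative decay rate, then larger |s0|), and clamps
    the list to exactly ``n_modes`` entries.  Conjugate-pair representatives
    are preferred — the gait model is a sum of oscillatory pairs, and a lone
    real eigenvalue (frequency pinned at 0 or Nyquist) breaks the
    frequency-rank correspondence across steps — so surplus trimming keeps
    the ``n_modes`` largest-|s0| pairs, falls back to singletons only to
    fill a deficit, and finally pads with entries flagged ``missing``.
    """
    if model.eigvals.size == 0:
        raise ValueError("empty DMD model cannot be featurized")
    reps = pair_conjugates(model, tol=tol)
    pairs = sorted((r for r in reps if r.pair), key=lambda f: -f.s0)
    singles = sorted((r for r in reps if not r.pair), key=lambda f: -f.s0)
    keep = pairs[:n_modes]
    if len(keep) < n_modes:
        keep += singles[: n_modes - len(keep)]
    keep = sorted(keep, key=_sort_key)
    while len(keep) < n_modes:
        keep.append(ModeFeature(alpha=np.nan, freq=np.nan, s0_complex=0j, missing=True))
    return StepFeatureSet(features=keep, dt=model.dt, foot=foot, speed=speed,
                          cycle=cycle, person=person)


#: Default Hankel row count for step feature extraction: just under half the
#: 100-frame padded window, matching the ~41-45 frame stance of the default
#: profile so the delay window spans one full stance.
FEATURE_ROWS = 45

#: Rank escalation schedule: start at the r = 12 operating point; if the
#: spectrum does not contain n_modes clean conjugate pairs, retry slightly
#: larger truncations before declaring the step ineligible.
RANK_SEQUENCE = (12, 14, 16)


def features_from_signal(signal, n_modes: int = 6, rows: int | None = FEATURE_ROWS,
                         rank_sequence: Sequence[int] = RANK_SEQUENCE,
                         dt: float | None = None, **labels) -> StepFeatureSet:
    """Hankel-DMD feature triplets of one step signal, with eligibility.

    Fits at each truncation rank in ``rank_sequence`` until the spectrum
    yields ``n_modes`` conjugate-pair representatives; the returned feature
    set's ``eligible`` attribute is False if no rank does (such steps are
    excluded from baselines, mirroring the restriction of clustering to
    eligible steps).
    """
    from .dmd import RankRule, hankel_dmd

    fs = None
    for r in rank_sequence:
        model = hankel_dmd(signal, rows=rows, rank_rule=RankRule.fixed(r), dt=dt)
        fs = featurize_step(model, n_modes=n_modes, **labels)
        if all(f.pair and not f.missing for f in fs.features):
            fs.eligible = True
            return fs
    _log.info("step has fewer than %d conjugate pairs at ranks %s; marked ineligible",
              n_modes, tuple(rank_sequence))
    fs.eligible = False
    return fs


def reconstruct_from_features(fs: StepFeatureSet, n_frames: int,
                              dt: float | None = None) -> np.ndarray:
    """Rebuild the force series from feature triplets.

    Pairs contribute ``2 Re(s0 exp((alpha + 2 pi j f) n dt))`` — the mode plus
    its conjugate — and lone real modes their single real term.  Equals the
    source model's reconstruction to numerical precision.
    """
    if dt is None:
        dt = fs.dt
    n = np.arange(int(n_frames))
    out = np.zeros(n.size)
    for f in fs.features:
        if f.missing:
            _log.info("skipping missing mode in feature reconstruction")
            continue
        term = f.s0_complex * np.exp((f.alpha + 2j * np.pi * f.freq) * n * dt)
        out += 2.0 * term.real if f.pair else term.real
    return out


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def feature_table(step_sets: Sequence[StepFeatureSet]) -> pd.DataFrame:
    """Long-format table of feature triplets, one row per (step, mode rank)."""
    recs = [r for fs in step_sets for r in fs.to_records()]
    return pd.DataFrame.from_records(recs)


def write_features_csv(step_sets: Sequence[StepFeatureSet], path) -> None:
    feature_table(step_sets).to_csv(path, index=False)


def write_features_json(step_sets: Sequence[StepFeatureSet], path) -> None:
    with open(path, "w") as fh:
        json.dump([fs.to_records() for fs in step_sets], fh, indent=1, sort_keys=True)


def read_features_csv(path, dt: float = 0.02) -> list[StepFeatureSet]:
    """Rebuild step feature sets from the long-format CSV."""
    df = pd.read_csv(path)
    out = []
    keys = ["person", "foot", "speed", "cycle"]
    for vals, grp in df.groupby(keys, sort=True, dropna=False):
        grp = grp.sort_values("mode_rank")
        feats = [ModeFeature(alpha=r.alpha, freq=r.freq,
                             s0_complex=complex(r.s0_re, r.s0_im),
                             missing=bool(r.missing))
                 for r in grp.itertuples()]
        lab = dict(zip(keys, vals))
        out.append(StepFeatureSet(features=feats, dt=dt,
                                  person=None if pd.isna(lab["person"]) else str(lab["person"]),
                                  foot=None if pd.isna(lab["foot"]) else str(lab["foot"]),
                                  speed=None if pd.isna(lab["speed"]) else str(lab["speed"]),
                                  cycle=None if pd.isna(lab["cycle"]) else int(lab["cycle"])))
    return out
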