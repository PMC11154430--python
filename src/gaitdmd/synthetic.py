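"""Synthetic walkway cohorts with known ground-truth gait mode parameters.

The generator works in the same parameterization the decomposition
estimates: a person's step force signal is a sum of K = 6 damped complex
conjugate sinusoid pairs,

    s_n = sum_k 2 exp(alpha_k n dt) Re(s0_k exp(2 pi i f_k n dt)) + noise,

with person-specific triplets ``(alpha_k, f_k, s0_k)`` (decay rate in 1/s,
frequency in Hz, complex initial condition in N), step-to-step jitter on
the triplets, and additive measurement noise.  Because the model and the
estimator share this form, recovery of the triplets from noiseless steps
is exact and every downstream stage can be tested against known truth.

The base triplet table is a damped Fourier sine series on the stance:
the six frequencies are the odd harmonics ``f_k = k / (2 T)``,
k = 1, 3, ..., 11, of the stance duration T ~ 0.885 s, and every initial
condition is pure imaginary, so each mode is a damped sine vanishing at
first contact and (jointly, to leading order) at toe-off.  Odd harmonics
keep the frequency spacing (~1.13 Hz) above the spectral resolution of
the stance window, which keeps the Hankel matrix well conditioned and
every mode recoverable under noise; amplitudes below a floor were raised
to that floor for the same reason.  Amplitudes were fitted once to a
reference stance profile (heel-strike peak ~830 N, then a push-off bump,
valley in between), giving a signal with exactly two principal
(10%-prominence) force maxima over a stance of 44 frames at 50 Hz.
Because the series is Fourier-like, its partial sums converge
progressively: the two largest-|s0| pairs alone (the stance arch and the
2.8 Hz heel/push-off modulation) correlate > 0.95 with the full signal.
Past toe-off the expansion keeps ringing at a few percent of peak (a sum
of damped exponentials is not compactly supported); the stance window,
defined as the first run of frames with positive force above 0.5% of
peak (brief dips tolerated), excludes that ringing wherever signals are
cropped, padded or rendered.

Cohorts are drawn around this base profile: the ``separation`` parameter
scales the between-person spread of the triplets (``separation=0`` makes
everyone identical, the chance-level control), and per-person variants
for foot (l/r) and walking speed (normal/fast) apply small fixed
rescalings, so baselines are built per foot and speed as in the
identification protocol.

2D rendering (`simulate_recording`) places steps as three-component
Gaussian pressure blobs (heel, metatarsal, toe) whose per-frame spatial
integral reproduces the step's force signal exactly; anatomical fidelity
is a non-goal, integral fidelity is the contract.  Rendering uses the
rectified (non-negative) force signal, since pressures cannot be
negative; the pure linear expansion (``rectify=False``, the default of
`simulate_step_force`) remains available as the analytic oracle for the
decomposition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from .pressure import CONTACT_REL_THRESHOLD, PressureRecording, StepSignal

_log = logging.getLogger(__name__)

#: Frozen base profile: 6 conjugate-pair triplets (alpha [1/s], freq [Hz],
#: complex s0 [N]) whose expansion is the canonical double-bump stance signal.
BASE_MODES: tuple[tuple[float, float, complex], ...] = (
    (-2.831779, 0.565228, complex(0.0, -619.883813)),
    (-2.733449, 1.695684, complex(0.0, -100.803361)),
    (-2.635120, 2.826141, complex(0.0, 216.906318)),
    (-2.536791, 3.956597, complex(0.0, -55.108209)),
    (-2.438462, 5.087053, complex(0.0, -55.108209)),
    (-2.340133, 6.217509, complex(0.0, 55.108209)),
)

#: Additive between-person frequency spread, Hz per unit of ``separation``.
FREQ_SEPARATION_SCALE = 0.3


@dataclass(frozen=True)
class ModeParams:
    """One conjugate pair's ground-truth triplet."""

    alpha: float        # decay rate, 1/s, negative
    freq: float         # Hz, >= 0
    s0: complex         # initial condition, N


@dataclass(frozen=True)
class Jitter:
    """Step-to-step variability: multiplicative on alpha and |s0|, additive on f."""

    alpha_rel: float = 0.015
    s0_rel: float = 0.015
    freq_hz: float = 0.005


@dataclass
class PersonProfile:
    """A synthetic walker: K mode triplets plus their step-to-step variability."""

    person_id: str
    modes: list[ModeParams]
    jitter: Jitter = field(default_factory=Jitter)
    noise_sd: float = 0.05      # additive in-stance measurement noise, N

    def validate(self, dt: float = 0.02) -> None:
        nyq = 1.0 / (2.0 * dt)
        freqs = [m.freq for m in self.modes]
        if not self.modes:
            raise ValueError(f"profile {self.person_id}: modes must be non-empty")
        if any(m.alpha >= 0 for m in self.modes):
            raise ValueError(f"profile {self.person_id}: all alpha must be < 0")
        if any(not 0 <= f < nyq for f in freqs):
            raise ValueError(
                f"profile {self.person_id}: freqs must lie in [0, {nyq} Hz)")
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValueError(
                f"profile {self.person_id}: freqs must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError(f"profile {self.person_id}: noise_sd must be >= 0")

    def scaled(self, alpha_scale: float = 1.0, freq_scale: float = 1.0,
               s0_scale: float = 1.0, suffix: str = "") -> "PersonProfile":
        """Variant with rescaled triplets (used for foot/speed conditions)."""
        modes = [ModeParams(m.alpha * alpha_scale, m.freq * freq_scale,
                            m.s0 * s0_scale) for m in self.modes]
        return PersonProfile(person_id=self.person_id + suffix, modes=modes,
                             jitter=self.jitter, noise_sd=self.noise_sd)


@dataclass
class CohortSpec:
    """Study conditions of a synthetic cohort."""

    n_persons: int = 16
    n_modes: int = 6
    separation: float = 0.012
    steps_per_person: int = 30
    seed: int = 0

    def validate(self) -> None:
        if self.n_persons < 2:
            raise ValueError(f"n_persons must be >= 2 (got {self.n_persons})")
        if not 1 <= self.n_modes <= len(BASE_MODES):
            raise ValueError(
                f"n_modes must be in [1, {len(BASE_MODES)}] (got {self.n_modes})")
        if self.separation < 0:
            raise ValueError(f"separation must be >= 0 (got {self.separation})")
        if self.steps_per_person < 2:
            raise ValueError(
                f"steps_per_person must be >= 2 (got {self.steps_per_person})")


@dataclass
class WalkwayGeometry:
    """Sensor grid: rows along the walking direction, columns across it."""

    n_rows: int = 256
    n_cols: int = 64
    cell_size: float = 0.005    # m
    dt: float = 0.02            # s

    def validate(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0 (got {self.cell_size})")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0 (got {self.dt})")

    @classmethod
    def full_size(cls) -> "WalkwayGeometry":
        """Full-resolution instrument grid (895 x 128 sensels at 5 mm)."""
        return cls(n_rows=895, n_cols=128)


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def _rebalance_first_contact(modes: list[ModeParams],
                             ref: list[ModeParams]) -> list[ModeParams]:
    """Restore the near-zero signal value at first contact after perturbing s0.

    The expansion at n = 0 is ``2 sum_k Re(s0_k)`` — a fine cancellation of
    large amplitudes.  Independent per-mode perturbations break it and make
    the force jump at heel strike, so the excess real part is subtracted from
    the dominant (first) mode, which leaves s(0) exactly at its reference
    value while changing |s0_1| by at most a percent.
    """
    excess = sum(m.s0.real for m in modes) - sum(m.s0.real for m in ref)
    first = modes[0]
    return [ModeParams(first.alpha, first.freq, first.s0 - excess)] + modes[1:]


def make_cohort(spec: CohortSpec) -> list[PersonProfile]:
    """Draw a cohort of person profiles around the base mode table.

    Between-person spread: decay rates and |s0| are scaled by
    ``1 + separation * z`` (z standard normal) and frequencies shifted by
    ``separation * 0.3 Hz * z``; ``separation=0`` makes every profile
    identical to the base.  The lowest-frequency pair keeps the largest
    |s0| by construction of the base table.  Deterministic given the seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    base = BASE_MODES[: spec.n_modes]
    profiles = []
    for i in range(spec.n_persons):
        z = rng.standard_normal((spec.n_modes, 3))
        modes = []
        for k, (a, f, s0) in enumerate(base):
            alpha = a * (1.0 + spec.separation * z[k, 0])
            alpha = min(alpha, -0.1)                      # keep decaying
            freq = f + spec.separation * FREQ_SEPARATION_SCALE * z[k, 1]
            freq = float(np.clip(freq, 0.05, 24.0))
            s0k = s0 * (1.0 + spec.separation * z[k, 2])
            modes.append(ModeParams(alpha, freq, s0k))
        modes = _rebalance_first_contact(
            modes, [ModeParams(a, f, s) for a, f, s in base])
        modes.sort(key=lambda m: m.freq)
        prof = PersonProfile(person_id=f"p{i:02d}", modes=modes)
        prof.validate()
        profiles.append(prof)
    return profiles


def draw_step_params(profile: PersonProfile, rng: np.random.Generator) -> list[ModeParams]:
    """One step's jittered copy of the profile's triplets.

    Multiplicative Gaussian jitter on alpha and s0, additive on frequency;
    the dominant mode's real part is rebalanced so the signal still starts
    at the profile's first-contact value (near zero) after jittering.
    """
    j = profile.jitter
    out = []
    for m in profile.modes:
        alpha = m.alpha * (1.0 + j.alpha_rel * rng.standard_normal())
        alpha = min(alpha, -1e-3)
        freq = max(m.freq + j.freq_hz * rng.standard_normal(), 0.0)
        s0 = m.s0 * (1.0 + j.s0_rel * rng.standard_normal())
        out.append(ModeParams(alpha, freq, s0))
    return _rebalance_first_contact(out, profile.modes)


def step_force_from_params(modes: list[ModeParams], n_frames: int,
                           dt: float) -> NDArray[np.floating]:
    """Exact K-pair expansion s_n = sum_k 2 e^{alpha n dt} Re(s0 e^{2 pi i f n dt})."""
    t = np.arange(n_frames) * dt
    out = np.zeros(n_frames)
    for m in modes:
        out += 2.0 * (m.s0 * np.exp((m.alpha + 2j * np.pi * m.freq) * t)).real
    return out


def simulate_step_force(profile: PersonProfile, rng: np.random.Generator,
                        n_frames: int = 100, dt: float = 0.02,
                        rectify: bool = False,
                        return_params: bool = False):
    """Simulate one step's force signal (StepSignal).

    With jitter and noise zero the output is the exact K-pair expansion of
    the profile's triplets — the analytic oracle for the decomposition.
    Measurement noise acts only over the stance window of the expansion
    (walkway sensors read exact zeros off contact, so frames past toe-off
    carry no noise).  ``rectify=True`` clips the signal at zero (pressures
    are non-negative; the 2D renderer uses this), at the cost of breaking
    the linear model.  The stance length is the first contact run of the
    signal (see ``contact_run_length``); values beyond it are kept as
    generated (the expansion's low-level ringing) unless steps are cropped
    and re-padded via ``StepSignal.from_force``.
    """
    from .pressure import contact_run_length

    params = draw_step_params(profile, rng)
    values = step_force_from_params(params, n_frames, dt)
    support_end = contact_run_length(values)
    if profile.noise_sd > 0 and support_end:
        values[:support_end] += profile.noise_sd * rng.standard_normal(support_end)
    if rectify:
        values = np.clip(values, 0.0, None)
    stance = contact_run_length(values)
    sig = StepSignal(values=values, dt=dt, stance_len=stance,
                     person=profile.person_id)
    return (sig, params) if return_params else sig


#: Fixed condition rescalings: fast walking compresses stance (larger decay
#: rates and frequencies) and lands slightly harder; feet differ by a small
#: asymmetry in decay and amplitude.
SPEED_SCALES = {"normal": (1.0, 1.0, 1.0), "fast": (1.15, 1.15, 1.06)}
FOOT_SCALES = {"l": (1.0, 1.0, 1.0), "r": (1.03, 1.0, 0.97)}


def condition_variant(profile: PersonProfile, foot: str, speed: str) -> PersonProfile:
    """The profile's fixed per-condition variant for one foot and speed."""
    fa, ff, fs = FOOT_SCALES[foot]
    sa, sf, ss = SPEED_SCALES[speed]
    return profile.scaled(alpha_scale=fa * sa, freq_scale=ff * sf,
                          s0_scale=fs * ss, suffix=f"/{foot}/{speed}")


def simulate_cohort_steps(profiles: list[PersonProfile], steps_per_person: int,
                          seed: int, feet=("l", "r"), speeds=("normal",),
                          n_frames: int = 100, dt: float = 0.02,
                          rectify: bool = False) -> dict:
    """Step signals for every (person, foot, speed) condition.

    Returns a dict mapping ``(person_id, foot, speed)`` to a list of
    labelled StepSignal.  Each person gets an independent RNG substream, so
    cohort composition does not perturb any individual's steps.
    """
    root = np.random.default_rng(seed)
    streams = root.spawn(len(profiles))
    out: dict[tuple[str, str, str], list[StepSignal]] = {}
    for prof, rng in zip(profiles, streams):
        for foot in feet:
            for speed in speeds:
                var = condition_variant(prof, foot, speed)
                sigs = []
                for c in range(steps_per_person):
                    sig = simulate_step_force(var, rng, n_frames=n_frames,
                                              dt=dt, rectify=rectify)
                    sig.person = prof.person_id
                    sig.foot = foot
                    sig.speed = speed
                    sig.cycle = c
                    sigs.append(sig)
                out[(prof.person_id, foot, speed)] = sigs
    return out


# ---------------------------------------------------------------------------
# 2D rendering
# ---------------------------------------------------------------------------

@dataclass
class StepTruth:
    """Ground-truth metadata of one rendered step (canonical orientation)."""

    pass_index: int
    foot: str
    cycle: int                  # per-foot order within the pass
    start_frame: int            # absolute frame of first rendered sample
    stance_len: int
    row_range: tuple[int, int]  # half-open, canonical (post-normalization) coords
    col_range: tuple[int, int]
    values: NDArray[np.floating]    # rendered force series, N (zero outside stance)


_FOOT_ROWS = 18
_FOOT_COLS = 10
# (row center, col center, row sigma, col sigma) within the footprint box
_BLOBS = ((3.0, 4.5, 2.2, 2.2),     # heel
          (12.0, 4.5, 2.8, 2.8),    # metatarsals
          (16.0, 4.5, 1.6, 2.0))    # toes


def _blob_kernels() -> NDArray:
    r = np.arange(_FOOT_ROWS)[:, None]
    c = np.arange(_FOOT_COLS)[None, :]
    kernels = []
    for rc, cc, sr, sc in _BLOBS:
        g = np.exp(-((r - rc) ** 2) / (2 * sr**2) - ((c - cc) ** 2) / (2 * sc**2))
        kernels.append(g / g.sum())
    return np.stack(kernels)


def _phase_weights(phase: NDArray) -> NDArray:
    """Heel -> metatarsal -> toe load transfer over the stance (rows sum to 1)."""
    p = np.clip(phase, 0.0, 1.0)
    w_heel = np.cos(0.5 * np.pi * np.clip(p / 0.5, 0, 1)) ** 2
    w_toe = np.sin(0.5 * np.pi * np.clip((p - 0.5) / 0.5, 0, 1)) ** 2
    w_met = 1.0 - w_heel - w_toe
    return np.stack([w_heel, w_met, w_toe], axis=1)


def simulate_recording(profile: PersonProfile, geometry: WalkwayGeometry | None = None,
                       n_passes: int = 4, steps_per_pass: int = 8,
                       seed: int | np.random.Generator = 0,
                       step_period: int = 28, gap_frames: int = 10,
                       pad_to: int = 100
                       ) -> tuple[PressureRecording, list[StepTruth]]:
    """Render a multi-pass walkway recording for one person.

    Passes alternate walking direction (odd passes are stored flipped row-
    and column-wise, exactly undone by direction normalization) and are
    separated by ``gap_frames`` all-zero frames.  Steps alternate feet along
    the walkway with the left foot laterally offset to the higher columns
    (canonical orientation).  Each step's rendered per-frame spatial
    integral equals its (rectified) force signal exactly; truth metadata is
    returned in canonical orientation for comparison after normalization.
    """
    geometry = geometry or WalkwayGeometry()
    geometry.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    margin = 6
    if steps_per_pass > 1:
        stride = (geometry.n_rows - 2 * margin - _FOOT_ROWS) // (steps_per_pass - 1)
    else:
        stride = 0
    if steps_per_pass > 1 and stride < _FOOT_ROWS + 2:
        raise ValueError(
            f"walkway of {geometry.n_rows} rows cannot hold {steps_per_pass} "
            f"non-overlapping steps; use a larger geometry or fewer steps")
    mid = (geometry.n_cols - 1) / 2.0
    col_off = {"l": int(round(mid + 7 - _FOOT_COLS / 2)),
               "r": int(round(mid - 7 - _FOOT_COLS / 2))}
    if col_off["r"] < 0 or col_off["l"] + _FOOT_COLS > geometry.n_cols:
        raise ValueError("walkway too narrow for the lateral foot offsets")

    pass_active = (steps_per_pass - 1) * step_period + pad_to if steps_per_pass else 0
    total = gap_frames + n_passes * (pass_active + gap_frames)
    if n_passes == 0:
        total = gap_frames
    tensor = np.zeros((total, geometry.n_rows, geometry.n_cols))
    kernels = _blob_kernels()
    cell_area = geometry.cell_size**2
    truths: list[StepTruth] = []

    for p in range(n_passes):
        p_start = gap_frames + p * (pass_active + gap_frames)
        foot_counts = {"l": 0, "r": 0}
        for i in range(steps_per_pass):
            foot = "r" if i % 2 == 0 else "l"
            sig = simulate_step_force(profile, rng, n_frames=pad_to,
                                      dt=geometry.dt, rectify=True)
            t0 = p_start + i * step_period
            r0 = margin + i * stride
            c0 = col_off[foot]
            stance = max(sig.stance_len, 1)
            # render the active span only: sub-threshold lead-in and tail of
            # the rectified signal are (near-)exact zeros and would split
            # passes at the zero-gap rule
            peak = sig.values.max()
            act = np.flatnonzero(sig.values > CONTACT_REL_THRESHOLD * peak)
            first = int(act[0]) if act.size else 0
            phase = np.arange(first, stance) / stance
            w = _phase_weights(phase)                       # (stance - first, 3)
            # (frames, rows, cols) footprint: per-frame integral == values[n]
            shapes = np.einsum("nj,jrc->nrc", w, kernels)
            block = shapes * (sig.values[first:stance, None, None] / cell_area)
            tensor[t0 + first:t0 + stance, r0:r0 + _FOOT_ROWS, c0:c0 + _FOOT_COLS] += block
            truth_values = np.zeros_like(sig.values)
            truth_values[first:stance] = sig.values[first:stance]
            truths.append(StepTruth(pass_index=p, foot=foot,
                                    cycle=foot_counts[foot], start_frame=t0,
                                    stance_len=sig.stance_len,
                                    row_range=(r0, r0 + _FOOT_ROWS),
                                    col_range=(c0, c0 + _FOOT_COLS),
                                    values=truth_values))
            foot_counts[foot] += 1
        if p % 2 == 1:
            sl = slice(p_start, p_start + pass_active)
            tensor[sl] = tensor[sl, ::-1, ::-1]
    rec = PressureRecording(tensor=tensor, dt=geometry.dt,
                            cell_size=geometry.cell_size)
    return rec, truths


# ---------------------------------------------------------------------------
# ground-truth serialization
# ---------------------------------------------------------------------------

def cohort_to_json(profiles: list[PersonProfile], path) -> None:
    data = []
    for p in profiles:
        data.append({
            "person_id": p.person_id,
            "modes": [[m.alpha, m.freq, m.s0.real, m.s0.imag] for m in p.modes],
            "jitter": {"alpha_rel": p.jitter.alpha_rel, "s0_rel": p.jitter.s0_rel,
                       "freq_hz": p.jitter.freq_hz},
            "noise_sd": p.noise_sd,
        })
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)


def cohort_from_json(path) -> list[PersonProfile]:
    with open(path) as fh:
        data = json.load(fh)
    out = []
    for d in data:
        modes = [ModeParams(a, f, complex(re, im)) for a, f, re, im in d["modes"]]
        out.append(PersonProfile(person_id=d["person_id"], modes=modes,
                                 jitter=Jitter(**d["jitter"]),
                                 noise_sd=d["noise_sd"]))
    return out
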