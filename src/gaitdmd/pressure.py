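"""Walkway pressure recordings: I/O and preprocessing into per-step force signals.

A recording is a calibrated 3D tensor (frame x row x column) of plantar
pressures in Pa sampled at a fixed frame interval on a grid of square
cells; rows run along the walking direction and columns across it.  The
preprocessing chain mirrors how walkway data are condensed for temporal
analysis:

1. `segment_passes` — split the recording at runs of all-zero frames (the
   walker off the mat, turning around) into passes;
2. `normalize_direction` — flip every other pass row- and column-wise so
   all passes share one walking direction, with the left foot in the
   higher columns;
3. `detect_steps` — threshold the time-integrated pressure map, label
   8-connected footprints, assign foot side by column centroid and cycle
   index by first contact;
4. `extract_step_signal` — spatially integrate each footprint box per
   frame (pressure times cell area, giving Newtons), re-index so first
   contact is frame 0, and zero-pad to a fixed length (default 100
   frames, i.e. 2 s at 50 Hz).

The zero padding matters downstream: it makes every step signal decay to
zero, which keeps the fitted DMD eigenvalues inside the unit circle.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy import ndimage

_log = logging.getLogger(__name__)

#: A frame belongs to a step's stance while its in-box force exceeds this
#: fraction of the step's peak force.
CONTACT_REL_THRESHOLD = 5e-3


def contact_run_length(values, rel_threshold: float = CONTACT_REL_THRESHOLD,
                       max_gap: int = 5) -> int:
    """Stance length: end of the first above-threshold contact run.

    Frames count as contact while the positive force exceeds
    ``rel_threshold`` of the peak (contact pressure cannot pull); brief dips
    shorter than ``max_gap`` frames (mid-stance near-zeros, noise) are
    bridged, but a longer quiet spell ends the stance, so low-level ringing
    after toe-off is excluded.
    """
    v = np.clip(np.asarray(values, dtype=float).ravel(), 0.0, None)
    peak = v.max() if v.size else 0.0
    if peak <= 0:
        return 0
    act = np.flatnonzero(v > rel_threshold * peak)
    if act.size == 0:
        return 0
    end = int(act[0])
    for i in act[1:]:
        if int(i) - end - 1 >= max_gap:
            break
        end = int(i)
    return end + 1


@dataclass
class PressureRecording:
    """Calibrated pressure tensor (frames x rows x cols) with grid metadata."""

    tensor: NDArray[np.floating]
    dt: float = 0.02            # s
    cell_size: float = 0.005    # m
    units: str = "Pa"

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.ndim != 3:
            raise ValueError(f"tensor must be 3D (frames, rows, cols), got shape {self.tensor.shape}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if np.any(self.tensor < 0):
            raise ValueError("pressures must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.tensor.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensor.shape


@dataclass
class Pass:
    """One maximal run of active frames: the walker crossing the mat once."""

    tensor: NDArray[np.floating]
    frame_range: tuple[int, int]     # half-open [start, end) into the recording
    index: int
    dt: float
    cell_size: float
    normalized: bool = False

    @property
    def direction(self) -> str:
        """Walking direction by alternation convention: even passes canonical."""
        return "canonical" if self.index % 2 == 0 else "reversed"


@dataclass
class StepRegion:
    """One footprint: spatial bounding box plus stance frame window (pass-local)."""

    pass_index: int
    row_range: tuple[int, int]       # half-open
    col_range: tuple[int, int]       # half-open
    frame_range: tuple[int, int]     # half-open, frames within the pass
    foot: str                        # 'l' | 'r'
    cycle: int                       # per-foot cycle index, 0-based


@dataclass
class StepSignal:
    """Spatially integrated force series of one step, zero-padded.

    ``values`` is in Pa*m^2 = N, indexed so first contact is frame 0; entries
    at and beyond ``stance_len`` are exactly zero.
    """

    values: NDArray[np.floating]
    dt: float
    stance_len: int
    foot: str | None = None
    cycle: int | None = None
    person: str | None = None
    speed: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.stance_len > self.values.size:
            raise ValueError("stance_len exceeds signal length")

    @property
    def n_frames(self) -> int:
        return self.values.size

    @classmethod
    def from_force(cls, force, dt: float, pad_to: int = 100,
                   rel_threshold: float = CONTACT_REL_THRESHOLD, **labels) -> "StepSignal":
        """Crop a raw force series at the contact threshold and zero-pad.

        The stance is the initial contact run of the series (frames above
        ``rel_threshold`` of peak force, brief dips bridged); everything
        beyond is set to exactly zero and the series padded (or an error
        raised if the stance exceeds ``pad_to``).
        """
        f = np.asarray(force, dtype=float).ravel()
        stance = contact_run_length(f, rel_threshold=rel_threshold)
        if stance > pad_to:
            raise ValueError(
                f"stance of {stance} frames exceeds pad_to={pad_to}; increase pad_to")
        out = np.zeros(pad_to)
        out[:stance] = np.clip(f[:stance], 0.0, None)
        return cls(values=out, dt=dt, stance_len=stance, **labels)


# ---------------------------------------------------------------------------
# text frame format
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(
    r"#\s*dt=(?P<dt>[\d.eE+-]+)\s+cell=(?P<cell>[\d.eE+-]+)"
    r"\s+rows=(?P<rows>\d+)\s+cols=(?P<cols>\d+)\s+frames=(?P<frames>\d+)")


def write_frames_text(rec: PressureRecording, path) -> None:
    """Write the plain-text frame-block dialect (header, then per-frame rows)."""
    F, R, C = rec.tensor.shape
    with open(path, "w") as fh:
        fh.write(f"# dt={rec.dt:g} cell={rec.cell_size:g} rows={R} cols={C} frames={F}\n")
        for k in range(F):
            fh.write(f"Frame {k}\n")
            for row in rec.tensor[k]:
                fh.write(",".join(f"{x:g}" for x in row) + "\n")


def read_frames_text(path) -> PressureRecording:
    """Read the text frame dialect written by :func:`write_frames_text`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file is not a valid recording")
    m = _HEADER_RE.match(lines[0])
    if not m:
        raise ValueError(f"{path}: missing or malformed header line")
    dt, cell = float(m["dt"]), float(m["cell"])
    R, C, F = int(m["rows"]), int(m["cols"]), int(m["frames"])
    tensor = np.empty((F, R, C))
    pos = 1
    for k in range(F):
        if pos >= len(lines) or not lines[pos].startswith("Frame"):
            raise ValueError(f"{path}: expected 'Frame {k}' marker at line {pos + 1}")
        pos += 1
        for r in range(R):
            if pos >= len(lines):
                raise ValueError(f"{path}: frame {k} truncated (row {r} missing)")
            fields = lines[pos].split(",")
            if len(fields) != C:
                raise ValueError(
                    f"{path}: frame {k} row {r} has {len(fields)} columns, expected {C}")
            tensor[k, r] = [float(x) for x in fields]
            pos += 1
    return PressureRecording(tensor=tensor, dt=dt, cell_size=cell)


def write_frames_h5(rec: PressureRecording, path) -> None:
    """Binary container: HDF5 dataset ``pressure`` with dt/cell_size attrs."""
    import h5py

    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("pressure", data=rec.tensor, compression="gzip")
        ds.attrs["dt"] = rec.dt
        ds.attrs["cell_size"] = rec.cell_size
        ds.attrs["units"] = rec.units


def read_frames_h5(path) -> PressureRecording:
    import h5py

    with h5py.File(path, "r") as fh:
        ds = fh["pressure"]
        return PressureRecording(tensor=ds[...], dt=float(ds.attrs["dt"]),
                                 cell_size=float(ds.attrs["cell_size"]),
                                 units=str(ds.attrs.get("units", "Pa")))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def segment_passes(rec: PressureRecording, min_gap: int = 5) -> list[Pass]:
    """Split a recording into passes at all-zero gaps of at least ``min_gap`` frames.

    Passes are maximal runs of frames bounded by qualifying zero gaps, trimmed
    so they start and end on active (non-zero) frames; an all-zero recording
    yields an empty list.
    """
    if min_gap < 1:
        raise ValueError(f"min_gap must be >= 1, got {min_gap}")
    active = rec.tensor.reshape(rec.n_frames, -1).any(axis=1)
    idx = np.flatnonzero(active)
    if idx.size == 0:
        return []
    # break where consecutive active frames are separated by >= min_gap zeros
    gaps = np.diff(idx) - 1
    breaks = np.flatnonzero(gaps >= min_gap)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    passes = []
    for i, (a, b) in enumerate(zip(starts, ends)):
        lo, hi = int(idx[a]), int(idx[b]) + 1
        passes.append(Pass(tensor=rec.tensor[lo:hi].copy(), frame_range=(lo, hi),
                           index=i, dt=rec.dt, cell_size=rec.cell_size))
    return passes


def normalize_direction(p: Pass, pass_index: int | None = None) -> Pass:
    """Flip odd-indexed passes row- and column-wise to a common walking direction.

    After normalization all passes share the even-pass orientation (left foot
    in the higher columns).  Normalizing an already normalized pass is an
    error — the flip is an involution and applying it twice would silently
    restore the raw orientation.
    """
    if p.normalized:
        raise ValueError(f"pass {p.index} is already normalized")
    i = p.index if pass_index is None else pass_index
    tensor = p.tensor[:, ::-1, ::-1].copy() if i % 2 == 1 else p.tensor.copy()
    return Pass(tensor=tensor, frame_range=p.frame_range, index=p.index,
                dt=p.dt, cell_size=p.cell_size, normalized=True)


def detect_steps(p: Pass, contact_threshold: float = CONTACT_REL_THRESHOLD,
                 min_area: int = 20) -> list[StepRegion]:
    """Detect footprints in a normalized pass.

    The pressure tensor is integrated over time and thresholded; 8-connected
    components with at least ``min_area`` cells become steps (a full footprint
    covers ~430 cells at 5 mm resolution, so smaller specks are noise).  Foot
    side follows the column centroid relative to the walkway midline (left =
    higher columns); per-foot cycle indices follow first-contact order; the
    stance window spans frames where the in-box force exceeds
    ``contact_threshold`` of that step's peak.
    """
    if not p.normalized:
        raise ValueError("pass must be direction-normalized before step detection")
    integ = p.tensor.sum(axis=0)
    mask = integ > 0
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    mid = (p.tensor.shape[2] - 1) / 2.0
    regions = []
    for sl in ndimage.find_objects(labels):
        if sl is None:
            continue
        comp = labels[sl] > 0
        if comp.sum() < min_area:
            continue
        r0, r1 = sl[0].start, sl[0].stop
        c0, c1 = sl[1].start, sl[1].stop
        cols = np.nonzero(comp)[1] + c0
        foot = "l" if cols.mean() > mid else "r"
        series = p.tensor[:, r0:r1, c0:c1].sum(axis=(1, 2))
        peak = series.max()
        if peak <= 0:
            continue
        on = np.flatnonzero(series > contact_threshold * peak)
        regions.append(StepRegion(pass_index=p.index, row_range=(r0, r1),
                                  col_range=(c0, c1),
                                  frame_range=(int(on[0]), int(on[-1]) + 1),
                                  foot=foot, cycle=-1))
    # per-foot cycle indices in first-contact order
    for foot in ("l", "r"):
        of_foot = sorted((r for r in regions if r.foot == foot),
                         key=lambda r: r.frame_range[0])
        for c, r in enumerate(of_foot):
            r.cycle = c
    regions.sort(key=lambda r: r.frame_range[0])
    return regions


def extract_step_signal(p: Pass, region: StepRegion, pad_to: int = 100) -> StepSignal:
    """Integrate one footprint box into its temporal force signal.

    ``values[n]`` is the sum of pressures in the box at stance frame n times
    the cell area (units Pa*m^2 = N), with first contact re-indexed to n = 0
    and trailing zeros appended up to ``pad_to``.
    """
    f0, f1 = region.frame_range
    stance = f1 - f0
    if stance > pad_to:
        raise ValueError(
            f"stance of {stance} frames exceeds pad_to={pad_to}; increase pad_to")
    r0, r1 = region.row_range
    c0, c1 = region.col_range
    series = p.tensor[f0:f1, r0:r1, c0:c1].sum(axis=(1, 2)) * p.cell_size**2
    out = np.zeros(pad_to)
    out[:stance] = series
    return StepSignal(values=out, dt=p.dt, stance_len=stance,
                      foot=region.foot, cycle=region.cycle)


def preprocess_recording(rec: PressureRecording, min_gap: int = 5,
                         pad_to: int = 100,
                         contact_threshold: float = CONTACT_REL_THRESHOLD,
                         min_area: int = 20) -> list[StepSignal]:
    """Full chain: segment passes, normalize direction, detect and extract steps."""
    steps: list[StepSignal] = []
    for p in segment_passes(rec, min_gap=min_gap):
        pn = normalize_direction(p)
        for region in detect_steps(pn, contact_threshold=contact_threshold,
                                   min_area=min_area):
            steps.append(extract_step_signal(pn, region, pad_to=pad_to))
    _log.info("preprocessed recording: %d steps extracted", len(steps))
    return steps
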