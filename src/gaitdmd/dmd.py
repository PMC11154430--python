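"""Exact and Hankel dynamic mode decomposition (DMD) for scalar gait signals.

Exact DMD approximates the Koopman operator of a dynamical system from a
matrix of snapshot columns ``D = [D_0, D_1, ..., D_N]``: with ``X`` the
first N columns and ``Y`` the one-step-shifted copy, the best linear
propagator ``A = Y X^+`` is represented in the subspace of the leading
left singular vectors of ``X``.  Its eigenvalues ``mu_k`` encode a
per-frame decay factor and oscillation angle; the *exact dynamic modes*
``v_k = (1/mu_k) Y V S^-1 w_k`` lift the reduced eigenvectors ``w_k``
back to snapshot space, and projection coefficients ``b_k`` expand the
initial snapshot on the modes, so that ``D_n ~= sum_k mu_k^n v_k b_k``.

A scalar time series has no spatial dimension for the SVD to compress,
so it is first embedded in a Hankel matrix of time-shifted copies
(``entry (i, j) = s[i + j]``) whose columns act as delay-coordinate
snapshots.  For a signal that is exactly a sum of K damped complex
conjugate sinusoid pairs the Hankel matrix has rank 2K and the embedding
recovers every pair's decay rate, frequency and complex amplitude to
machine precision; this is the property the test suite leans on.

The user-facing entry point is :class:`HankelDMD` (a model object whose
``fit`` returns :class:`DMDResults`), with the lower-level functions
(`build_hankel`, `exact_dmd`, `choose_truncation`, `hankel_dmd`,
`reconstruct`) exposed for pipeline use.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass


import numpy as np
from numpy.typing import ArrayLike, NDArray

_log = logging.getLogger(__name__)

#: Singular values below ``SV_FLOOR * sigma_max`` are numerical noise and are
#: always discarded before any rank rule is applied.
SV_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# rank-selection rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankRule:
    """How many singular directions of X to keep.

    Three rules are supported:

    ``fixed(r)``
        keep exactly ``r`` directions (clamped to the numerical rank);
    ``variance_retained(q)``
        smallest r whose cumulative squared singular values reach a
        fraction ``q`` of the total;
    ``error_threshold(eps)``
        smallest r whose rank-r model satisfies ``||Y - A X||_2 <= eps``.
        With ``eps=None`` the threshold is scaled to the data matrix as
        ``1e-6 * (n_rows + n_cols)`` of the snapshot matrix, the scaling
        used throughout the gait pipeline for Hankel-embedded steps.
    """

    kind: str
    value: float | None = None

    @classmethod
    def fixed(cls, r: int) -> "RankRule":
        if r < 1:
            raise ValueError(f"fixed rank must be >= 1, got {r}")
        return cls("fixed", int(r))

    @classmethod
    def variance_retained(cls, q: float) -> "RankRule":
        if not 0.0 < q <= 1.0:
            raise ValueError(f"variance fraction must be in (0, 1], got {q}")
        return cls("variance", float(q))

    @classmethod
    def error_threshold(cls, eps: float | None = None) -> "RankRule":
        if eps is not None and eps <= 0:
            raise ValueError(f"error threshold must be > 0, got {eps}")
        return cls("error", eps)


@dataclass
class SnapshotPair:
    """One-step-shifted snapshot matrices X (columns D_0..D_{N-2}) and Y (D_1..D_{N-1})."""

    X: NDArray[np.floating]
    Y: NDArray[np.floating]

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.X.shape != self.Y.shape:
            raise ValueError(
                f"X and Y must have identical shapes, got {self.X.shape} vs {self.Y.shape}"
            )

    @classmethod
    def from_snapshots(cls, D: ArrayLike) -> "SnapshotPair":
        D = np.atleast_2d(np.asarray(D, dtype=float))
        if D.shape[1] < 2:
            raise ValueError("need at least 2 snapshot columns")
        return cls(D[:, :-1], D[:, 1:])


def build_hankel(series: ArrayLike, rows: int, cols: int | None = None) -> NDArray:
    """Hankel (time-delay) matrix with entry (i, j) = series[i + j].

    The first row reproduces the first ``cols`` entries of the series; each
    subsequent row is the series shifted by one frame.  ``cols`` defaults to
    the largest value the series supports, ``len(series) - rows + 1``.
    """
    s = np.asarray(series, dtype=float).ravel()
    if rows < 1:
        raise ValueError(f"rows must be >= 1, got {rows}")
    if cols is None:
        cols = s.size - rows + 1
    need = rows + cols - 1
    if s.size < need:
        raise ValueError(
            f"series of length {s.size} too short for a {rows}x{cols} Hankel "
            f"matrix (needs {need} samples)"
        )
    idx = np.arange(rows)[:, None] + np.arange(cols)[None, :]
    return s[idx]


# ---------------------------------------------------------------------------
# exact DMD
# ---------------------------------------------------------------------------

def _thin_svd(X: NDArray) -> tuple[NDArray, NDArray, NDArray]:
    W, s, Vh = np.linalg.svd(X, full_matrices=False)
    keep = s > SV_FLOOR * s[0]
    n = int(np.count_nonzero(keep))
    return W[:, :n], s[:n], Vh[:n]


def _residual_norm(Y: NDArray, Vh: NDArray, r: int) -> float:
    """Spectral norm of Y - A_r X = Y (I - V_r V_r*) for the rank-r model."""
    Vr = Vh[:r]
    resid = Y - (Y @ Vr.conj().T) @ Vr
    return float(np.linalg.norm(resid, 2))


def _select_rank(s: NDArray, Y: NDArray, Vh: NDArray, rule: RankRule,
                 scale_dims: tuple[int, int] | None = None) -> int:
    nkeep = s.size
    if rule.kind == "fixed":
        r = int(rule.value)
        if r > nkeep:
            _log.warning("requested rank %d exceeds numerical rank %d; clamping", r, nkeep)
            r = nkeep
        return r
    if rule.kind == "variance":
        energy = np.cumsum(s**2)
        target = rule.value * energy[-1]
        # smallest r with cumulative energy >= q * total (tolerate rounding)
        r = int(np.searchsorted(energy, target * (1 - 1e-14)) + 1)
        return min(r, nkeep)
    if rule.kind == "error":
        eps = rule.value
        if eps is None:
            if scale_dims is None:
                scale_dims = (Y.shape[0], Y.shape[1] + 1)
            eps = 1e-6 * (scale_dims[0] + scale_dims[1])
        for r in range(1, nkeep + 1):
            if _residual_norm(Y, Vh, r) <= eps:
                return r
        _log.warning("error threshold %.3g unattainable at full rank %d", eps, nkeep)
        return nkeep
    raise ValueError(f"unknown rank rule kind {rule.kind!r}")


@dataclass
class DMDModel:
    """Result of one exact / Hankel DMD fit.

    Attributes
    ----------
    eigvals
        Complex eigenvalues ``mu_k`` of the reduced propagator (per-frame
        multipliers), ordered by descending mode energy ``|v_k b_k|``.
    modes
        Exact dynamic modes as columns (snapshot-space vectors).
    amplitudes
        Projection coefficients ``b_k`` of the initial snapshot on the modes.
    rank
        Retained truncation rank r.
    fit_error
        ``||Y - A X||_2`` of the rank-r model (spectral norm).
    dt
        Frame interval in seconds (carried for feature conversion).
    hankel_rows
        Row count of the Hankel embedding, when the model came from one.
    """

    eigvals: NDArray[np.complexfloating]
    modes: NDArray[np.complexfloating]
    amplitudes: NDArray[np.complexfloating]
    rank: int
    fit_error: float
    dt: float
    hankel_rows: int | None = None

    @property
    def mode_scalars(self) -> NDArray[np.complexfloating]:
        """First element of each exact mode: the scalar v_k of the delay embedding."""
        return self.modes[0, :]

    def reconstruct(self, n_frames: int) -> NDArray[np.floating]:
        return reconstruct(self, n_frames)

    # --- serialization (complex numbers as [re, im] pairs) ---

    def to_dict(self) -> dict:
        c = lambda a: np.stack([np.real(a), np.imag(a)], axis=-1).tolist()
        return {
            "eigvals": c(self.eigvals),
            "modes": c(self.modes),
            "amplitudes": c(self.amplitudes),
            "rank": self.rank,
            "fit_error": self.fit_error,
            "dt": self.dt,
            "hankel_rows": self.hankel_rows,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "DMDModel":
        cplx = lambda a: np.asarray(a, dtype=float)[..., 0] + 1j * np.asarray(a, dtype=float)[..., 1]
        return cls(
            eigvals=cplx(d["eigvals"]),
            modes=cplx(d["modes"]),
            amplitudes=cplx(d["amplitudes"]),
            rank=int(d["rank"]),
            fit_error=float(d["fit_error"]),
            dt=float(d["dt"]),
            hankel_rows=d.get("hankel_rows"),
        )

    @classmethod
    def from_json(cls, path) -> "DMDModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def choose_truncation(pair: SnapshotPair, rule: RankRule) -> int:
    """Truncation rank r chosen by `rule` on the snapshot pair.

    The error-threshold rule returns the smallest r whose rank-r propagator
    satisfies ``||Y - A X||_2 <= eps``; the variance rule the smallest r whose
    cumulative squared singular values reach the requested fraction.  Both are
    monotone: a looser threshold never yields a larger r.
    """
    _, s, Vh = _thin_svd(pair.X)
    return _select_rank(s, pair.Y, Vh, rule,
                        scale_dims=(pair.X.shape[0], pair.X.shape[1] + 1))


def compute_amplitudes(mode_matrix: ArrayLike, first_snapshot: ArrayLike) -> NDArray:
    """Least-squares projection coefficients b with modes @ b = D_0.

    Degenerate (rank-deficient) mode matrices fall back to the minimum-norm
    solution with a warning.
    """
    M = np.atleast_2d(np.asarray(mode_matrix, dtype=complex))
    d0 = np.asarray(first_snapshot, dtype=complex).ravel()
    b, _, rank, _ = np.linalg.lstsq(M, d0, rcond=None)
    if rank < M.shape[1]:
        _log.warning("mode matrix rank-deficient (%d < %d); minimum-norm amplitudes", rank, M.shape[1])
    return b


def exact_dmd(pair: SnapshotPair, rank_rule: RankRule = RankRule.error_threshold(),
              dt: float = 1.0, projected: bool = False) -> DMDModel:
    """SVD-based exact DMD of a snapshot pair.

    Computes the thin SVD of X, truncates per ``rank_rule``, eigendecomposes
    the reduced propagator ``A_hat = W* Y V S^-1``, and lifts eigenvectors to
    exact dynamic modes ``v_k = (1/mu_k) Y V S^-1 w_k`` (or projected modes
    ``W w_k`` when ``projected=True``).  Amplitudes solve
    ``modes @ b = D_0`` in least squares.  Modes are ordered by descending
    energy ``|v_k[0] b_k|``.
    """
    X, Y = pair.X, pair.Y
    if not np.any(X):
        raise ValueError("zero data matrix: DMD undefined")
    W, s, Vh = _thin_svd(X)
    r = _select_rank(s, Y, Vh, rank_rule,
                     scale_dims=(X.shape[0], X.shape[1] + 1))
    Wr, sr, Vhr = W[:, :r], s[:r], Vh[:r]
    B = (Y @ Vhr.conj().T) / sr       # Y V S^-1, shape (M, r)
    Ahat = Wr.conj().T @ B
    mu, w = np.linalg.eig(Ahat)
    lifted = B @ w
    if projected:
        modes = Wr @ w
    else:
        # exact modes need 1/mu; a (numerically) zero eigenvalue falls back to
        # the projected mode for that column
        safe = np.abs(mu) > SV_FLOOR
        modes = np.empty_like(lifted)
        modes[:, safe] = lifted[:, safe] / mu[safe]
        if not np.all(safe):
            modes[:, ~safe] = (Wr @ w)[:, ~safe]
    b = compute_amplitudes(modes, X[:, 0])
    order = np.argsort(-np.abs(modes[0, :] * b), kind="stable")
    return DMDModel(
        eigvals=mu[order],
        modes=modes[:, order],
        amplitudes=b[order],
        rank=r,
        fit_error=_residual_norm(Y, Vh, r),
        dt=dt,
    )


# ---------------------------------------------------------------------------
# Hankel DMD for scalar step signals
# ---------------------------------------------------------------------------

def _row_candidates(n: int, stance_len: int | None) -> list[int]:
    """Auto grid of Hankel row counts: stance length, half of it, and 25.

    Candidates violating rows >= 2 or the aspect requirement cols >= rows
    (cols = n - rows + 1) are dropped.
    """
    cands = []
    if stance_len:
        cands += [stance_len, stance_len // 2]
    cands.append(25)
    out = []
    for r in cands:
        cols = n - r + 1
        if r >= 2 and cols >= r and r not in out:
            out.append(r)
    if not out:
        r = max(2, (n + 1) // 2)
        out.append(r)
    return out


def hankel_dmd(step, rows: int | None = None,
               rank_rule: RankRule = RankRule.error_threshold(),
               dt: float | None = None,
               stance_len: int | None = None) -> DMDModel:
    """Hankel (time-delay) DMD of one step's force signal.

    ``step`` may be a StepSignal (dt and stance length are taken from it) or a
    plain series with ``dt`` given.  With ``rows=None`` a small grid of row
    counts is searched — the stance length, half the stance length, and 25 —
    and the embedding minimising the fit error, preferring those meeting the
    error threshold, is kept.  The scalar mode values v_k are the first
    elements of the exact modes, so the first row of the reconstruction is the
    fitted series.
    """
    values = getattr(step, "values", step)
    if dt is None:
        dt = getattr(step, "dt", None)
        if dt is None:
            raise ValueError("dt required when step is a bare series")
    if stance_len is None:
        stance_len = getattr(step, "stance_len", None)
    series = np.asarray(values, dtype=float).ravel()
    n = series.size
    if rows is None and stance_len is not None and stance_len < 2:
        raise ValueError(f"stance of {stance_len} frames too short for a Hankel embedding")

    candidates = [rows] if rows is not None else _row_candidates(n, stance_len)
    best = None  # (not meets_threshold, fit_error, model)
    for rws in candidates:
        cols = n - rws + 1
        if rws < 2 or cols < 2:
            raise ValueError(f"series of {n} frames cannot support rows={rws}")
        D = build_hankel(series, rws, cols)
        pair = SnapshotPair.from_snapshots(D)
        rule = rank_rule
        if rule.kind == "error" and rule.value is None:
            rule = RankRule.error_threshold(1e-6 * (rws + cols))
            eps = rule.value
        else:
            eps = rule.value if rule.kind == "error" else None
        model = exact_dmd(pair, rule, dt=dt)
        model.hankel_rows = rws
        meets = model.fit_error <= eps if eps is not None else True
        key = (not meets, model.fit_error)
        if best is None or key < best[0]:
            best = (key, model)
    return best[1]


def reconstruct(model: DMDModel, n_frames: int) -> NDArray[np.floating]:
    """Scalar series s_n = sum_k mu_k^n v_k b_k for n = 0 .. n_frames-1.

    For a conjugate-symmetric spectrum the imaginary residual is numerical
    noise; it is checked against the signal scale and the real part returned.
    """
    n = np.arange(int(n_frames))
    vand = model.eigvals[None, :] ** n[:, None]
    series = vand @ (model.mode_scalars * model.amplitudes)
    scale = np.max(np.abs(series)) or 1.0
    imag = np.max(np.abs(series.imag))
    if imag > 1e-6 * scale:
        _log.warning("reconstruction imaginary residual %.3g of signal scale", imag / scale)
    return np.ascontiguousarray(series.real)


# ---------------------------------------------------------------------------
# model-object interface
# ---------------------------------------------------------------------------

class HankelDMD:
    """Hankel-DMD model of one step's plantar-force signal.

    Parameters
    ----------
    signal : array-like or StepSignal
        Force series, one gait cycle, zero-padded per the pipeline convention.
    dt : float
        Frame interval in seconds (default 0.02, i.e. 50 Hz).
    rows : int, optional
        Hankel row count; ``None`` searches the auto grid.
    rank_rule : RankRule
        Truncation rule (default: error threshold ``1e-6 (N + M)``).

    Examples
    --------
    >>> model = HankelDMD(step.values, dt=0.02, rank_rule=RankRule.fixed(12))
    >>> res = model.fit()
    >>> res.summary()          # doctest: +SKIP
    """

    def __init__(self, signal, dt: float = 0.02, rows: int | None = None,
                 rank_rule: RankRule = RankRule.error_threshold(),
                 stance_len: int | None = None):
        self.signal = np.asarray(getattr(signal, "values", signal), dtype=float).ravel()
        self.dt = float(getattr(signal, "dt", dt))
        self.rows = rows
        self.rank_rule = rank_rule
        self.stance_len = stance_len if stance_len is not None else getattr(signal, "stance_len", None)

    def fit(self) -> "DMDResults":
        model = hankel_dmd(self.signal, rows=self.rows, rank_rule=self.rank_rule,
                           dt=self.dt, stance_len=self.stance_len)
        return DMDResults(self, model)


class DMDResults:
    """Fit results of :class:`HankelDMD`: spectrum, physical-unit features, diagnostics."""

    def __init__(self, model: HankelDMD, dmd: DMDModel):
        self.model = model
        self.dmd = dmd

    @property
    def eigvals(self) -> NDArray:
        return self.dmd.eigvals

    @property
    def rank(self) -> int:
        return self.dmd.rank

    @property
    def fit_error(self) -> float:
        return self.dmd.fit_error

    def features(self, n_modes: int = 6):
        """Conjugate-pair feature triplets (decay rate, frequency, initial condition)."""
        from .features import featurize_step

        return featurize_step(self.dmd, n_modes=n_modes)

    def reconstruct(self, n_frames: int | None = None) -> NDArray:
        if n_frames is None:
            n_frames = self.model.signal.size
        return reconstruct(self.dmd, n_frames)

    def rel_reconstruction_error(self) -> float:
        """Relative L2 error of the reconstruction over the fitted support."""
        cols = self.model.signal.size - (self.dmd.hankel_rows or 1) + 1
        rec = self.reconstruct(cols)
        ref = self.model.signal[:cols]
        return float(np.linalg.norm(rec - ref) / np.linalg.norm(ref))

    def summary(self) -> str:
        from .features import featurize_step

        fs = featurize_step(self.dmd, n_modes=(self.rank + 1) // 2)
        lines = [
            "Hankel DMD fit",
            f"  frames: {self.model.signal.size}   dt: {self.model.dt:g} s   "
            f"rows: {self.dmd.hankel_rows}   rank r: {self.rank}",
            f"  fit error ||Y - AX||_2: {self.fit_error:.3e}   "
            f"rel. reconstruction error: {self.rel_reconstruction_error():.3e}",
            "  mode   alpha [1/s]    freq [Hz]     |s0|",
        ]
        for k, f in enumerate(fs.features, 1):
            if f.missing:
                lines.append(f"  {k:4d}   (missing)")
            else:
                lines.append(f"  {k:4d}   {f.alpha:10.4f}   {f.freq:10.4f}   {f.s0:10.4f}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<DMDResults rank={self.rank} rows={self.dmd.hankel_rows} "
                f"fit_error={self.fit_error:.3e}>")
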