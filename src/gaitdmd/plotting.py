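"""Quick-look plots: step reconstruction and mode feature scatter."""

from __future__ import annotations

from typing import Sequence

import numpy as np


def plot_reconstruction(signal, results, n_modes_list: Sequence[int] = (1, 2, 6), ax=None):
    """Measured step signal against reconstructions with increasing mode counts."""
    import matplotlib.pyplot as plt

    from .features import featurize_step, reconstruct_from_features

    values = np.asarray(getattr(signal, "values", signal), dtype=float)
    dt = getattr(signal, "dt", results.model.dt)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    t = np.arange(values.size) * dt
    ax.plot(t, values, "k-", lw=2, label="measured")
    for k in n_modes_list:
        fs = featurize_step(results.dmd, n_modes=k)
        rec = reconstruct_from_features(fs, values.size, dt)
        ax.plot(t, rec, "--", label=f"{k} mode(s)")
    ax.set_xlabel("time [s]")
    ax.set_ylabel("plantar force [N]")
    ax.legend(frameon=False)
    return ax


def plot_mode_features(step_sets, ax=None, color_by="mode"):
    """Scatter of (frequency, |s0|) feature points, colored by mode rank."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    K = max(len(fs) for fs in step_sets)
    cmap = plt.get_cmap("tab10")
    for k in range(K):
        f = [fs.features[k].freq for fs in step_sets if not fs.features[k].missing]
        s = [fs.features[k].s0 for fs in step_sets if not fs.features[k].missing]
        ax.scatter(f, s, s=12, color=cmap(k % 10), label=f"mode {k + 1}", alpha=0.6)
    ax.set_xlabel("frequency [Hz]")
    ax.set_ylabel("|s0| [N]")
    ax.set_yscale("log")
    ax.legend(frameon=False, fontsize=8)
    return ax
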