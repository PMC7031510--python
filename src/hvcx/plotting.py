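"""Plotting helpers for traces and error landscapes."""

from __future__ import annotations

import numpy as np

from hvcx.hh import Trace

__all__ = ["plot_trace", "plot_landscape"]


def plot_trace(trace: Trace, ax=None, show_current: bool = True):
    """Voltage (and optionally injected current) of one sweep."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    ax.plot(trace.t, trace.v, lw=0.8, color="k")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("V (mV)")
    nid = trace.meta.get("neuron_id")
    if nid:
        ax.set_title(str(nid))
    if show_current:
        ax2 = ax.twinx()
        ax2.plot(trace.t, trace.i, lw=0.6, color="tab:blue", alpha=0.6)
        ax2.set_ylabel("I (pA)", color="tab:blue")
    return ax


def plot_landscape(slice_df, ax=None, log_error: bool = True):
    """Heat map of a 2-D error slice from ``FitResult.landscape``.

    Disregarded regions (NaN) render blank; the minimum is marked.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    Z = slice_df.to_numpy(float)
    plot_z = np.log10(Z + 1e-12) if log_error else Z
    x = slice_df.columns.to_numpy(float)
    y = slice_df.index.to_numpy(float)
    pc = ax.pcolormesh(x, y, plot_z, shading="nearest", cmap="viridis")
    label = "log10 error" if log_error else "error"
    ax.figure.colorbar(pc, ax=ax, label=label)
    ij = np.unravel_index(np.nanargmin(Z), Z.shape)
    ax.plot(x[ij[1]], y[ij[0]], "r*", ms=12)
    ax.set_xlabel(slice_df.columns.name or "axis 1")
    ax.set_ylabel(slice_df.index.name or "axis 2")
    return ax
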