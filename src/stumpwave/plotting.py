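"""Matplotlib views of traces and representative beats."""
from __future__ import annotations

import numpy as np

__all__ = ["plot_trace", "plot_representative"]


def plot_trace(trace, ax=None, **kwargs):
    """Plot a raw or conditioned pressure trace."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    ax.plot(trace.times, trace.samples, lw=0.8, **kwargs)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("pressure (mmHg)")
    ax.set_title(f"{trace.channel.value} {trace.subject_id}".strip())
    return ax


def plot_representative(results, ax=None):
    """Representative beat with shaded systolic and diastolic areas.

    The systolic area runs from the beat foot to the dicrotic notch, the
    diastolic area (used by the area-method decay constant) from the notch
    to cycle end.
    """
    import matplotlib.pyplot as plt

    from .metrics import _cycle_end, _foot_and_peak

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    beat = results.ensemble
    rep = beat.representative
    t = beat.times
    ax.plot(t, rep, color="k", lw=1.5, label="representative beat")

    foot, _peak = _foot_and_peak(beat)
    cend = _cycle_end(beat, foot)
    notch = results.notch_index
    if notch is not None:
        ax.fill_between(t[foot : notch + 1], rep[foot : notch + 1],
                        rep.min(), alpha=0.25, color="lightgrey",
                        label="systolic area")
        ax.fill_between(t[notch : cend + 1], rep[notch : cend + 1],
                        rep.min(), alpha=0.45, color="grey",
                        label="diastolic area")
        ax.axvline(t[notch], color="grey", ls="--", lw=0.8)
    f = results.features
    ax.set_xlabel("time (s)")
    ax.set_ylabel("pressure (mmHg)")
    ax.set_title(
        f"SBP {f.sbp:.0f} / DBP {f.dbp:.0f} mmHg, tau {f.tau:.2f} s"
        if np.isfinite(f.tau)
        else f"SBP {f.sbp:.0f} / DBP {f.dbp:.0f} mmHg"
    )
    ax.legend(loc="upper right", fontsize=8)
    return ax
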