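"""Minimal plots: CIF step curves and diversity-over-time lines.

matplotlib is imported lazily so the analysis stack works without it.
"""

from __future__ import annotations

from .survival import CIFCurve


def plot_cif(curves: dict[str, CIFCurve], ax=None, title: str = ""):
    """Step plot of one CIF curve per group; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, curve in curves.items():
        ax.step([0.0, *curve.times], [0.0, *curve.cif], where="post", label=label)
    ax.set_xlabel("months")
    ax.set_ylabel("cumulative incidence")
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    ax.legend()
    return ax


def plot_diversity_over_time(samples, ax=None, value: str = "inv_simpson"):
    """Per-subject 1/D trajectories; `samples` is a DataFrame with
    subject_id, timepoint and the value column."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for sid, g in samples.groupby("subject_id"):
        g = g.sort_values("timepoint")
        ax.plot(g["timepoint"], g[value], marker="o", label=str(sid))
    ax.set_xlabel("days relative to DLI")
    ax.set_ylabel("inverse Simpson diversity (1/D)")
    return ax
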