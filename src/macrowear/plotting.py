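"""Ternary diagram of relative wear-area compositions.

Each specimen's (buccal phase I, lingual phase I, phase II incl. tip crush)
triple is a point in the unit equilateral triangle; vertices are 100% of a
component, the opposite base is 0%.
"""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

_CORNERS = [(0.0, 0.0), (1.0, 0.0), (0.5, math.sqrt(3) / 2.0)]
_LABELS = ["buccal PI", "lingual PI", "phase II"]


def plot_ternary(coords: pd.DataFrame, out_path=None, hue: str = "taxon"):
    """Scatter ternary coordinates (from :func:`macrowear.cohort.ternary_coordinates`)."""
    fig, ax = plt.subplots(figsize=(6, 5.5))
    xs, ys = zip(*(_CORNERS + [_CORNERS[0]]))
    ax.plot(xs, ys, color="0.3", lw=1)
    for (cx, cy), lab in zip(_CORNERS, _LABELS):
        ax.annotate(lab, (cx, cy), textcoords="offset points",
                    xytext=(0, -12 if cy == 0 else 8), ha="center")
    if hue in coords:
        for name, chunk in coords.groupby(hue, sort=True):
            ax.scatter(chunk["x"], chunk["y"], s=22, alpha=0.8, label=str(name))
        ax.legend(frameon=False, fontsize=8, loc="upper left")
    else:
        ax.scatter(coords["x"], coords["y"], s=22, alpha=0.8)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
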