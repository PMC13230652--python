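"""Confidence-interval behaviour plots.

The signature figure of the method comparison: a 3×3 grid of 95% CI
bounds against test reliability, one row per approach (traditional,
regression, scale-corrected regression) and one column per observed
T-score (30, 50, 70).  It makes the regression approach's anomaly
visible — its interval is widest at reliability .50 and collapses to
zero width at reliability 0 — while the traditional and scale-corrected
intervals narrow monotonically as reliability grows.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import ctt
from .scales import NormScale, T_SCALE
from .coverage import _CI_FUNCS, APPROACHES

__all__ = ["ci_vs_reliability_figure"]

_TITLES = {
    "traditional": "Traditional",
    "regression": "Regression",
    "rets": "Regression + scale correction",
}


def ci_vs_reliability_figure(
    out_path,
    scale: NormScale = T_SCALE,
    observed_scores: Sequence[float] = (30.0, 50.0, 70.0),
    level: float = 0.95,
    n_grid: int = 199,
):
    """Render the 3×3 CI-vs-reliability panel grid and save it.

    Returns the matplotlib figure (also written to ``out_path``; the
    format follows the file extension).
    """
    rels = np.linspace(0.005, 1.0, n_grid)
    fig, axes = plt.subplots(
        3, len(observed_scores), figsize=(3.4 * len(observed_scores), 9),
        sharex=True, sharey=True,
    )
    panel = iter("ABCDEFGHI")
    for row, approach in enumerate(APPROACHES):
        for col, x in enumerate(observed_scores):
            ax = axes[row, col]
            lower = np.empty_like(rels)
            upper = np.empty_like(rels)
            center = np.empty_like(rels)
            for i, r in enumerate(rels):
                ci = _CI_FUNCS[approach](x, scale, r, level)
                lower[i], upper[i], center[i] = ci.lower, ci.upper, ci.center
            ax.fill_between(rels, lower, upper, alpha=0.25)
            ax.plot(rels, center, lw=1.5)
            ax.plot(rels, lower, lw=0.8)
            ax.plot(rels, upper, lw=0.8)
            ax.axhline(scale.mean, color="grey", lw=0.5, ls=":")
            ax.set_title(f"{next(panel)}: {_TITLES[approach]}, observed {scale.label or 'score'} = {x:g}",
                         fontsize=9)
            if row == 2:
                ax.set_xlabel("reliability $r_{xx}$")
            if col == 0:
                ax.set_ylabel(f"{int(level * 100)}% CI ({scale.label or 'norm'} scale)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return fig
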