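"""Bland–Altman plotting helpers (optional outputs of ``validate``)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .blandaltman import BAResult, ModeledBA


def bland_altman_plot(
    reference: np.ndarray,
    device: np.ndarray,
    result: BAResult | ModeledBA,
    title: str = "",
    path: str | Path | None = None,
):
    """Scatter of differences against the reference with bias/LOA lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = np.asarray(reference, dtype=float)
    diff = ref - np.asarray(device, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(ref, diff, s=6, alpha=0.4, color="#3b6aa0", edgecolors="none")
    grid = np.linspace(ref.min(), ref.max(), 100)
    if isinstance(result, ModeledBA):
        ax.plot(grid, result.bias_at(grid), "r-", lw=1.5, label="bias")
        lo, hi = result.loa_at(grid)
        ax.plot(grid, lo, "r--", lw=1, label="95% LOA")
        ax.plot(grid, hi, "r--", lw=1)
    else:
        ax.axhline(result.bias, color="r", lw=1.5, label="bias")
        ax.axhline(result.loa_lower, color="r", ls="--", lw=1, label="95% LOA")
        ax.axhline(result.loa_upper, color="r", ls="--", lw=1)
    ax.set_xlabel("reference")
    ax.set_ylabel("reference − device")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
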