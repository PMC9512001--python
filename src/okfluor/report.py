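"""Diagnostic exports: intermediate-signal CSVs and summary plots."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import MeasureResult

__all__ = ["profile_csv", "derivative_csv", "peaks_csv", "diagnostic_plot"]


def profile_csv(result: MeasureResult, path: str | Path) -> None:
    """Write the intensity profile as columns (x, value)."""
    values = np.asarray(result.profile.values)
    pd.DataFrame({"x": np.arange(len(values)), "value": values}).to_csv(path, index=False)


def derivative_csv(result: MeasureResult, path: str | Path) -> None:
    """Write the absolute derivative as columns (x, value)."""
    values = np.asarray(result.derivative.values)
    pd.DataFrame({"x": np.arange(len(values)), "value": values}).to_csv(path, index=False)


def peaks_csv(result: MeasureResult, path: str | Path) -> None:
    """Write detected peaks as columns (x, value)."""
    pd.DataFrame(
        {"x": result.peaks.positions, "value": result.peaks.magnitudes}
    ).to_csv(path, index=False)


def diagnostic_plot(result: MeasureResult, path: str | Path) -> None:
    """Two-panel figure: intensity profile, and |derivative| with peaks.

    The selected zone-boundary edges are marked on both panels; unselected
    candidate peaks appear as open circles on the derivative panel.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    ax1.plot(result.profile.values, color="tab:green", lw=1)
    ax1.set_ylabel("intensity ratio")
    ax1.set_title(f"{result.image_id}: horizontal-meridian intensity profile")
    ax2.plot(result.derivative.values, color="tab:blue", lw=1)
    ax2.scatter(
        result.peaks.positions,
        result.peaks.magnitudes,
        facecolors="none",
        edgecolors="tab:orange",
        label="candidate peaks",
    )
    selected = result.edge_set.x
    for x in selected:
        ax1.axvline(x, color="grey", ls=":", lw=0.8)
        ax2.axvline(x, color="grey", ls=":", lw=0.8)
    ax2.set_xlabel("horizontal image pixels")
    ax2.set_ylabel("|dI/dx|")
    ax2.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
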