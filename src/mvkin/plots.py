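"""Overlay plots of paired traces (test system red, reference black)."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless-safe; plots are always written to files
import matplotlib.pyplot as plt

from .alignment import AlignedTracePair

__all__ = ["overlay_plot"]


def overlay_plot(pair: AlignedTracePair, path: str | Path, title: str | None = None) -> None:
    """Write a two-curve overlay of an aligned pair on the 0-99 grid."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    frames = range(pair.n_frames)
    ax.plot(frames, pair.reference, color="black", lw=1.5, label="reference")
    ax.plot(frames, pair.test, color="red", lw=1.5, label="markerless")
    ax.set_xlabel("normalized frame")
    ax.set_ylabel("angle (deg)")
    if title is None:
        prov = pair.provenance
        bits = [str(prov[k]) for k in ("task", "participant", "side") if k in prov]
        title = " / ".join(bits) if bits else "aligned pair"
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
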