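"""Volcano-plot coordinates and rendering for a screen's results.

Each screened event becomes a point at (ln ROR, -log10 Fisher p); points in
the region ln ROR > 0 and -log10 p > 1.3 (p < 10^-1.3 ~ 0.05) stand out as
disproportionality candidates.  Point color encodes log10 of the report
count.  The axis assignment (x = ln ROR, y = -log10 p) follows the usual
volcano convention.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .disproportionality import SignalResult
from .errors import ConfigurationError

__all__ = ["VolcanoPoint", "volcano_table", "volcano_frame", "render_volcano",
           "LN_ROR_THRESHOLD", "NEG_LOG10_P_THRESHOLD"]

LN_ROR_THRESHOLD = 0.0
NEG_LOG10_P_THRESHOLD = 1.3


@dataclass(frozen=True)
class VolcanoPoint:
    pt_term: str
    ln_ror: float
    neg_log10_p: float
    n_cases: int
    above_threshold: bool
    p_clamped: bool = False


def volcano_table(results: list[SignalResult]) -> list[VolcanoPoint]:
    """Map screen results to volcano coordinates.

    A p-value of exactly 0 (impossible for a true Fisher p, but tolerated
    from external inputs) is clamped to the smallest positive float and the
    point flagged.
    """
    points = []
    for r in results:
        if r.ror <= 0:
            raise ConfigurationError(f"ROR must be positive, got {r.ror} for {r.pt_term!r}")
        p, clamped = r.p_value, False
        if p <= 0:
            p, clamped = sys.float_info.min, True
        ln_ror = float(np.log(r.ror))
        nlp = float(-np.log10(p))
        points.append(VolcanoPoint(
            pt_term=r.pt_term, ln_ror=ln_ror, neg_log10_p=nlp, n_cases=r.n_cases,
            above_threshold=(ln_ror > LN_ROR_THRESHOLD and nlp > NEG_LOG10_P_THRESHOLD),
            p_clamped=clamped))
    return points


def volcano_frame(points: list[VolcanoPoint]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pt_term": p.pt_term, "ln_ror": p.ln_ror, "neg_log10_p": p.neg_log10_p,
        "n_cases": p.n_cases, "above_threshold": p.above_threshold,
    } for p in points])


def render_volcano(points: list[VolcanoPoint], path, *, title: str = "",
                   n_labels: int = 8) -> None:
    """Write the volcano figure (PNG or SVG by extension).

    Dashed threshold lines at x = 0 and y = 1.3; color maps log10(report
    count) through a red–green–blue scale (most-reported events red); the
    ``n_labels`` points with the largest |ln ROR| are labeled.  Output is
    deterministic for a fixed input (fixed SVG hash salt, no embedded
    timestamps).
    """
    if not points:
        raise ConfigurationError("cannot render a volcano plot with no points")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "pvsignalkit"
    x = np.array([p.ln_ror for p in points])
    y = np.array([p.neg_log10_p for p in points])
    n = np.array([max(p.n_cases, 1) for p in points], dtype=float)

    fig, ax = plt.subplots(figsize=(6.0, 5.0))
    sc = ax.scatter(x, y, c=np.log10(n), cmap="jet", s=28, edgecolors="none", zorder=3)
    ax.axvline(LN_ROR_THRESHOLD, linestyle="--", color="gray", linewidth=1)
    ax.axhline(NEG_LOG10_P_THRESHOLD, linestyle="--", color="gray", linewidth=1)
    for p in sorted(points, key=lambda q: -abs(q.ln_ror))[:n_labels]:
        ax.annotate(p.pt_term, (p.ln_ror, p.neg_log10_p), fontsize=6,
                    textcoords="offset points", xytext=(3, 3))
    ax.set_xlabel("ln(ROR)")
    ax.set_ylabel(r"$-\log_{10}$($P$-value)")
    if title:
        ax.set_title(title)
    fig.colorbar(sc, ax=ax, label=r"$\log_{10}$(reports)")
    fig.tight_layout()
    try:
        fig.savefig(path, dpi=150, metadata=_deterministic_metadata(str(path)))
    finally:
        plt.close(fig)


def _deterministic_metadata(path: str) -> dict | None:
    if path.endswith(".svg"):
        return {"Date": None}
    if path.endswith(".png"):
        return {"Software": "pvsignalkit"}
    return None
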