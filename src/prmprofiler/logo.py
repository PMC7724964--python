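"""Sequence-logo rendering for specificity profiles.

Letters are drawn as scaled font glyphs: within a column each letter's height
is proportional to its weight W_ij and the total column height equals the
position's specificity potential SP_j, so a fully conserved position reaches
height 1 and an indifferent position vanishes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
from matplotlib.font_manager import FontProperties
from matplotlib.patches import PathPatch
from matplotlib.textpath import TextPath
from matplotlib.transforms import Affine2D

#: Chemistry-based letter colors (hydrophobic black, polar green, acidic red,
#: basic blue, aromatic purple tint for W/Y/F handled as hydrophobic).
LETTER_COLORS = {
    **{a: "black" for a in "AVLIMFW"},
    **{a: "forestgreen" for a in "STNQYC"},
    **{a: "firebrick" for a in "DE"},
    **{a: "royalblue" for a in "KRH"},
    "G": "darkorange",
    "P": "darkorange",
}

_FONT = FontProperties(family="DejaVu Sans", weight="bold")
_MIN_HEIGHT = 1e-3  # letters thinner than this are invisible anyway


def render_logo(profile, path: str | Path | None = None, ax=None, dpi: int = 150):
    """Draw the profile as a sequence logo; write to *path* if given.

    Returns the matplotlib Axes. An empty (fully trimmed) profile yields a
    blank placeholder annotated as having no significant positions.
    """
    created = False
    if ax is None:
        fig, ax = plt.subplots(figsize=(max(2.0, 0.45 * max(profile.n_positions, 1)), 2.2))
        created = True
    if profile.is_empty:
        ax.text(0.5, 0.5, "no significant profile", ha="center", va="center",
                transform=ax.transAxes, color="gray")
        ax.set_xticks([])
    else:
        for j in range(profile.n_positions):
            order = np.argsort(profile.w[:, j])  # ascending: largest letter ends on top
            y = 0.0
            for i in order:
                h = float(profile.w[i, j])
                if h < _MIN_HEIGHT:
                    continue
                _draw_letter(ax, profile.alphabet[i], x=j, y=y, height=h)
                y += h
        ax.set_xlim(-0.6, profile.n_positions - 0.4)
        ax.set_xticks(range(profile.n_positions))
        ax.set_xticklabels([str(j + 1) for j in range(profile.n_positions)])
    ax.set_ylim(0, 1.02)
    ax.set_ylabel("SP")
    ax.set_title(profile.prm_id)
    ax.spines[["top", "right"]].set_visible(False)
    if path is not None:
        ax.figure.savefig(path, dpi=dpi, bbox_inches="tight")
    if created:
        plt.close(ax.figure)
    return ax


def _draw_letter(ax, letter: str, x: float, y: float, height: float, width: float = 0.9):
    tp = TextPath((0, 0), letter, size=1.0, prop=_FONT)
    bbox = tp.get_extents()
    if bbox.width == 0 or bbox.height == 0:
        return
    transform = (
        Affine2D()
        .translate(-bbox.x0, -bbox.y0)
        .scale(width / bbox.width, height / bbox.height)
        .translate(x - width / 2, y)
    )
    patch = PathPatch(
        transform.transform_path(tp),
        facecolor=LETTER_COLORS.get(letter, "gray"),
        edgecolor="none",
    )
    ax.add_patch(patch)
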