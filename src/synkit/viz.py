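"""Per-participant diagnostic plots.

One row per grapheme: the inducer symbol rendered once per trial in the
trial's response color (missing trials as a hatched open marker) on a
mid-gray background — so both near-white and near-black responses stay
visible — alongside a horizontal bar showing the grapheme-level
consistency score. When a cutoff is configured (or a published default
applies) it is drawn as a dashed reference line on the score axis.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
# deterministic element ids so identical inputs give identical SVG output
matplotlib.rcParams["svg.hashsalt"] = "synkit"

import matplotlib.pyplot as plt

from .errors import DataFormatError
from .model_io import Participant
from .scoring import ScoringConfig, grapheme_score

__all__ = ["plot_participant"]

_BACKGROUND = "#808080"


def plot_participant(
    p: Participant,
    cfg: ScoringConfig = ScoringConfig(),
    out_path: str | Path = "participant.png",
) -> Path:
    """Render the diagnostic panel to PNG or SVG (chosen by extension)."""
    if not p.graphemes:
        raise DataFormatError(f"participant {p.id!r} has no graphemes to plot")

    graphemes = p.graphemes
    scores = [grapheme_score(g, cfg) for g in graphemes]
    n = len(graphemes)
    n_trials = max(len(g.responses) for g in graphemes)

    fig, (ax_sym, ax_bar) = plt.subplots(
        1,
        2,
        sharey=True,
        figsize=(7.5, 0.45 * n + 1.6),
        gridspec_kw={"width_ratios": [1.0, 2.0]},
    )
    fig.suptitle(f"participant {p.id}")

    ax_sym.set_facecolor(_BACKGROUND)
    for i, g in enumerate(graphemes):
        for j, response in enumerate(g.responses):
            if response is None:
                ax_sym.scatter(
                    j, i, marker="s", s=110, facecolors="none",
                    edgecolors="0.25", hatch="////",
                )
            else:
                ax_sym.text(
                    j, i, g.symbol, color=response.coords,
                    ha="center", va="center", fontsize=12, fontweight="bold",
                )
    ax_sym.set_xlim(-0.6, n_trials - 0.4)
    ax_sym.set_ylim(-0.6, n - 0.4)
    ax_sym.set_yticks(range(n), [g.symbol for g in graphemes])
    ax_sym.set_xticks(range(n_trials), [f"trial {j + 1}" for j in range(n_trials)])
    ax_sym.invert_yaxis()

    positions = [i for i, s in enumerate(scores) if s is not None]
    ax_bar.barh(positions, [scores[i] for i in positions], color="0.35", height=0.6)
    cutoff = cfg.resolved_cutoff()
    if cutoff is not None:
        ax_bar.axvline(cutoff, linestyle="--", color="firebrick", linewidth=1)
    ax_bar.set_xlabel(f"consistency score ({cfg.color_space}, {cfg.metric})")
    ax_bar.set_xlim(left=0)

    fig.tight_layout()
    out_path = Path(out_path)
    if out_path.suffix.lower() == ".svg":
        fig.savefig(out_path, metadata={"Date": None})
    else:
        fig.savefig(out_path)
    plt.close(fig)
    return out_path
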