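"""Consistency scoring, mean colors, and cutoff classification.

The consistency score of a grapheme is the sum of pairwise color distances
over its trial responses, computed in the configured working space with the
configured metric (for 3 trials: d12 + d13 + d23). A participant's score is
the arithmetic mean of their grapheme scores. Lower scores mean more
consistent responses; scores strictly below a cutoff are conventionally
taken to indicate synesthesia.

Two (space, metric) pairs have published cutoffs calibrated on three-trial
tests, and these are the module defaults when no explicit cutoff is given:

* CIELUV + Euclidean: 135,
* unit-normalized sRGB + taxicab: 1.0.

Because the per-grapheme score is a sum over trial pairs, it grows with the
number of pairs; with a trial count other than three the published cutoffs
do not apply and no re-normalization is attempted. Scores for graphemes
with exactly 2 usable responses (reachable with ``complete_only=False``)
are likewise left on the raw single-pair scale.

MISSING values (unscorable graphemes/participants) are returned as ``None``
and appear as empty cells in score tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .colorspace import METRICS, SPACES, ColorPoint, srgb_to
from .errors import ConfigError
from .model_io import Grapheme, Participant, ParticipantGroup

__all__ = [
    "DEFAULT_CUTOFFS",
    "ScoringConfig",
    "grapheme_score",
    "participant_score",
    "group_scores",
    "mean_color",
    "classify_synesthetic",
]

#: Published synesthesia cutoffs, applicable to three-trial tests only.
DEFAULT_CUTOFFS: dict[tuple[str, str], float] = {
    ("Luv", "euclidean"): 135.0,
    ("sRGB", "taxicab"): 1.0,
}

_PDIST_METRIC = {"euclidean": "euclidean", "taxicab": "cityblock"}


@dataclass(frozen=True)
class ScoringConfig:
    """How scores are computed and, optionally, classified.

    ``complete_only=True`` (the default) excludes graphemes with any
    MISSING response: only fully answered inducers are interpretable.
    """

    metric: str = "euclidean"
    color_space: str = "Luv"
    symbol_filter: Optional[frozenset[str]] = None
    complete_only: bool = True
    cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ConfigError(f"unknown metric {self.metric!r}; expected {METRICS}")
        if self.color_space not in SPACES:
            raise ConfigError(
                f"unknown color space {self.color_space!r}; expected {SPACES}"
            )
        if self.cutoff is not None and self.cutoff <= 0:
            raise ConfigError("cutoff must be > 0")
        if self.symbol_filter is not None:
            object.__setattr__(self, "symbol_filter", frozenset(self.symbol_filter))

    def resolved_cutoff(self) -> Optional[float]:
        """Explicit cutoff, else the published default for (space, metric)."""
        if self.cutoff is not None:
            return self.cutoff
        return DEFAULT_CUTOFFS.get((self.color_space, self.metric))


def grapheme_score(g: Grapheme, cfg: ScoringConfig = ScoringConfig()) -> Optional[float]:
    """Sum of pairwise distances over a grapheme's usable responses.

    Returns ``None`` if the grapheme is excluded by ``complete_only`` or
    has fewer than two usable responses.
    """
    present = [r for r in g.responses if r is not None]
    if cfg.complete_only and len(present) != len(g.responses):
        return None
    if len(present) < 2:
        return None
    arr = np.array([r.to_array() for r in present])
    points = srgb_to(arr, cfg.color_space)
    return float(pdist(points, metric=_PDIST_METRIC[cfg.metric]).sum())


def participant_score(
    p: Participant, cfg: ScoringConfig = ScoringConfig()
) -> Optional[float]:
    """Mean of the participant's non-missing grapheme scores, or ``None``."""
    scores = [
        s
        for g in p.filtered_graphemes(cfg.symbol_filter)
        if (s := grapheme_score(g, cfg)) is not None
    ]
    if not scores:
        return None
    return float(np.mean(scores))


def _scored_grapheme_count(p: Participant, cfg: ScoringConfig) -> int:
    return sum(
        1
        for g in p.filtered_graphemes(cfg.symbol_filter)
        if grapheme_score(g, cfg) is not None
    )


def group_scores(
    grp: ParticipantGroup, cfg: ScoringConfig = ScoringConfig()
) -> pd.DataFrame:
    """Per-participant score table, in group order.

    Columns: ``participant_id``, ``score``, ``n_graphemes_used`` and — when
    a cutoff is explicit or a published default exists — ``synesthetic``.
    """
    cutoff = cfg.resolved_cutoff()
    rows = []
    for p in grp.participants:
        score = participant_score(p, cfg)
        row = {
            "participant_id": p.id,
            "score": np.nan if score is None else score,
            "n_graphemes_used": _scored_grapheme_count(p, cfg),
        }
        if cutoff is not None:
            verdict = classify_synesthetic(score, cutoff)
            row["synesthetic"] = pd.NA if verdict is None else verdict
        rows.append(row)
    columns = ["participant_id", "score", "n_graphemes_used"]
    if cutoff is not None:
        columns.append("synesthetic")
    return pd.DataFrame(rows, columns=columns)


def mean_color(
    p: Participant, space: str = "Luv", symbol_filter: Optional[Iterable[str]] = None
) -> Optional[ColorPoint]:
    """Per-axis mean of all non-missing responses, in ``space``."""
    arrays = [
        g.response_array() for g in p.filtered_graphemes(symbol_filter)
    ]
    stacked = np.concatenate(arrays, axis=0) if arrays else np.empty((0, 3))
    if stacked.shape[0] == 0:
        return None
    converted = srgb_to(stacked, space)
    return ColorPoint(tuple(converted.mean(axis=0)), space)


def classify_synesthetic(score: Optional[float], cutoff: float) -> Optional[bool]:
    """Strictly-below-cutoff rule: 134.9 vs 135 → True, 135 vs 135 → False."""
    if score is None:
        return None
    return bool(score < cutoff)
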