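"""Seeded generation of synthetic consistency-test respondents.

Real consistency-test datasets contain a mixture of response styles, four
of which matter for exercising scoring and validity classification:

* ``synesthete``     — each inducer has a stable associated color drawn
  from a personal palette of well-separated colors; trial-to-trial
  variation is small Gaussian jitter. Mimics genuine synesthetic data.
* ``random``         — every response uniform on the sRGB cube; mimics a
  non-synesthete guessing freely.
* ``single_color``   — one base color (plus jitter) for every trial;
  mimics participants who click the same swatch throughout, whose scores
  look "consistent" but are uninterpretable.
* ``light_varying``  — hue varies freely but lightness is high and
  saturation low (drawn in HSL, converted to sRGB). These responses are
  hue-inconsistent yet numerically consistent in CIELUV/RGB space because
  light colors crowd together near white — the known scoring artifact.
* ``few_colors``     — every response drawn from a small palette; the
  in-between case for dominant-color criteria.

All randomness flows from ``numpy.random.default_rng`` seeded per
participant, so the same parameters and seed reproduce identical data. HSL
is only a generation device; analysis always happens in the four supported
spaces.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .colorspace import ColorPoint
from .errors import ConfigError, GenerationError
from .model_io import Grapheme, Participant, ParticipantGroup

__all__ = ["ARCHETYPES", "ArchetypeParams", "gen_participant", "gen_group"]

ARCHETYPES = ("synesthete", "random", "single_color", "light_varying", "few_colors")

_SYMBOLS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"

#: Minimum pairwise sRGB Euclidean separation of palette colors.
_PALETTE_MIN_SEP = 0.5


@dataclass(frozen=True)
class ArchetypeParams:
    """Generator settings for one respondent archetype.

    Defaults emulate a 16-inducer, three-trials-per-inducer test. The
    jitter standard deviation (0.02 in sRGB units per channel) reflects
    the small trial-to-trial wobble of color-picker use; ``palette_size``
    only matters for the palette-based archetypes.
    """

    archetype: str
    n_symbols: int = 16
    trials_per_symbol: int = 3
    palette_size: int = 8
    jitter_sd: float = 0.02
    lightness_range: tuple[float, float] = (0.85, 0.97)
    saturation_range: tuple[float, float] = (0.0, 0.4)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ConfigError(
                f"unknown archetype {self.archetype!r}; expected one of {ARCHETYPES}"
            )
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.n_symbols < 1 or self.n_symbols > len(_SYMBOLS):
            raise ConfigError(f"n_symbols must be in [1, {len(_SYMBOLS)}]")
        if self.palette_size < 1:
            raise ConfigError("palette_size must be >= 1")


def _draw_palette(
    rng: np.random.Generator, size: int, min_sep: float = _PALETTE_MIN_SEP,
    max_tries: int = 2000,
) -> np.ndarray:
    """Rejection-sample ``size`` colors pairwise >= ``min_sep`` apart."""
    colors: list[np.ndarray] = []
    for _ in range(size):
        for _ in range(max_tries):
            candidate = rng.random(3)
            if all(np.linalg.norm(candidate - c) >= min_sep for c in colors):
                colors.append(candidate)
                break
        else:
            raise GenerationError(
                f"could not place {size} palette colors with pairwise "
                f"sRGB separation >= {min_sep}"
            )
    return np.array(colors)


def _jitter(rng: np.random.Generator, base: np.ndarray, sd: float) -> np.ndarray:
    return np.clip(base + rng.normal(0.0, sd, size=3), 0.0, 1.0)


def _base_colors(params: ArchetypeParams, rng: np.random.Generator) -> np.ndarray:
    """The (n_symbols, trials, 3) sRGB response block, before missingness."""
    n, t = params.n_symbols, params.trials_per_symbol
    kind = params.archetype

    if kind == "synesthete":
        # Cyclic palette assignment guarantees each palette color backs
        # ceil(n / palette_size) inducers, i.e. several nearby points.
        palette = _draw_palette(rng, min(params.palette_size, n))
        return np.array(
            [
                [_jitter(rng, palette[i % len(palette)], params.jitter_sd) for _ in range(t)]
                for i in range(n)
            ]
        )
    if kind == "random":
        return rng.random((n, t, 3))
    if kind == "single_color":
        base = rng.random(3)
        return np.array(
            [[_jitter(rng, base, params.jitter_sd) for _ in range(t)] for _ in range(n)]
        )
    if kind == "light_varying":
        lo_l, hi_l = params.lightness_range
        lo_s, hi_s = params.saturation_range
        block = np.empty((n, t, 3))
        for i in range(n):
            for j in range(t):
                h = rng.uniform(0.0, 1.0)
                l = rng.uniform(lo_l, hi_l)
                s = rng.uniform(lo_s, hi_s)
                block[i, j] = colorsys.hls_to_rgb(h, l, s)
        return block
    # few_colors: every trial draws from a small separated palette.
    palette = _draw_palette(rng, params.palette_size)
    return np.array(
        [
            [
                _jitter(rng, palette[rng.integers(len(palette))], params.jitter_sd)
                for _ in range(t)
            ]
            for _ in range(n)
        ]
    )


def gen_participant(
    params: ArchetypeParams, participant_id: Optional[str] = None
) -> Participant:
    """Generate one synthetic participant (deterministic in ``params.seed``)."""
    rng = np.random.default_rng(params.seed)
    block = _base_colors(params, rng)
    missing = rng.random((params.n_symbols, params.trials_per_symbol)) < params.missing_rate

    graphemes = tuple(
        Grapheme(
            _SYMBOLS[i],
            tuple(
                None if missing[i, j] else ColorPoint(tuple(block[i, j]), "sRGB")
                for j in range(params.trials_per_symbol)
            ),
        )
        for i in range(params.n_symbols)
    )
    pid = participant_id or f"{params.archetype}_{params.seed}"
    return Participant(pid, graphemes)


def gen_group(
    mixture: Sequence[tuple[ArchetypeParams, int]],
    seed: int = 0,
    color_space: str = "Luv",
) -> tuple[ParticipantGroup, pd.DataFrame]:
    """Generate a mixed group plus its ground-truth archetype table.

    Participant sub-seeds are ``seed + index`` (index running over the
    whole mixture), so groups are reproducible and individual participants
    can be regenerated in isolation.
    """
    participants = []
    truth_rows = []
    index = 0
    for params, count in mixture:
        for _ in range(count):
            sub = replace(params, seed=seed + index)
            pid = f"p{index:04d}_{params.archetype}"
            participants.append(gen_participant(sub, pid))
            truth_rows.append({"participant_id": pid, "archetype": params.archetype})
            index += 1
    truth = pd.DataFrame(truth_rows, columns=["participant_id", "archetype"])
    return ParticipantGroup(tuple(participants), color_space), truth
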