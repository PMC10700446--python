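"""Data model and tidy-CSV ingestion for consistency-test trial data.

The expected input is a tidy long-format table: one row per trial, with a
participant ID column, an inducer symbol column and a response color column
holding ``#RRGGBB`` hex strings. "No color" responses and otherwise absent
trials are both treated as MISSING (represented as ``None``), which is
distinct from every color including pure black.

The in-memory model mirrors how consistency tests are structured:

``ParticipantGroup`` → ``Participant`` → ``Grapheme`` → responses.

A grapheme holds exactly ``trials_per_symbol`` response slots, in encounter
order (or ordered by an optional trial-index column); symbols with fewer
rows than expected are padded with MISSING, since aborted tests are common
and completeness is the validation module's concern. More rows than
expected is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .colorspace import SPACES, ColorPoint, parse_hex, to_hex
from .errors import ConfigError, DataFormatError

__all__ = [
    "GroupConfig",
    "Grapheme",
    "Participant",
    "ParticipantGroup",
    "build_group",
    "read_group_csv",
    "group_to_frame",
    "recode_to_missing",
    "complete_symbol_count",
    "write_scores_csv",
    "write_validation_csv",
]

#: Cell values (after stripping) interpreted as a missing response.
DEFAULT_NA_MARKERS = ("", "NA", "nocolor")


@dataclass(frozen=True)
class GroupConfig:
    """Column names and layout of the tidy input table."""

    id_column: str = "participant_id"
    symbol_column: str = "symbol"
    color_column: str = "color"
    trials_per_symbol: int = 3
    color_space: str = "Luv"
    trial_index_column: Optional[str] = None
    na_markers: tuple[str, ...] = DEFAULT_NA_MARKERS

    def __post_init__(self) -> None:
        if self.trials_per_symbol < 1:
            raise ConfigError("trials_per_symbol must be >= 1")
        if self.color_space not in SPACES:
            raise ConfigError(
                f"unknown color space {self.color_space!r}; expected one of {SPACES}"
            )


@dataclass(frozen=True)
class Grapheme:
    """One inducer symbol and its ordered trial responses (None = MISSING)."""

    symbol: str
    responses: tuple[Optional[ColorPoint], ...]

    @property
    def is_complete(self) -> bool:
        return all(r is not None for r in self.responses)

    def response_array(self) -> np.ndarray:
        """Non-missing responses as an (n, 3) sRGB array."""
        present = [r.to_array() for r in self.responses if r is not None]
        return np.array(present, dtype=float).reshape(-1, 3)


@dataclass(frozen=True)
class Participant:
    id: str
    graphemes: tuple[Grapheme, ...]

    def __post_init__(self) -> None:
        symbols = [g.symbol for g in self.graphemes]
        if len(symbols) != len(set(symbols)):
            raise DataFormatError(
                f"participant {self.id!r} has duplicate grapheme symbols"
            )

    def filtered_graphemes(
        self, symbol_filter: Optional[Iterable[str]] = None
    ) -> tuple[Grapheme, ...]:
        if symbol_filter is None:
            return self.graphemes
        wanted = set(symbol_filter)
        return tuple(g for g in self.graphemes if g.symbol in wanted)


@dataclass(frozen=True)
class ParticipantGroup:
    """All participants of a study plus the working color space."""

    participants: tuple[Participant, ...]
    color_space: str = "Luv"

    def __post_init__(self) -> None:
        ids = [p.id for p in self.participants]
        if len(ids) != len(set(ids)):
            raise DataFormatError("participant ids are not unique")
        if self.color_space not in SPACES:
            raise ConfigError(
                f"unknown color space {self.color_space!r}; expected one of {SPACES}"
            )

    def __len__(self) -> int:
        return len(self.participants)

    def get(self, participant_id: str) -> Participant:
        for p in self.participants:
            if p.id == participant_id:
                return p
        raise KeyError(f"no participant with id {participant_id!r}")


def _parse_cell(cell, na_markers: Sequence[str]) -> Optional[ColorPoint]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    text = str(cell).strip()
    if text in na_markers:
        return None
    return parse_hex(text)


def build_group(records: pd.DataFrame, config: GroupConfig = GroupConfig()) -> ParticipantGroup:
    """Assemble a :class:`ParticipantGroup` from a tidy trial table.

    Rows are grouped per participant by symbol in encounter order. Trial
    order within a symbol is file order unless ``config.trial_index_column``
    names a column, in which case rows are stably sorted by it.
    """
    needed = [config.id_column, config.symbol_column, config.color_column]
    if config.trial_index_column is not None:
        needed.append(config.trial_index_column)
    for col in needed:
        if col not in records.columns:
            raise ConfigError(f"input table has no column named {col!r}")

    ids = records[config.id_column].tolist()
    symbols = records[config.symbol_column].tolist()
    colors = records[config.color_column].tolist()
    order_keys = (
        records[config.trial_index_column].tolist()
        if config.trial_index_column is not None
        else range(len(records))
    )

    # participant -> symbol -> list of (order key, response)
    per_participant: dict[str, dict[str, list]] = {}
    for pid, sym, cell, key in zip(ids, symbols, colors, order_keys):
        response = _parse_cell(cell, config.na_markers)
        per_participant.setdefault(str(pid), {}).setdefault(str(sym), []).append(
            (key, response)
        )

    participants = []
    for pid, by_symbol in per_participant.items():
        graphemes = []
        for sym, entries in by_symbol.items():
            if len(entries) > config.trials_per_symbol:
                raise DataFormatError(
                    f"participant {pid!r}, symbol {sym!r}: {len(entries)} rows "
                    f"exceed trials_per_symbol={config.trials_per_symbol}"
                )
            entries = sorted(entries, key=lambda e: e[0])
            responses = [resp for _, resp in entries]
            responses += [None] * (config.trials_per_symbol - len(responses))
            graphemes.append(Grapheme(sym, tuple(responses)))
        participants.append(Participant(pid, tuple(graphemes)))
    return ParticipantGroup(tuple(participants), config.color_space)


def read_group_csv(path: str | Path, config: GroupConfig = GroupConfig()) -> ParticipantGroup:
    """Read a tidy UTF-8 CSV (header row required) into a group.

    All cells are read as text so that NA handling is governed solely by
    ``config.na_markers``.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    return build_group(frame, config)


def group_to_frame(
    group: ParticipantGroup, config: GroupConfig = GroupConfig()
) -> pd.DataFrame:
    """Flatten a group back to the tidy layout (colors re-quantized to hex).

    MISSING responses become empty cells. Colors are written as 8-bit hex,
    so coordinates that did not originate from hex strings are rounded to
    the nearest 8-bit channel value.
    """
    rows = []
    for p in group.participants:
        for g in p.graphemes:
            for r in g.responses:
                rows.append(
                    {
                        config.id_column: p.id,
                        config.symbol_column: g.symbol,
                        config.color_column: "" if r is None else to_hex(r),
                    }
                )
    return pd.DataFrame(
        rows, columns=[config.id_column, config.symbol_column, config.color_column]
    )


def recode_to_missing(
    group: ParticipantGroup, hex_set: Iterable[str]
) -> ParticipantGroup:
    """Return a copy with every response matching a listed color set MISSING.

    Typical use is recoding pure black (``"#000000"``) before scoring when
    inducers were displayed in black. Matching is exact on the sRGB triple.
    """
    targets = {parse_hex(h).coords for h in hex_set}
    if not targets:
        return group

    def _recode(r: Optional[ColorPoint]) -> Optional[ColorPoint]:
        if r is not None and r.coords in targets:
            return None
        return r

    participants = tuple(
        replace(
            p,
            graphemes=tuple(
                replace(g, responses=tuple(_recode(r) for r in g.responses))
                for g in p.graphemes
            ),
        )
        for p in group.participants
    )
    return replace(group, participants=participants)


def complete_symbol_count(
    p: Participant, symbol_filter: Optional[Iterable[str]] = None
) -> int:
    """Number of graphemes (optionally restricted) with no MISSING response."""
    return sum(1 for g in p.filtered_graphemes(symbol_filter) if g.is_complete)


def write_scores_csv(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, index=False)


def write_validation_csv(validation: pd.DataFrame, path: str | Path) -> None:
    validation.to_csv(path, index=False)
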