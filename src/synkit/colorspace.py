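"""Hex-color parsing, color-space conversion and color distances.

Consistency-test responses arrive as 8-bit sRGB hex strings. Scoring and
validation, however, are done in a user-selected working space; this module
supports the four spaces commonly used for that purpose:

* ``sRGB`` — nonlinear sRGB with channels in [0, 1],
* ``XYZ``  — CIE XYZ under the D65 illuminant, scaled so that the sRGB
  white point has Y = 100,
* ``Lab``  — CIELAB relative to D65,
* ``Luv``  — CIELUV relative to D65 (the space for which the widely used
  consistency-score cutoff of 135 was calibrated).

Conversions follow the IEC 61966-2-1 sRGB transfer function and the CIE
formulas. The reference white is taken as the image of sRGB (1, 1, 1) under
the sRGB→XYZ matrix, so that pure white maps exactly onto L* = 100 with
zero chroma and the gray axis is chroma-free to machine precision. For
zero luminance (X = Y = Z = 0) the CIELUV chromaticities u', v' are
undefined; u* and v* are defined as 0 there so pure-black responses remain
representable.

Array helpers (``srgb_to`` etc.) operate on ``(..., 3)`` float arrays and
are what the scoring and validation code uses internally; :class:`ColorPoint`
is the scalar, user-facing wrapper.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import ColorRangeError, HexColorError, SpaceMismatchError

__all__ = [
    "SPACES",
    "METRICS",
    "ColorPoint",
    "parse_hex",
    "to_hex",
    "convert_color",
    "color_distance",
    "srgb_to",
    "srgb_to_xyz",
    "xyz_to_srgb",
    "xyz_to_lab",
    "xyz_to_luv",
]

SPACES = ("sRGB", "XYZ", "Lab", "Luv")
METRICS = ("euclidean", "taxicab")

# Linear sRGB -> XYZ under D65, rows scaled to the conventional Y of the
# primaries; multiplied by 100 on use so white lands at Y = 100.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_XYZ_TO_SRGB = np.linalg.inv(_SRGB_TO_XYZ)

#: XYZ of the sRGB white point on the Y = 100 scale (~[95.047, 100, 108.883]).
WHITE_XYZ = _SRGB_TO_XYZ.sum(axis=1) * 100.0

# CIE constants in their exact rational form.
_EPSILON = 216.0 / 24389.0
_KAPPA = 24389.0 / 27.0

_HEX_RE = re.compile(r"#?([0-9a-fA-F]{6})")


@dataclass(frozen=True)
class ColorPoint:
    """A single color as a 3-vector in one of the supported spaces."""

    coords: tuple[float, float, float]
    space: str = "sRGB"

    def __post_init__(self) -> None:
        if self.space not in SPACES:
            raise SpaceMismatchError(
                f"unknown color space {self.space!r}; expected one of {SPACES}"
            )
        coords = tuple(float(c) for c in self.coords)
        if len(coords) != 3:
            raise ValueError(f"a color needs exactly 3 coordinates, got {len(coords)}")
        object.__setattr__(self, "coords", coords)

    def to_array(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


def parse_hex(text: str) -> ColorPoint:
    """Parse ``"#RRGGBB"`` (case-insensitive, "#" optional) into sRGB [0,1]³.

    8-digit (alpha) hex and any other malformed input raise
    :class:`~synkit.errors.HexColorError`.
    """
    if not isinstance(text, str):
        raise HexColorError(f"not a hex color string: {text!r}")
    m = _HEX_RE.fullmatch(text.strip())
    if m is None:
        raise HexColorError(f"not a '#RRGGBB' hex color: {text!r}")
    digits = m.group(1)
    channels = tuple(int(digits[i : i + 2], 16) / 255.0 for i in (0, 2, 4))
    return ColorPoint(channels, "sRGB")


def to_hex(point: ColorPoint) -> str:
    """Quantize an sRGB color back to ``"#RRGGBB"`` (8 bits per channel)."""
    if point.space != "sRGB":
        raise SpaceMismatchError(f"can only hex-encode sRGB colors, got {point.space}")
    return "#" + "".join(
        f"{int(round(c * 255)):02X}" for c in np.clip(point.coords, 0.0, 1.0)
    )


# ---------------------------------------------------------------------------
# array conversions
# ---------------------------------------------------------------------------


def srgb_to_xyz(arr: np.ndarray) -> np.ndarray:
    """Nonlinear sRGB in [0,1]³ to XYZ with white Y = 100."""
    arr = np.asarray(arr, dtype=float)
    linear = np.where(
        arr <= 0.04045, arr / 12.92, ((arr + 0.055) / 1.055) ** 2.4
    )
    return linear @ _SRGB_TO_XYZ.T * 100.0


def xyz_to_srgb(arr: np.ndarray) -> np.ndarray:
    """Inverse of :func:`srgb_to_xyz` (result clipped only by the caller)."""
    linear = np.asarray(arr, dtype=float) / 100.0 @ _XYZ_TO_SRGB.T
    return np.where(
        linear <= 0.04045 / 12.92,
        linear * 12.92,
        1.055 * np.clip(linear, 0.0, None) ** (1.0 / 2.4) - 0.055,
    )


def _lab_f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _EPSILON, np.cbrt(t), (_KAPPA * t + 16.0) / 116.0)


def xyz_to_lab(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    f = _lab_f(arr / WHITE_XYZ)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def xyz_to_luv(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    X, Y, Z = arr[..., 0], arr[..., 1], arr[..., 2]
    y = Y / WHITE_XYZ[1]
    L = np.where(y > _EPSILON, 116.0 * np.cbrt(y) - 16.0, _KAPPA * y)

    denom = X + 15.0 * Y + 3.0 * Z
    wx, wy, wz = WHITE_XYZ
    wdenom = wx + 15.0 * wy + 3.0 * wz
    # u', v' are undefined at zero luminance; the placeholder value is
    # irrelevant because L = 0 multiplies it away, yielding u* = v* = 0.
    safe = np.where(denom > 0.0, denom, 1.0)
    up = np.where(denom > 0.0, 4.0 * X / safe, 4.0 * wx / wdenom)
    vp = np.where(denom > 0.0, 9.0 * Y / safe, 9.0 * wy / wdenom)
    u = 13.0 * L * (up - 4.0 * wx / wdenom)
    v = 13.0 * L * (vp - 9.0 * wy / wdenom)
    return np.stack([L, u, v], axis=-1)


def srgb_to(arr: np.ndarray, space: str) -> np.ndarray:
    """Convert an ``(..., 3)`` array of sRGB colors to ``space``."""
    if space == "sRGB":
        return np.asarray(arr, dtype=float)
    if space == "XYZ":
        return srgb_to_xyz(arr)
    if space == "Lab":
        return xyz_to_lab(srgb_to_xyz(arr))
    if space == "Luv":
        return xyz_to_luv(srgb_to_xyz(arr))
    raise SpaceMismatchError(f"unknown color space {space!r}; expected one of {SPACES}")


def convert_color(c: ColorPoint, target: str) -> ColorPoint:
    """Convert a single sRGB :class:`ColorPoint` to the target space."""
    if c.space != "sRGB":
        raise SpaceMismatchError(
            f"convert_color expects an sRGB input, got {c.space}"
        )
    arr = c.to_array()
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ColorRangeError(f"sRGB channels must lie in [0, 1], got {c.coords}")
    return ColorPoint(tuple(srgb_to(arr, target)), target)


def color_distance(p: ColorPoint, q: ColorPoint, metric: str = "euclidean") -> float:
    """Euclidean or taxicab (Manhattan) distance between same-space colors."""
    if p.space != q.space:
        raise SpaceMismatchError(
            f"cannot compare colors across spaces: {p.space} vs {q.space}"
        )
    delta = p.to_array() - q.to_array()
    if metric == "euclidean":
        return float(np.sqrt(np.sum(delta**2)))
    if metric == "taxicab":
        return float(np.sum(np.abs(delta)))
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
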