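"""Screening arithmetic: positive predictive value at a given prevalence.

Even a consistency test with high sensitivity and specificity yields many
false positives when the screened trait is rare. For sensitivity ``se``,
specificity ``sp`` and prevalence ``pi``, the positive predictive value is

    PPV = se * pi / (se * pi + (1 - sp) * (1 - pi))

and 1 - PPV is the expected proportion of false positives among those who
screen positive. All three parameters are proportions in [0, 1]; percentage
inputs (e.g. 1.1 for 1.1%) are rejected by the range check, which guards
against silent hundred-fold errors.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ScreeningParams", "ppv", "false_positive_proportion"]


@dataclass(frozen=True)
class ScreeningParams:
    sensitivity: float
    specificity: float
    prevalence: float

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "prevalence"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(
                    f"{name} must be a proportion in [0, 1], got {value}"
                )


def ppv(p: ScreeningParams) -> float:
    """Proportion of true positives among positive screens."""
    true_pos = p.sensitivity * p.prevalence
    false_pos = (1.0 - p.specificity) * (1.0 - p.prevalence)
    denom = true_pos + false_pos
    if denom == 0.0:
        raise ZeroDivisionError(
            "PPV undefined: no positive screens under these parameters"
        )
    return true_pos / denom


def false_positive_proportion(p: ScreeningParams) -> float:
    """Expected proportion of false positives among positive screens."""
    return 1.0 - ppv(p)
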