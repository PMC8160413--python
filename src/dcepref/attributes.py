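"""Attribute space for gadolinium-based contrast media (GBCM) choice experiments.

An attribute is a product property respondents trade off when choosing a
contrast agent: cancer detection sensitivity, intracranial gadolinium
retention, severe and mild allergic-like reaction rates, and out-of-pocket
cost. Each attribute takes a small set of numeric levels spanning a
clinically plausible range, has a monotone preference direction, and an
interpolation metric (linear or logarithmic) used when a product's value
falls between design levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "AttributeSpec",
    "build_default_attribute_space",
    "DIRECTIONS",
    "SCALES",
]

DIRECTIONS = ("higher_better", "lower_better")
SCALES = ("linear", "log")


@dataclass(frozen=True)
class AttributeSpec:
    """One choice attribute with its numeric levels.

    Parameters
    ----------
    name
        Identifier, e.g. ``"sensitivity"``.
    levels
        Strictly increasing numeric level values (at least two, all finite).
        Units are attribute-specific: percent for sensitivity, molecules per
        100 million administered for retention, events per 100,000
        administrations for reaction rates, USD for cost.
    direction
        ``"higher_better"`` or ``"lower_better"``: the monotone preference
        direction a rational respondent is assumed to have.
    scale
        ``"linear"`` or ``"log"``: the axis on which utilities are
        interpolated between levels. Log scale requires positive levels.
    """

    name: str
    levels: tuple[float, ...]
    direction: str = "lower_better"
    scale: str = "linear"

    def __post_init__(self) -> None:
        levels = tuple(float(v) for v in self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) < 2:
            raise ValueError(f"attribute {self.name!r}: need >=2 levels, got {len(levels)}")
        if not all(math.isfinite(v) for v in levels):
            raise ValueError(f"attribute {self.name!r}: levels must be finite")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError(f"attribute {self.name!r}: levels must be strictly increasing")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"attribute {self.name!r}: direction must be one of {DIRECTIONS}")
        if self.scale not in SCALES:
            raise ValueError(f"attribute {self.name!r}: scale must be one of {SCALES}")
        if self.scale == "log" and levels[0] <= 0:
            raise ValueError(f"attribute {self.name!r}: log scale requires all levels > 0")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def axis(self) -> list[float]:
        """Level positions on the interpolation axis (log10 for log scale)."""
        if self.scale == "log":
            return [math.log10(v) for v in self.levels]
        return list(self.levels)

    def level_index(self, value: float, atol: float = 1e-9) -> int:
        """Index of the level equal to ``value`` (within tolerance)."""
        for i, v in enumerate(self.levels):
            if math.isclose(v, value, rel_tol=1e-9, abs_tol=atol):
                return i
        raise KeyError(f"value {value} is not a level of attribute {self.name!r}")


def build_default_attribute_space() -> list[AttributeSpec]:
    """The five GBCM attributes with four levels each.

    Level grids span the published clinical ranges: sensitivity 80-95%,
    retention 1-100 molecules/100M, severe reactions 1-19/100k, mild
    reactions 10-1000/100k, cost $25-$100. Sensitivity is the only
    higher-is-better attribute; retention and both reaction rates span one
    to two orders of magnitude and therefore interpolate on a log axis.
    """
    return [
        AttributeSpec("sensitivity", (80.0, 85.0, 90.0, 95.0), "higher_better", "linear"),
        AttributeSpec("retention", (1.0, 10.0, 50.0, 100.0), "lower_better", "log"),
        AttributeSpec("severe_reaction", (1.0, 7.0, 13.0, 19.0), "lower_better", "log"),
        AttributeSpec("mild_reaction", (10.0, 100.0, 500.0, 1000.0), "lower_better", "log"),
        AttributeSpec("cost", (25.0, 50.0, 75.0, 100.0), "lower_better", "linear"),
    ]


def attribute_index(space: list[AttributeSpec]) -> dict[str, AttributeSpec]:
    """Name -> spec lookup; raises on duplicate names."""
    idx: dict[str, AttributeSpec] = {}
    for spec in space:
        if spec.name in idx:
            raise ValueError(f"duplicate attribute name {spec.name!r}")
        idx[spec.name] = spec
    return idx
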