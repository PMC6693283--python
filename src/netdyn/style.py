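"""Expression-to-colour and degree-to-radius mapping.

The colour scale is a symmetric diverging ramp.  Its domain is
``[-M, +M]`` where ``M`` is the maximum absolute value over the *whole*
expression series (all nodes, all frames), so a dark red at one end means
exactly as much downregulation as the bright green (or blue) at the other
end means upregulation, and colours are comparable across every frame of
an animation.  The ramp runs dark-to-bright through a near-black neutral
at zero: full red (255, 0, 0) at -M, the neutral at 0, full green
(0, 255, 0) — or blue for the red/blue palette — at +M, linear per RGB
channel.  Values outside the domain clamp; missing values render in a
neutral grey distinct from the zero colour.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import ExpressionSeries

__all__ = [
    "ColourScale",
    "SizeRule",
    "build_colour_scale",
    "value_to_colour",
    "colour_to_hex",
    "degree_to_radius",
    "NEUTRAL_COLOUR",
    "MISSING_COLOUR",
    "PALETTES",
]

RGB = tuple[int, int, int]

#: colour at expression 0 (dark neutral midpoint of the ramp)
NEUTRAL_COLOUR: RGB = (0, 0, 0)
#: colour for nodes with no expression value (missing is not zero)
MISSING_COLOUR: RGB = (128, 128, 128)

#: palette name -> (colour at -M, colour at +M)
PALETTES: dict[str, tuple[RGB, RGB]] = {
    "red_green": ((255, 0, 0), (0, 255, 0)),
    "red_blue": ((255, 0, 0), (0, 0, 255)),
}


@dataclass(frozen=True)
class ColourScale:
    """Symmetric linear colour map over [-max_abs, +max_abs]."""

    max_abs: float
    palette: str = "red_green"

    def __post_init__(self) -> None:
        if self.palette not in PALETTES:
            raise ValueError(
                f"palette must be one of {sorted(PALETTES)}, got {self.palette!r}"
            )
        if self.max_abs < 0:
            raise ValueError("max_abs must be non-negative")

    @property
    def domain(self) -> tuple[float, float]:
        return (-self.max_abs, self.max_abs)


def build_colour_scale(
    expr: ExpressionSeries, palette: str = "red_green"
) -> ColourScale:
    """Scale with domain [-M, +M], M = max |value| over the whole series.

    An all-zero series yields the degenerate domain [0, 0]: every value
    maps to the neutral colour.  A series with no numeric values at all
    is an error.
    """
    return ColourScale(max_abs=expr.max_abs(), palette=palette)


def _lerp(a: RGB, b: RGB, t: float) -> RGB:
    # round half up so the halfway point lands exactly between channels
    return tuple(int(ca + (cb - ca) * t + 0.5) for ca, cb in zip(a, b))  # type: ignore[return-value]


def value_to_colour(scale: ColourScale, value: float | None) -> RGB:
    """Map an expression value to RGB.  Total function: out-of-domain
    values clamp to the endpoints, ``None`` (missing) maps to grey."""
    if value is None:
        return MISSING_COLOUR
    low, high = PALETTES[scale.palette]
    if scale.max_abs == 0:
        return NEUTRAL_COLOUR
    t = max(-1.0, min(1.0, value / scale.max_abs))
    if t >= 0:
        return _lerp(NEUTRAL_COLOUR, high, t)
    return _lerp(NEUTRAL_COLOUR, low, -t)


def colour_to_hex(colour: RGB) -> str:
    return "#{:02x}{:02x}{:02x}".format(*colour)


@dataclass(frozen=True)
class SizeRule:
    """Node radius policy.

    ``mode`` selects the degree component driving the size (or ``fixed``);
    the radius maps [0, max_degree] linearly onto [min_radius, max_radius]
    in display units, so radius is monotone in the chosen degree.
    """

    mode: str = "fixed"  # fixed | by_total | by_inner | by_outer
    min_radius: float = 6.0
    max_radius: float = 24.0
    max_degree: int = 0

    VALID_MODES = ("fixed", "by_total", "by_inner", "by_outer")

    def __post_init__(self) -> None:
        if self.mode not in self.VALID_MODES:
            raise ValueError(
                f"mode must be one of {self.VALID_MODES}, got {self.mode!r}"
            )
        if self.min_radius > self.max_radius:
            raise ValueError("min_radius must not exceed max_radius")

    @property
    def degree_kind(self) -> str | None:
        """The degree-table column this rule reads, or None for fixed."""
        return None if self.mode == "fixed" else self.mode.removeprefix("by_")


def degree_to_radius(rule: SizeRule, degree: int) -> float:
    """Radius for a node of the given degree under the rule."""
    if degree < 0:
        raise ValueError("degree must be >= 0")
    if rule.mode == "fixed" or rule.max_degree == 0:
        return rule.min_radius
    t = min(degree, rule.max_degree) / rule.max_degree
    return rule.min_radius + (rule.max_radius - rule.min_radius) * t
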