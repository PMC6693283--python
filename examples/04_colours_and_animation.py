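"""Map dose-over-time expression to colours and export an animation.

The colour domain is [-M, +M] with M the maximum absolute value over the
whole series, so downregulation (towards red) and upregulation (towards
green or blue) are visually symmetric and comparable across frames.
The animation recolours a fixed layout frame by frame and exports as an
animated GIF, a numbered PNG sequence, or a standalone HTML page with
forward/backward controls.
"""

import tempfile
from pathlib import Path

from netdyn import (
    ExpressionSeries,
    TemporalNetwork,
    build_animation,
    build_colour_scale,
    colour_to_hex,
    export_animation,
    step,
    value_to_colour,
)

net = TemporalNetwork.from_edges(
    [("TLR4", "TNFSF11"), ("TLR4", "CCL4"), ("TLR4", "GADD45B")]
)
# frames cross dose and time: T<time>_D<dose>
frames = ["T8_D200", "T8_D1000", "T8_D5000"]
expr = ExpressionSeries.from_dict(
    {
        "TLR4": [0.1, -0.8, -2.4],      # strong downregulation at high dose
        "TNFSF11": [0.0, -0.5, -2.0],
        "CCL4": [0.2, 0.6, 1.8],        # upregulated
        "GADD45B": [0.1, 0.4, 1.2],
    },
    frames=frames,
)

scale = build_colour_scale(expr, palette="red_green")
print(f"colour domain: [{scale.domain[0]:+.1f}, {scale.domain[1]:+.1f}]")
for value in (-2.4, 0.0, 1.8):
    print(f"  expression {value:+.1f} -> {colour_to_hex(value_to_colour(scale, value))}")

anim = build_animation(net, expr, scale=scale, seed=1)
print(f"\nanimation has {len(anim)} frames: {anim.labels}")
frame = step(anim, "forward")
print(f"stepping forward shows {frame.label}; "
      f"TLR4 is {frame.colours['TLR4']} there (darker red = more downregulated)")

with tempfile.TemporaryDirectory() as workdir:
    written = export_animation(anim, Path(workdir) / "animation.gif", "gif")
    size = written[0].stat().st_size
    print(f"\nwrote {written[0].name} ({size} bytes, "
          f"{len(anim)} frames at 1 s per frame)")
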