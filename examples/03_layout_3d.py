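"""Compute a deterministic force-directed layout and lift it to 3D.

The 2D spring embedding pulls connected nodes together and pushes all
pairs apart; coordinates are normalized to the unit square.  The third
dimension is the closed-form dome z = 0.8 y sin(pi y) + 0.8 x sin(pi x),
zero on the square's corners and 0.8 at the centre, so central (densely
connected) nodes are lifted highest.
"""

from netdyn import TemporalNetwork, extend_to_3d, force_directed_2d, z_value

edges = [("HUB", f"s{i}") for i in range(6)] + [("s0", "s1"), ("s2", "s3")]
net = TemporalNetwork.from_edges(edges)

pos2d = force_directed_2d(net, "frame1", seed=42)
pos3d = extend_to_3d(pos2d)

print("node        x      y      z")
for node, (x, y, z) in sorted(pos3d.coords.items()):
    print(f"{node:8s} {x:6.3f} {y:6.3f} {z:6.3f}")

hx, hy, hz = pos3d["HUB"]
print(
    f"\nThe hub sits near the centre of the square and is lifted to "
    f"z = {hz:.3f} (the theoretical maximum at (0.5, 0.5) is "
    f"{z_value(0.5, 0.5):.1f}); peripheral spokes stay low."
)
print("Same seed, same input -> bitwise identical coordinates on re-run.")
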