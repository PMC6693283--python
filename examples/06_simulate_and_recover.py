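"""Generate a synthetic exposure/washout study and recover its ground truth.

The generator plants a focal hub whose interactions grow over three
exposure frames and partially persist after washout, plus expression
trajectories, on top of random background edge turnover.  Everything is
seeded; the analysis pipeline then recovers the planted numbers exactly
from the written files, which is how the engine's end-to-end correctness
is checked without any external download.
"""

import json
import tempfile

from netdyn import degree_over_time, read_dynamic_edges, read_expression
from netdyn.fixtures import FixtureSpec, generate_fixture

spec = FixtureSpec(seed=123)  # 100 genes, frames day1..day3 + washout

with tempfile.TemporaryDirectory() as workdir:
    paths = generate_fixture(spec, workdir)
    truth = json.loads(paths["ground_truth"].read_text())

    net = read_dynamic_edges(paths["dynamic_edges"])
    expr = read_expression(paths["expression"])

    hub = truth["hub"]["node"]
    tidy = degree_over_time(net)
    recovered = tidy[tidy.node == hub].set_index("frame")

    print("frame     planted(total)  recovered(total)")
    for frame, planted in zip(truth["frames"], truth["hub"]["total"]):
        print(f"{frame:9s} {planted:14d} {int(recovered.loc[frame, 'total']):17d}")

    peak, washout = truth["frames"][-2], truth["frames"][-1]
    a = {e for e in net.edges(peak) if hub in e}
    b = {e for e in net.edges(washout) if hub in e}
    print(
        f"\nhub keeps {len(a & b)} of {len(a)} interactions after washout "
        f"(planted: {truth['hub_persistent_counts'][f'{peak}->{washout}']})"
    )
    print(
        f"planted HUB trajectory {truth['trajectories'][hub]} read back as "
        f"{[expr.value(hub, f) for f in truth['frames']]}"
    )
    print("\nEvery number above is recovered from the files, not copied from memory.")
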