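"""Layer-graph compilation: reference schedule, counts, invariants."""

import numpy as np
import pytest

from eunet.archspec import parse_architecture, random_valid_spec
from eunet.errors import GraphConfigError, ShapeError
from eunet.graphgen import (LayerGraph, analytic_parameter_count,
                            build_baseline_unet, build_dilated_unet,
                            build_layer_graph, count_layer_blocks,
                            dilated_kernel_extent, graphs_isomorphic,
                            infer_shapes)

SHP = "U_1(4-4)-U_2(4-4)"

#: the reference SHP layer schedule at 128x128: resolution and channel
#: multiplier (x base_filters) per indexed block
SHP_SCHEDULE = {
    "Lay1": (128, 1), "Lay2": (64, 2), "Lay3": (32, 4), "Lay4": (16, 8),
    "Lay5": (32, 4), "Lay6": (64, 2), "Lay7": (128, 1), "Lay8": (64, 2),
    "Lay9": (32, 4), "Lay10": (16, 8), "Lay11": (32, 4), "Lay12": (64, 2),
    "Lay13": (128, 1),
}


@pytest.fixture(scope="module")
def shp_graph():
    return build_layer_graph(SHP, (128, 128), base_filters=4)


def test_shp_reference_schedule(shp_graph):
    """Resolutions and channel multipliers of Lay1..Lay13 and the output."""
    table = infer_shapes(shp_graph)
    for lay, (res, mult) in SHP_SCHEDULE.items():
        assert table.resolution(lay) == (res, res), lay
        assert table.channels(lay) == 4 * mult, lay
    assert table.resolution("Output") == (128, 128)
    assert table.channels("Output") == 1


def test_shp_block_structure(shp_graph):
    ids = shp_graph.block_ids()
    assert ids == [f"Lay{i}" for i in range(1, 14)]
    roles = {nid: shp_graph.nodes[nid].role for nid in ids}
    assert roles["Lay1"] == "input_down"
    assert roles["Lay4"] == roles["Lay10"] == "valley"
    assert roles["Lay7"] == "peak"
    assert roles["Lay13"] == "output_up"
    # the peak block ends one U (upsample path) and starts the next (pool)
    kinds = [op.kind for op in shp_graph.nodes["Lay7"].ops]
    assert kinds[0] == "upsample" and kinds[-1] == "pool"
    # terminal up layer ends with a 1x1 conv
    convs = [op for op in shp_graph.nodes["Lay13"].ops if op.kind == "conv"]
    assert convs[-1].kernel == (1, 1)


def test_skip_partners(shp_graph):
    skips = {(s, d) for s, d, k in shp_graph.edges if k == "skip"}
    assert skips == {("Lay3", "Lay5"), ("Lay2", "Lay6"), ("Lay1", "Lay7"),
                     ("Lay9", "Lay11"), ("Lay8", "Lay12"), ("Lay7", "Lay13")}


def test_peak_concatenated_into_output(shp_graph):
    assert shp_graph.nodes["Output"].concat_sources == ["Lay7"]
    g = build_layer_graph(SHP, (128, 128), 4, peak_to_output_concat=False)
    assert g.nodes["Output"].concat_sources == []


@pytest.mark.parametrize(
    "notation, expected",
    [(SHP, 13), ("U_1(4-4)", 7), ("U_1(2-2)", 3), ("U_1(4)//U^1(4)", 7),
     ("U_1(4-3)-U_2(3-4)", 11), ("U_1(4-4)-U_2(4-4)-U_3(4-4)", 19)],
)
def test_count_layer_blocks(notation, expected):
    assert count_layer_blocks(notation) == expected


def test_count_matches_built_graph():
    rng = np.random.default_rng(3)
    for _ in range(25):
        spec = random_valid_spec(rng, max_branches=1)
        g = build_layer_graph(spec, 2 ** (spec.max_depth_below_input + 2), 2)
        assert count_layer_blocks(spec) == len(g.block_ids())


@pytest.mark.parametrize("kernel, rate, extent",
                         [(3, 2, 5), (3, 1, 3), (5, 1, 5), (3, 3, 7), (1, 4, 1)])
def test_dilated_kernel_extent(kernel, rate, extent):
    assert dilated_kernel_extent(kernel, rate) == extent


@pytest.mark.parametrize("kernel, rate", [(0, 1), (3, 0), (-3, 2)])
def test_dilated_kernel_extent_rejects(kernel, rate):
    with pytest.raises(ValueError):
        dilated_kernel_extent(kernel, rate)


def test_shapes_scale_with_input():
    g = build_layer_graph(SHP, (64, 64), 4)
    table = infer_shapes(g)
    assert table.resolution("Lay4") == (8, 8)  # 64 / 2^3


def test_divisibility_enforced():
    with pytest.raises(GraphConfigError, match="divisible"):
        build_layer_graph("U_1(5-5)", (40, 40), 4)  # 40 % 16 != 0
    build_layer_graph("U_1(5-5)", (64, 64), 4)  # 64 / 2^4 = 4: fine


def test_depth1_is_poolless_passthrough():
    g = build_layer_graph("U_1(1-1)", (16, 16), 4)
    kinds = [op.kind for n in g.nodes.values() for op in n.ops]
    assert "pool" not in kinds and "upsample" not in kinds
    assert infer_shapes(g).resolution("Output") == (16, 16)


def test_branch_merges_at_valleys_and_outputs():
    g = build_layer_graph("U_1(4)//U^1(4)", (128, 128), 4)
    merges = {s for s, d, k in g.edges if k == "branch_merge"}
    assert merges == {"Lay4_1", "Lay4^1", "Lay7_1", "Lay7^1"}
    assert g.nodes["Merge1v"].concat_sources == ["Lay4_1", "Lay4^1"]
    assert g.nodes["Merge1o"].concat_sources == ["Lay7_1", "Lay7^1"]
    # the fused valley feeds both expansive paths
    fanout = {d for s, d, k in g.edges if s == "Merge1v" and k == "forward"}
    assert fanout == {"Lay5_1", "Lay5^1"}


def test_baseline_equivalence():
    for d in range(1, 6):
        size = 2 ** (d + 1)
        assert graphs_isomorphic(
            build_baseline_unet(d, (size, size), 4),
            build_layer_graph(parse_architecture(f"U_1({d}-{d})"), (size, size), 4))


def test_dilated_unet_levels():
    g = build_dilated_unet(4, 2, (128, 128), 4)
    for node in g.nodes.values():
        rates = {op.dilation for op in node.ops if op.kind == "conv" and op.kernel == (3, 3)}
        if node.role in ("input_down", "down", "valley") and node.elevation > -2:
            assert rates == {2}, node.id
        elif rates:
            assert rates == {1}, node.id
    # dilation must not change the shape schedule
    assert infer_shapes(g).resolution("Lay4") == (16, 16)
    with pytest.raises(ValueError):
        build_dilated_unet(4, 0, (128, 128), 4)
    with pytest.raises(ValueError):
        build_dilated_unet(4, 5, (128, 128), 4)


def test_independence_and_symmetry_invariants():
    """Skip edges stay inside one U at equal elevation; U interiors touch
    only through shared peaks, declared joints and merge nodes."""
    rng = np.random.default_rng(11)
    for _ in range(60):
        spec = random_valid_spec(rng)
        g = build_layer_graph(spec, 2 ** (spec.max_depth_below_input + 2), 2)
        for s, d, k in g.edges:
            if k == "skip":
                a, b = g.nodes[s], g.nodes[d]
                assert a.elevation == b.elevation
                assert a.u_labels & b.u_labels
        g.validate()  # raises on any independence violation


def test_resolution_conservation_random_suite():
    rng = np.random.default_rng(5)
    for _ in range(40):
        spec = random_valid_spec(rng)
        size = 2 ** (spec.max_depth_below_input + 2)
        table = infer_shapes(build_layer_graph(spec, size, 2))
        assert table.resolution("Output") == (size, size)


def test_parameter_count_monotonicity():
    p_small = analytic_parameter_count(build_layer_graph(SHP, 64, 2))
    p_big = analytic_parameter_count(build_layer_graph(SHP, 64, 4))
    p_more_seg = analytic_parameter_count(
        build_layer_graph("U_1(4-4)-U_2(4-4)-U_3(4-4)", 64, 2))
    p_more_branch = analytic_parameter_count(
        build_layer_graph("U_1(4)//U^1(4)", 64, 2))
    p_single = analytic_parameter_count(build_layer_graph("U_1(4-4)", 64, 2))
    assert p_big > p_small
    assert p_more_seg > p_small
    assert p_more_branch > p_single


def test_graph_json_round_trip(shp_graph):
    clone = LayerGraph.from_dict(shp_graph.to_dict())
    assert clone.to_json() == shp_graph.to_json()
    assert graphs_isomorphic(clone, shp_graph)


def test_concat_mismatch_reported():
    g = build_layer_graph(SHP, (128, 128), 4)
    g.nodes["Lay5"].ops.insert(0, g.nodes["Lay5"].ops[0])  # extra upsample
    with pytest.raises(ShapeError, match="Lay5"):
        infer_shapes(g)
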