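"""Compile an :class:`~eunet.archspec.ArchitectureSpec` into an explicit
layer graph.

The compiler realizes the construction rules of the elastomeric U-Net
family:

* a **down layer** at depth *k* applies two 3×3 convolutions at
  ``f_d × 2^(k−1)`` channels (batch-norm + ReLU after each) followed by a
  2×2 max-pool;
* the **valley** (deepest layer of a U) applies two 3×3 convolutions and a
  0.5 dropout, with no pool;
* an **up layer** applies 2× nearest upsampling, a 2×2 convolution halving
  the channels, channel-axis concatenation with its equal-elevation skip
  partner from the same U, and two 3×3 convolutions;
* a **peak layer** shared by two cascaded U structures additionally ends
  with the next structure's 2×2 pool;
* the **terminal up layer** of the cascade ends with a 1×1 convolution, and
  the **output head** maps to 2 channels (3×3 conv) then 1 channel (1×1
  conv) with a sigmoid.

Parallel branch groups are fanned out by a ``split`` node; ``merge`` nodes
(concatenation plus one 3×3 fusion convolution) fuse the branches at their
valleys and at their terminal layers, the fused valley tensor feeding every
branch's expansive path.

Different U structures are independent: no skip connection ever crosses
from one U into another; they communicate only through the shared peak
block (or declared merge nodes).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

from .archspec import ArchitectureSpec, parse_architecture
from .errors import GraphConfigError, ShapeError, SpecValidationError

__all__ = [
    "PrimitiveOp",
    "LayerNode",
    "LayerGraph",
    "ShapeTable",
    "build_layer_graph",
    "infer_shapes",
    "count_layer_blocks",
    "dilated_kernel_extent",
    "build_baseline_unet",
    "build_dilated_unet",
    "graphs_isomorphic",
    "analytic_parameter_count",
]

BLOCK_ROLES = frozenset(
    {"input_down", "down", "valley", "up", "peak", "output_up"}
)
INTERIOR_ROLES = frozenset({"input_down", "down", "valley", "up", "output_up"})


@dataclass(frozen=True)
class PrimitiveOp:
    """One primitive tensor operation inside a layer block."""

    kind: str  # conv | pool | upsample | concat | dropout | batchnorm | activation
    kernel: tuple[int, int] | None = None
    channels_out: int | None = None
    factor: int = 2
    dilation: int = 1
    rate: float | None = None
    fn: str | None = None  # activation name

    def __post_init__(self):
        if self.kind == "conv":
            if self.kernel is None or min(self.kernel) < 1:
                raise GraphConfigError(f"conv kernel must be positive, got {self.kernel}")
            if self.channels_out is None or self.channels_out < 1:
                raise GraphConfigError("conv channels_out must be positive")
            if self.dilation < 1:
                raise GraphConfigError("dilation rate must be >= 1")
        elif self.kind in ("pool", "upsample") and self.factor < 1:
            raise GraphConfigError("pool/upsample factor must be positive")
        elif self.kind == "dropout" and not (self.rate and 0 < self.rate < 1):
            raise GraphConfigError("dropout rate must lie in (0, 1)")

    def signature(self) -> tuple:
        return (self.kind, self.kernel, self.channels_out, self.factor,
                self.dilation, self.rate, self.fn)


def _conv(c: int, k: int = 3, dilation: int = 1) -> PrimitiveOp:
    return PrimitiveOp("conv", kernel=(k, k), channels_out=c, dilation=dilation)


@dataclass
class LayerNode:
    """One block of the layer graph (e.g. ``Lay7``)."""

    id: str
    role: str
    u_label: str
    branch_index: int = 0
    elevation: int = 0
    ops: list[PrimitiveOp] = field(default_factory=list)
    #: sources consumed by this node's concat op, in order (skip partner,
    #: branch tensors for a merge, or peak features for the output head).
    concat_sources: list[str] = field(default_factory=list)
    #: second owning U for a shared peak block.
    u_label_next: str | None = None

    @property
    def u_labels(self) -> frozenset[str]:
        labels = {self.u_label}
        if self.u_label_next is not None:
            labels.add(self.u_label_next)
        return frozenset(labels)

    @property
    def has_trailing_pool(self) -> bool:
        return bool(self.ops) and self.ops[-1].kind == "pool"


class LayerGraph:
    """Directed acyclic graph of layer blocks with typed edges."""

    def __init__(self, input_size: tuple[int, int], base_filters: int,
                 input_channels: int = 1, meta: dict | None = None):
        self.nodes: dict[str, LayerNode] = {}
        self.edges: list[tuple[str, str, str]] = []
        self.input_size = tuple(input_size)
        self.base_filters = base_filters
        self.input_channels = input_channels
        self.meta = dict(meta or {})

    # -- construction -------------------------------------------------
    def add_node(self, node: LayerNode) -> LayerNode:
        if node.id in self.nodes:
            raise GraphConfigError(f"duplicate node id {node.id!r}")
        self.nodes[node.id] = node
        return node

    def add_edge(self, src: str, dst: str, kind: str) -> None:
        if kind not in ("forward", "skip", "branch_split", "branch_merge", "peak_concat"):
            raise GraphConfigError(f"unknown edge kind {kind!r}")
        self.edges.append((src, dst, kind))

    # -- queries ------------------------------------------------------
    def in_edges(self, node_id: str) -> list[tuple[str, str, str]]:
        return [e for e in self.edges if e[1] == node_id]

    def out_edges(self, node_id: str) -> list[tuple[str, str, str]]:
        return [e for e in self.edges if e[0] == node_id]

    def main_input(self, node_id: str) -> str | None:
        """Id of the node feeding this block's primary input, if any."""
        srcs = [s for s, _, k in self.in_edges(node_id) if k in ("forward", "branch_split")]
        if len(srcs) > 1:
            raise GraphConfigError(f"{node_id} has {len(srcs)} primary inputs")
        return srcs[0] if srcs else None

    @property
    def root_id(self) -> str:
        roots = [nid for nid in self.nodes if not self.in_edges(nid)]
        if len(roots) != 1:
            raise GraphConfigError(f"expected exactly one input node, found {roots}")
        return roots[0]

    @property
    def output_id(self) -> str:
        heads = [nid for nid, n in self.nodes.items() if n.role == "output_head"]
        if len(heads) != 1:
            raise GraphConfigError(f"expected exactly one output head, found {heads}")
        return heads[0]

    def topo_order(self) -> list[str]:
        indeg = {nid: 0 for nid in self.nodes}
        for src, dst, _ in self.edges:
            indeg[dst] += 1
        # stable: respect insertion order among ready nodes
        order, ready = [], [nid for nid in self.nodes if indeg[nid] == 0]
        while ready:
            nid = ready.pop(0)
            order.append(nid)
            for _, dst, _ in self.out_edges(nid):
                indeg[dst] -= 1
                if indeg[dst] == 0:
                    ready.append(dst)
        if len(order) != len(self.nodes):
            raise GraphConfigError("layer graph contains a cycle")
        return order

    def block_ids(self) -> list[str]:
        return [nid for nid, n in self.nodes.items() if n.role in BLOCK_ROLES]

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "input_size": list(self.input_size),
            "base_filters": self.base_filters,
            "input_channels": self.input_channels,
            "meta": self.meta,
            "nodes": [
                {
                    "id": n.id, "role": n.role, "u_label": n.u_label,
                    "u_label_next": n.u_label_next,
                    "branch_index": n.branch_index, "elevation": n.elevation,
                    "concat_sources": list(n.concat_sources),
                    "ops": [
                        {k: v for k, v in {
                            "kind": op.kind, "kernel": op.kernel,
                            "channels_out": op.channels_out, "factor": op.factor,
                            "dilation": op.dilation, "rate": op.rate, "fn": op.fn,
                        }.items() if v is not None}
                        for op in n.ops
                    ],
                }
                for n in self.nodes.values()
            ],
            "edges": [list(e) for e in self.edges],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LayerGraph":
        g = cls(tuple(d["input_size"]), d["base_filters"],
                d.get("input_channels", 1), d.get("meta"))
        for nd in d["nodes"]:
            ops = [PrimitiveOp(
                kind=od["kind"], kernel=tuple(od["kernel"]) if od.get("kernel") else None,
                channels_out=od.get("channels_out"), factor=od.get("factor", 2),
                dilation=od.get("dilation", 1), rate=od.get("rate"), fn=od.get("fn"),
            ) for od in nd["ops"]]
            g.add_node(LayerNode(
                id=nd["id"], role=nd["role"], u_label=nd["u_label"],
                u_label_next=nd.get("u_label_next"),
                branch_index=nd.get("branch_index", 0), elevation=nd["elevation"],
                ops=ops, concat_sources=list(nd.get("concat_sources", []))))
        for src, dst, kind in d["edges"]:
            g.add_edge(src, dst, kind)
        return g

    def to_json(self, indent: int | None = None) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def fingerprint(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def to_dot(self) -> str:
        colors = {"forward": "black", "skip": "blue", "branch_split": "darkgreen",
                  "branch_merge": "darkgreen", "peak_concat": "purple"}
        lines = ["digraph eunet {", "  rankdir=LR;"]
        for n in self.nodes.values():
            lines.append(f'  "{n.id}" [label="{n.id}\\n{n.role} e{n.elevation}"];')
        for src, dst, kind in self.edges:
            lines.append(f'  "{src}" -> "{dst}" [color={colors[kind]}, label="{kind}"];')
        lines.append("}")
        return "\n".join(lines)

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        """Check the structural invariants; raise GraphConfigError on failure."""
        self.topo_order()
        _ = self.root_id, self.output_id
        for nid, node in self.nodes.items():
            kinds = [op.kind for op in node.ops]
            if node.role == "valley":
                if "dropout" not in kinds or "pool" in kinds:
                    raise GraphConfigError(f"valley {nid} must contain dropout and no pool")
            if node.role == "peak":
                if "pool" not in kinds or "upsample" not in kinds:
                    raise GraphConfigError(f"peak {nid} must contain an up-path tail and a pool")
            skip_in = [e for e in self.in_edges(nid) if e[2] == "skip"]
            if len(skip_in) > 1:
                raise GraphConfigError(f"{nid} has {len(skip_in)} incoming skip edges")
        for src, dst, kind in self.edges:
            a, b = self.nodes[src], self.nodes[dst]
            if kind == "skip":
                if a.elevation != b.elevation:
                    raise GraphConfigError(
                        f"skip edge {src}->{dst} connects different elevations")
                if not (a.u_labels & b.u_labels):
                    raise GraphConfigError(
                        f"skip edge {src}->{dst} crosses U structures")
            if kind in ("forward", "skip"):
                # the only cross-U connections allowed are declared cascade
                # joints (one U's terminal feeding the next U's first block)
                joints = {tuple(e) for e in self.meta.get("joint_edges", [])}
                if (a.role in INTERIOR_ROLES and b.role in INTERIOR_ROLES
                        and not (a.u_labels & b.u_labels)
                        and (src, dst) not in joints):
                    raise GraphConfigError(
                        f"edge {src}->{dst} connects interior nodes of different U structures")


def _as_pair(size) -> tuple[int, int]:
    if isinstance(size, int):
        return (size, size)
    h, w = size
    return (int(h), int(w))


def build_layer_graph(
    spec: ArchitectureSpec | str,
    input_size=(128, 128),
    base_filters: int = 64,
    *,
    input_channels: int = 1,
    use_batchnorm: bool = True,
    dropout_rate: float = 0.5,
    peak_to_output_concat: bool = True,
) -> LayerGraph:
    """Compile an architecture into a validated :class:`LayerGraph`.

    ``input_size`` must be divisible by ``2**L`` where *L* is the number of
    pooling levels the deepest valley requires.
    """
    if isinstance(spec, str):
        spec = parse_architecture(spec)
    input_size = _as_pair(input_size)
    if base_filters < 1:
        raise GraphConfigError("base_filters must be >= 1")
    levels = spec.max_depth_below_input
    div = 2 ** levels
    for side in input_size:
        if side % div != 0:
            raise GraphConfigError(
                f"input size {input_size} not divisible by {div} "
                f"(required by {levels} pooling levels)")

    g = LayerGraph(input_size, base_filters, input_channels, meta={
        "notation": str(spec), "use_batchnorm": use_batchnorm,
        "dropout_rate": dropout_rate, "peak_to_output_concat": peak_to_output_concat,
    })

    def channels(elev: int) -> int:
        return base_filters * 2 ** (-elev)

    def conv_stack(c: int, k: int = 3) -> list[PrimitiveOp]:
        ops = [_conv(c, k)]
        if use_batchnorm:
            ops.append(PrimitiveOp("batchnorm"))
        ops.append(PrimitiveOp("activation", fn="relu"))
        return ops

    counter = 0              # global block index (Lay numbering)
    prev_out: str | None = None
    prev_terminal: str | None = None  # single-branch terminal eligible as shared peak
    peak_feats: list[str] = []
    e_in = 0
    n_seg = len(spec.segments)

    for si, group in enumerate(spec.segments):
        nb = len(group.branches)
        final_segment = si == n_seg - 1
        # collect the cascade-joint feature for the output concat
        if si > 0 and e_in == 0 and prev_out is not None:
            peak_feats.append(prev_out)

        split_id = None
        if nb > 1:
            split_id = f"Split{si + 1}"
            g.add_node(LayerNode(split_id, "split", u_label=f"seg{si + 1}", elevation=e_in))
            if prev_out is not None:
                g.add_edge(prev_out, split_id, "forward")

        base_idx = counter
        branch_chains: list[dict] = []
        created_max = 0
        for j, br in enumerate(group.branches):
            suffix = br.label if nb > 1 else ""
            share_peak = (nb == 1 and prev_terminal is not None and br.down_depth >= 2)
            down_ids: dict[int, str] = {}
            idx = base_idx
            chain_prev: str | None
            if share_peak:
                peak_node = g.nodes[prev_terminal]
                peak_node.ops.append(PrimitiveOp("pool", factor=2))
                peak_node.role = "peak"
                peak_node.u_label_next = br.label
                down_ids[e_in] = peak_node.id
                chain_prev = peak_node.id
                first_off = 1
            else:
                chain_prev = split_id if nb > 1 else prev_out
                first_off = 0

            # contracting path
            for off in range(first_off, br.down_depth):
                elev = e_in - off
                idx += 1
                nid = f"Lay{idx}{suffix}"
                is_valley = off == br.down_depth - 1
                ops = conv_stack(channels(elev)) + conv_stack(channels(elev))
                if is_valley:
                    ops.append(PrimitiveOp("dropout", rate=dropout_rate))
                    role = "valley"
                else:
                    ops.append(PrimitiveOp("pool", factor=2))
                    role = "input_down" if (si == 0 and off == 0) else "down"
                node = g.add_node(LayerNode(nid, role, u_label=br.label,
                                            branch_index=j, elevation=elev, ops=ops))
                if chain_prev is not None:
                    kind = "branch_split" if chain_prev == split_id else "forward"
                    g.add_edge(chain_prev, nid, kind)
                    if si > 0 and chain_prev == prev_out and off == first_off:
                        g.meta.setdefault("joint_edges", []).append((chain_prev, nid))
                down_ids[elev] = nid
                chain_prev = nid

            branch_chains.append({
                "branch": br, "suffix": suffix, "down_ids": down_ids,
                "valley_id": chain_prev, "next_idx": idx, "share_peak": share_peak,
            })
            created_max = max(created_max, idx - base_idx)

        # valley fusion across parallel branches (per equal elevation)
        valley_feed: dict[int, str] = {}  # branch index -> node feeding its up path
        for j, ch in enumerate(branch_chains):
            valley_feed[j] = ch["valley_id"]
        if nb > 1:
            by_elev: dict[int, list[int]] = {}
            for j, ch in enumerate(branch_chains):
                by_elev.setdefault(g.nodes[ch["valley_id"]].elevation, []).append(j)
            for elev, members in sorted(by_elev.items()):
                if len(members) < 2:
                    continue
                mid = f"Merge{si + 1}v" if len(by_elev) == 1 else f"Merge{si + 1}v{-elev}"
                merge = g.add_node(LayerNode(
                    mid, "merge", u_label=f"seg{si + 1}", elevation=elev,
                    ops=[PrimitiveOp("concat")] + conv_stack(channels(elev)),
                    concat_sources=[branch_chains[j]["valley_id"] for j in members]))
                for j in members:
                    g.add_edge(branch_chains[j]["valley_id"], mid, "branch_merge")
                    valley_feed[j] = mid

        # expansive paths
        terminal_ids = []
        for j, ch in enumerate(branch_chains):
            br, suffix, down_ids = ch["branch"], ch["suffix"], ch["down_ids"]
            valley_elev = e_in - (br.down_depth - 1)
            terminal_elev = e_in - br.down_depth + br.up_depth
            chain_prev = valley_feed[j]
            idx = ch["next_idx"]
            if br.up_depth == 1:
                terminal_ids.append(ch["valley_id"])
                continue
            for elev in range(valley_elev + 1, terminal_elev + 1):
                idx += 1
                nid = f"Lay{idx}{suffix}"
                is_terminal = elev == terminal_elev
                ops = [PrimitiveOp("upsample", factor=2)] + conv_stack(channels(elev), k=2)
                sources = []
                if elev in down_ids:
                    ops.append(PrimitiveOp("concat"))
                    sources.append(down_ids[elev])
                ops += conv_stack(channels(elev))
                if is_terminal and final_segment:
                    ops += conv_stack(channels(elev), k=1)
                    role = "output_up"
                else:
                    ops += conv_stack(channels(elev))
                    role = "up"
                node = g.add_node(LayerNode(nid, role, u_label=br.label,
                                            branch_index=j, elevation=elev, ops=ops,
                                            concat_sources=sources))
                g.add_edge(chain_prev, nid, "forward")
                for s in sources:
                    g.add_edge(s, nid, "skip")
                chain_prev = nid
            terminal_ids.append(chain_prev)
            created_max = max(created_max, idx - base_idx)

        counter = base_idx + created_max

        # terminal fusion for parallel branches
        if nb > 1:
            term_elev = g.nodes[terminal_ids[0]].elevation
            mid = f"Merge{si + 1}o"
            g.add_node(LayerNode(
                mid, "merge", u_label=f"seg{si + 1}", elevation=term_elev,
                ops=[PrimitiveOp("concat")] + conv_stack(channels(term_elev)),
                concat_sources=list(terminal_ids)))
            for t in terminal_ids:
                g.add_edge(t, mid, "branch_merge")
            prev_out = mid
            prev_terminal = None
        else:
            prev_out = terminal_ids[0]
            # only a genuine up block can be promoted to a shared peak
            is_up = g.nodes[terminal_ids[0]].role in ("up", "output_up")
            prev_terminal = terminal_ids[0] if is_up else None

        e_in += group.elevation_delta

    # output head
    head_ops: list[PrimitiveOp] = []
    head_sources: list[str] = []
    if peak_to_output_concat and peak_feats:
        head_ops.append(PrimitiveOp("concat"))
        head_sources = list(peak_feats)
    head_ops += conv_stack(2, k=3)
    head_ops += [_conv(1, k=1), PrimitiveOp("activation", fn="sigmoid")]
    g.add_node(LayerNode("Output", "output_head", u_label="head", elevation=0,
                         ops=head_ops, concat_sources=head_sources))
    g.add_edge(prev_out, "Output", "forward")
    for s in head_sources:
        g.add_edge(s, "Output", "peak_concat")

    g.validate()
    infer_shapes(g)  # raises on any shape inconsistency
    return g


# ---------------------------------------------------------------------------
# shape inference


@dataclass(frozen=True)
class ShapeRow:
    id: str
    resolution: tuple[int, int]
    channels: int


@dataclass
class ShapeTable:
    """Per-block (spatial resolution, channel count) table.

    The resolution of a block is the size at which its convolutions operate
    (i.e. before any trailing pool), matching the reference layer schedule.
    """

    rows: list[ShapeRow]
    base_filters: int

    def resolution(self, node_id: str) -> tuple[int, int]:
        return self._row(node_id).resolution

    def channels(self, node_id: str) -> int:
        return self._row(node_id).channels

    def _row(self, node_id: str) -> ShapeRow:
        for r in self.rows:
            if r.id == node_id:
                return r
        raise KeyError(node_id)

    def to_tsv(self, graph: "LayerGraph | None" = None) -> str:
        lines = ["Layer\tConfiguration\tFeature size"]
        for r in self.rows:
            config = ""
            if graph is not None and r.id in graph.nodes:
                config = describe_ops(graph.nodes[r.id].ops, self.base_filters)
            lines.append(f"{r.id}\t{config}\t{r.resolution[0]}×{r.resolution[1]}")
        return "\n".join(lines)


def describe_ops(ops: list[PrimitiveOp], base_filters: int) -> str:
    """Human-readable configuration summary in the style of the layer table
    (batch-norm and activations omitted, as there)."""
    parts = []
    for op in ops:
        if op.kind == "conv":
            c = op.channels_out
            label = (f"f_d×{c // base_filters}" if c % base_filters == 0 and c >= base_filters
                     else str(c))
            extent = f"{op.kernel[0]}×{op.kernel[1]}"
            if op.dilation > 1:
                extent += f" (rate {op.dilation})"
            parts.append(f"{label}, {extent}, Conv")
        elif op.kind == "pool":
            parts.append(f"{op.factor}×{op.factor}, Pooling")
        elif op.kind == "upsample":
            parts.append(f"{op.factor}×{op.factor}, UpSampling")
        elif op.kind == "concat":
            parts.append("Axis=3, concatenate")
        elif op.kind == "dropout":
            parts.append(f"{op.rate}, Dropout")
    return "  ".join(parts)


def _walk_shapes(graph: LayerGraph):
    """Propagate (h, w, c) through every node; returns per-node details.

    Returns ``shapes`` mapping node id to a dict with ``out`` (shape after
    all ops), ``feat`` (shape before a trailing pool; the skip-visible
    tensor) and ``per_op`` (list of (op, in_shape, out_shape)).
    """
    shapes: dict[str, dict] = {}

    def feat_shape(nid: str):
        return shapes[nid]["feat"]

    for nid in graph.topo_order():
        node = graph.nodes[nid]
        src = graph.main_input(nid)
        if src is None:
            cur = (*graph.input_size, graph.input_channels)
        else:
            cur = shapes[src]["out"]
        per_op = []
        last_non_pool = cur
        for op in node.ops:
            inp = cur
            if op.kind == "conv":
                cur = (inp[0], inp[1], op.channels_out)
            elif op.kind == "pool":
                if inp[0] % op.factor or inp[1] % op.factor:
                    raise ShapeError(f"{nid}: cannot pool odd size {inp[:2]}")
                cur = (inp[0] // op.factor, inp[1] // op.factor, inp[2])
            elif op.kind == "upsample":
                cur = (inp[0] * op.factor, inp[1] * op.factor, inp[2])
            elif op.kind == "concat":
                # merge nodes concatenate only their sources; every other
                # node prepends its running tensor
                names = list(node.concat_sources)
                pieces = [feat_shape(s) for s in names]
                if node.role != "merge":
                    names = [nid] + names
                    pieces = [inp] + pieces
                if not pieces:
                    raise ShapeError(f"{nid}: concat without sources")
                for name, p in zip(names[1:], pieces[1:]):
                    if p[:2] != pieces[0][:2]:
                        raise ShapeError(
                            f"{nid}: concat spatial mismatch between {names[0]} "
                            f"{pieces[0][:2]} and {name} {p[:2]}")
                cur = (pieces[0][0], pieces[0][1], sum(p[2] for p in pieces))
            # batchnorm / activation / dropout keep the shape
            per_op.append((op, inp, cur))
            if op.kind != "pool":
                last_non_pool = cur
        shapes[nid] = {"out": cur, "feat": last_non_pool, "per_op": per_op}
    return shapes


def infer_shapes(graph: LayerGraph) -> ShapeTable:
    """One row per node: the resolution and channel count of its feature
    map (before any trailing pool), mirroring the reference layer table."""
    shapes = _walk_shapes(graph)
    out_h = shapes[graph.output_id]["out"][:2]
    if out_h != graph.input_size:
        raise ShapeError(
            f"output resolution {out_h} differs from input {graph.input_size}")
    rows = []
    for nid in graph.nodes:
        if graph.nodes[nid].role == "split":
            continue
        h, w, c = shapes[nid]["feat"]
        rows.append(ShapeRow(nid, (h, w), c))
    return ShapeTable(rows=rows, base_filters=graph.base_filters)


# ---------------------------------------------------------------------------
# counts and small utilities


def count_layer_blocks(spec: ArchitectureSpec | str) -> int:
    """Number of indexed layer blocks along the longest root-to-output
    chain (per branch for parallel groups), excluding the output head.

    Cascade joints between consecutive single-branch structures share one
    peak block and are counted once, matching the Lay1–Lay13 labeling of
    the two-U reference cascade.
    """
    if isinstance(spec, str):
        spec = parse_architecture(spec)
    total = 0
    prev_shareable = False  # previous segment single-branch, terminal an up block
    for group in spec.segments:
        total += max(b.block_count for b in group.branches)
        single = len(group.branches) == 1
        if prev_shareable and single and group.branches[0].down_depth >= 2:
            total -= 1  # shared peak block
        prev_shareable = single and group.branches[0].up_depth >= 2
    return total


def dilated_kernel_extent(kernel: int, rate: int) -> int:
    """Effective receptive extent (one side) of a dilated convolution:
    ``kernel + (kernel − 1)·(rate − 1)``.  A 3×3 kernel at rate 2 covers
    5×5; rate 1 leaves the extent unchanged."""
    if kernel < 1 or rate < 1:
        raise ValueError(f"kernel and rate must be positive, got ({kernel}, {rate})")
    return kernel + (kernel - 1) * (rate - 1)


def build_baseline_unet(depth: int, input_size=(128, 128), base_filters: int = 64,
                        **kwargs) -> LayerGraph:
    """The plain U-Net of the given depth — by definition the single-segment
    cascade ``U_1(d-d)``; one code path with :func:`build_layer_graph`."""
    if depth < 1:
        raise SpecValidationError(f"depth must be >= 1, got {depth}")
    return build_layer_graph(f"U_1({depth}-{depth})", input_size, base_filters, **kwargs)


def build_dilated_unet(depth: int, dilated_levels: int, input_size=(128, 128),
                       base_filters: int = 64, **kwargs) -> LayerGraph:
    """Baseline U-Net whose top ``dilated_levels`` contracting layers use
    rate-2 dilated 3×3 convolutions (the 'Dilated UNet(L*)' comparison)."""
    if not 1 <= dilated_levels <= depth:
        raise ValueError(
            f"dilated_levels must lie in [1, {depth}], got {dilated_levels}")
    g = build_baseline_unet(depth, input_size, base_filters, **kwargs)
    g.meta["dilated_levels"] = dilated_levels
    for node in g.nodes.values():
        if node.role in ("input_down", "down", "valley") and node.elevation > -dilated_levels:
            node.ops = [
                replace(op, dilation=2)
                if op.kind == "conv" and op.kernel == (3, 3) else op
                for op in node.ops
            ]
    return g


def graphs_isomorphic(g1: LayerGraph, g2: LayerGraph) -> bool:
    """Structural isomorphism: matching roles, elevations, op schedules and
    edge kinds (node ids are allowed to differ)."""
    import networkx as nx

    def to_nx(g: LayerGraph) -> "nx.DiGraph":
        ng = nx.DiGraph()
        for n in g.nodes.values():
            ng.add_node(n.id, role=n.role, elevation=n.elevation,
                        sig=tuple(op.signature() for op in n.ops))
        for src, dst, kind in g.edges:
            ng.add_edge(src, dst, kind=kind)
        return ng

    nm = nx.algorithms.isomorphism.categorical_node_match(
        ["role", "elevation", "sig"], [None, None, None])
    em = nx.algorithms.isomorphism.categorical_edge_match("kind", None)
    return nx.is_isomorphic(to_nx(g1), to_nx(g2), node_match=nm, edge_match=em)


def analytic_parameter_count(graph: LayerGraph) -> int:
    """Trainable parameter count derived from the graph alone: each conv
    contributes ``kh·kw·c_in·c_out + c_out`` and each batch-norm ``2·c``."""
    shapes = _walk_shapes(graph)
    total = 0
    for nid, node in graph.nodes.items():
        for op, inp, out in shapes[nid]["per_op"]:
            if op.kind == "conv":
                kh, kw = op.kernel
                total += kh * kw * inp[2] * op.channels_out + op.channels_out
            elif op.kind == "batchnorm":
                total += 2 * inp[2]
    return total
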