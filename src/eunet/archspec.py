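"""Parsing, validation and formatting of the EUNet architecture notation.

The notation describes a cascade of parallel-branch groups of U-shaped
structures::

    spec  := group ('-' group)*
    group := uterm ('//' uterm)*
    uterm := 'U' label? '(' int ('-' int)? ')'

``U_1(4-4)-U_2(4-4)`` is the single-high-peak (SHP) horizontal EUNet:
two cascaded symmetric U structures with four levels each.
``U_1(4)//U^1(4)`` is the double-branch spatial EUNet (U*UNet): two
parallel four-level U structures split at the input and fused at the
valleys and the output layers.  A single integer inside parentheses is
shorthand for a symmetric structure, ``U(4)`` == ``U(4-4)``.

Elevation bookkeeping uses the convention that the input layer sits at
elevation 0 and each pooling step descends one level (elevation −1, −2,
...).  A structure ``U(d-u)`` descends ``d−1`` levels to its valley and
ascends ``u−1`` levels, so the cascade elevation after a segment is
``previous − d + u``.  A valid architecture ends at elevation 0 (the
output layer is at input height) and never rises above it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import NotationParseError, SpecValidationError

__all__ = [
    "UStructureSpec",
    "BranchGroup",
    "ArchitectureSpec",
    "parse_architecture",
    "format_architecture",
    "random_valid_spec",
    "VARIANT_ALIASES",
    "variant_notation",
]


@dataclass(frozen=True)
class UStructureSpec:
    """One U-shaped contract–expand structure, ``U(d-u)``.

    ``down_depth`` counts descending levels including the valley;
    ``up_depth`` counts ascending levels including the terminal layer.
    High-peak structures have ``d == u``; low-peak and raised transitions
    differ by exactly one level.
    """

    label: str
    down_depth: int
    up_depth: int

    def __post_init__(self):
        if self.down_depth < 1 or self.up_depth < 1:
            raise SpecValidationError(
                f"{self.label or 'U'}: depths must be >= 1, got "
                f"({self.down_depth}-{self.up_depth})"
            )
        if abs(self.down_depth - self.up_depth) > 1:
            raise SpecValidationError(
                f"{self.label or 'U'}: |down_depth - up_depth| must be <= 1, got "
                f"({self.down_depth}-{self.up_depth})"
            )

    @property
    def elevation_delta(self) -> int:
        """Net elevation change contributed by this structure."""
        return self.up_depth - self.down_depth

    @property
    def block_count(self) -> int:
        """Number of indexed layer blocks spanned by this structure alone."""
        return self.down_depth + self.up_depth - 1


@dataclass(frozen=True)
class BranchGroup:
    """An ordered set of U structures running in parallel (``//``)."""

    branches: tuple[UStructureSpec, ...]

    def __post_init__(self):
        if len(self.branches) < 1:
            raise SpecValidationError("a branch group needs at least one branch")
        deltas = {b.elevation_delta for b in self.branches}
        if len(deltas) > 1:
            raise SpecValidationError(
                "parallel branches must share the same net elevation change; got "
                + ", ".join(f"({b.down_depth}-{b.up_depth})" for b in self.branches)
            )

    @property
    def elevation_delta(self) -> int:
        return self.branches[0].elevation_delta

    @property
    def is_parallel(self) -> bool:
        return len(self.branches) > 1

    @property
    def homogeneous(self) -> bool:
        shapes = {(b.down_depth, b.up_depth) for b in self.branches}
        return len(shapes) == 1


@dataclass(frozen=True)
class ArchitectureSpec:
    """A validated cascade of branch groups.

    ``peak_elevations`` holds the cumulative elevation after each segment;
    the final entry must be 0 (output at input height) and no entry may be
    positive (nothing rises above the input layer).
    """

    segments: tuple[BranchGroup, ...]
    input_elevation: int = field(default=0)

    def __post_init__(self):
        if len(self.segments) < 1:
            raise SpecValidationError("an architecture needs at least one segment")
        elevations = self.peak_elevations
        for i, e in enumerate(elevations):
            if e > 0:
                raise SpecValidationError(
                    f"segment {i + 1} ends above input height (elevation {e})"
                )
        if elevations[-1] != 0:
            raise SpecValidationError(
                f"output not at input height (final elevation {elevations[-1]})"
            )

    @property
    def peak_elevations(self) -> tuple[int, ...]:
        out, e = [], self.input_elevation
        for g in self.segments:
            e += g.elevation_delta
            out.append(e)
        return tuple(out)

    @property
    def max_depth_below_input(self) -> int:
        """Deepest level reached, as a positive number of pooling steps."""
        deepest = 0
        e = self.input_elevation
        for g in self.segments:
            for b in g.branches:
                deepest = max(deepest, (b.down_depth - 1) - e)
            e += g.elevation_delta
        return deepest

    def __str__(self) -> str:  # pragma: no cover - convenience
        return format_architecture(self)


_UTERM_RE = re.compile(
    r"U(?P<label>(?:[_^][A-Za-z0-9]*)+)?"
    r"\((?P<d>\d+)(?:-(?P<u>\d+))?\)"
)


def _clean_label(raw: str | None) -> str | None:
    if raw is None:
        return None
    cleaned = raw.rstrip("_^")
    return cleaned or None


def _canonical_label(segment_index: int, branch_index: int) -> str:
    """Labels follow the figure convention: U_1, U^1, U^11 for the branches
    of segment 1; U_2, U^2 for segment 2, etc."""
    if branch_index == 0:
        return f"_{segment_index}"
    return "^" + str(segment_index) * branch_index


def parse_architecture(
    notation: str,
    *,
    allow_heterogeneous_branches: bool = False,
) -> ArchitectureSpec:
    """Parse a notation string such as ``"U_1(4-4)-U_2(4-4)"``.

    Whitespace and trailing subscript/superscript decorations are ignored;
    a single integer ``U(4)`` is normalized to the symmetric pair ``(4-4)``.
    Missing labels are assigned canonically.  Raises
    :class:`~eunet.errors.NotationParseError` on grammar violations and
    :class:`~eunet.errors.SpecValidationError` on inconsistent elevations
    or depths.
    """
    if not isinstance(notation, str):
        raise NotationParseError(f"notation must be a string, got {type(notation).__name__}")
    text = re.sub(r"\s+", "", notation)
    if not text:
        raise NotationParseError("empty notation string")

    pos = 0
    groups: list[list[UStructureSpec]] = [[]]
    expecting_term = True
    while pos < len(text):
        if expecting_term:
            m = _UTERM_RE.match(text, pos)
            if m is None:
                raise NotationParseError(
                    "expected a U term like 'U_1(4-4)'", position=pos,
                    token=text[pos:pos + 12],
                )
            d = int(m.group("d"))
            u = int(m.group("u")) if m.group("u") is not None else d
            groups[-1].append(
                UStructureSpec(label=_clean_label(m.group("label")) or "", down_depth=d, up_depth=u)
            )
            pos = m.end()
            expecting_term = False
        elif text.startswith("//", pos):
            pos += 2
            expecting_term = True
        elif text[pos] == "-":
            groups.append([])
            pos += 1
            expecting_term = True
        else:
            raise NotationParseError(
                "expected '-' (cascade) or '//' (parallel)", position=pos, token=text[pos],
            )
    if expecting_term:
        raise NotationParseError("notation ends with a dangling operator", position=pos, token="<end>")

    segments = []
    for si, branch_list in enumerate(groups, start=1):
        labeled = []
        for bi, b in enumerate(branch_list):
            label = b.label or _canonical_label(si, bi)
            labeled.append(UStructureSpec(label=label, down_depth=b.down_depth, up_depth=b.up_depth))
        group = BranchGroup(branches=tuple(labeled))
        if group.is_parallel and not group.homogeneous and not allow_heterogeneous_branches:
            raise SpecValidationError(
                f"segment {si}: parallel branches differ in depth "
                "(pass allow_heterogeneous_branches=True to permit this)"
            )
        segments.append(group)
    return ArchitectureSpec(segments=tuple(segments))


def format_architecture(spec: ArchitectureSpec) -> str:
    """Canonical string form; ``parse_architecture`` round-trips it.

    Single-branch groups use the explicit pair form ``U_1(4-4)``; parallel
    branches use the single-number shorthand when symmetric, matching the
    figure captions (``U_1(4)//U^1(4)``).
    """
    parts = []
    for g in spec.segments:
        terms = []
        for b in g.branches:
            if g.is_parallel and b.down_depth == b.up_depth:
                depth = str(b.down_depth)
            else:
                depth = f"{b.down_depth}-{b.up_depth}"
            terms.append(f"U{b.label}({depth})")
        parts.append("//".join(terms))
    return "-".join(parts)


def random_valid_spec(
    rng,
    *,
    max_segments: int = 4,
    max_branches: int = 3,
    depth_range: tuple[int, int] = (1, 6),
) -> ArchitectureSpec:
    """Draw a random valid architecture (for property tests and fuzzing).

    Segment elevation deltas form a non-positive excursion returning to 0,
    so every draw satisfies the elevation invariants by construction.
    """
    n_seg = int(rng.integers(1, max_segments + 1))
    lo, hi = depth_range
    # Random walk of per-segment deltas in {-1, 0, +1}: prefix sums <= 0, total 0.
    while True:
        deltas = rng.integers(-1, 2, size=n_seg)
        c = deltas.cumsum()
        if c[-1] == 0 and (c <= 0).all():
            break
    segments = []
    for si, delta in enumerate(deltas, start=1):
        n_br = int(rng.integers(1, max_branches + 1))
        d = int(rng.integers(max(lo, 1 - min(0, delta)), hi + 1))
        u = d + int(delta)
        branches = tuple(
            UStructureSpec(label=_canonical_label(si, bi), down_depth=d, up_depth=u)
            for bi in range(n_br)
        )
        segments.append(BranchGroup(branches=branches))
    return ArchitectureSpec(segments=tuple(segments))


#: Named variants used in the benchmark tables; depth d is configurable
#: (4 for the 128x128 microscopy protocol, 5 for the 584x565 retina protocol).
VARIANT_ALIASES = {
    "unet": lambda d: f"U_1({d}-{d})",
    "shp": lambda d: "-".join(f"U_{i}({d}-{d})" for i in (1, 2)),
    "slp": lambda d: f"U_1({d}-{d - 1})-U_2({d - 1}-{d})",
    "dhp": lambda d: "-".join(f"U_{i}({d}-{d})" for i in (1, 2, 3)),
    "thp": lambda d: "-".join(f"U_{i}({d}-{d})" for i in (1, 2, 3, 4)),
    "u*unet": lambda d: f"U_1({d})//U^1({d})",
    "u*u*unet": lambda d: f"U_1({d})//U^1({d})//U^11({d})",
}


def variant_notation(name: str, depth: int = 4) -> str:
    """Resolve a named variant (``"SHP"``, ``"U*UNet"`` ...) to notation.

    Strings that are not aliases are returned unchanged, so callers can
    accept either form.
    """
    key = name.strip().lower().replace(" ", "")
    key = key.replace("-horizontal", "").replace("horizontal", "")
    key = key.replace("-eunet", "").replace("eunet", "") or "eunet"
    key = {"sp": "shp", "dp": "dhp", "tp": "thp", "slp": "slp"}.get(key, key)
    if key in VARIANT_ALIASES:
        return VARIANT_ALIASES[key](depth)
    return name
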