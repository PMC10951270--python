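"""Glycan tree data model.

N-glycan structures are handled as rooted, unordered trees of monosaccharide
classes (Hex, HexNAc, NeuAc, NeuGc, Fuc) with the reducing end at the root.
Linkage and anomericity are deliberately out of scope: two structures are the
same object whenever their topologies match, which is the resolution at which
HCD fragment spectra can distinguish glycans.

Structure strings use a nested-parenthesis grammar: each node is
``(X children...)`` where ``X`` is the one-letter code and the children are
concatenated, e.g. ``"(N(N(H(H)(H))))"`` is the trimannosyl chitobiose core.
Because children are unordered, :func:`serialize_canonical` picks one
representative string (children sorted lexicographically by their own
canonical serialization).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from pyteomics import mass as _pt_mass

__all__ = [
    "Monosaccharide",
    "GlycanComposition",
    "GlycanTree",
    "CoreAnnotation",
    "parse_glycan_struct",
    "serialize_canonical",
    "composition_of",
    "enumerate_isomers",
    "detect_core",
    "residue_mass",
    "read_glycan_database",
    "GlycanParseError",
]


class GlycanParseError(ValueError):
    """Raised for malformed structure strings or unknown residue codes."""


class Monosaccharide(Enum):
    """The five monosaccharide classes distinguished by the model."""

    Hex = "H"
    HexNAc = "N"
    NeuAc = "A"
    NeuGc = "G"
    Fuc = "F"

    @property
    def short_code(self) -> str:
        return self.value


# Residue (dehydrated) elemental formulas; masses computed monoisotopically.
_RESIDUE_FORMULA = {
    Monosaccharide.Hex: "C6H10O5",
    Monosaccharide.HexNAc: "C8H13NO5",
    Monosaccharide.NeuAc: "C11H17NO8",
    Monosaccharide.NeuGc: "C11H17NO9",
    Monosaccharide.Fuc: "C6H10O4",
}

_RESIDUE_MASS = {
    m: _pt_mass.calculate_mass(formula=f) for m, f in _RESIDUE_FORMULA.items()
}

_CODE_TO_MONO = {m.value: m for m in Monosaccharide}

# Rendering order for compositions: H(x)N(y)F(z) style with sialic acids last.
_COMPOSITION_ORDER = ("H", "N", "F", "A", "G")


def residue_mass(m: Monosaccharide) -> float:
    """Monoisotopic residue mass in Da (the mass added upon glycosidic bond)."""
    return _RESIDUE_MASS[m]


@dataclass(frozen=True)
class GlycanComposition:
    """Multiset of monosaccharide classes, keyed by one-letter code."""

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "GlycanComposition":
        items = tuple(
            (code, int(d[code]))
            for code in _COMPOSITION_ORDER
            if d.get(code, 0) > 0
        )
        return cls(items)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def total(self) -> int:
        return sum(n for _, n in self.counts)

    def mass(self) -> float:
        return sum(
            residue_mass(_CODE_TO_MONO[code]) * n for code, n in self.counts
        )

    def __str__(self) -> str:
        return "".join(f"{code}({n})" for code, n in self.counts)

    def __len__(self) -> int:
        return self.total


@dataclass
class GlycanTree:
    """Rooted unordered tree; node 0 is the reducing end.

    ``codes[i]`` is the one-letter monosaccharide code of node ``i``;
    ``parent[i]`` is the parent id (-1 for the root); ``children[i]`` lists
    child ids in parse order (order carries no meaning).
    """

    codes: list[str]
    parent: list[int]
    children: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.children:
            self.children = [[] for _ in self.codes]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    self.children[p].append(i)
        if self.parent[0] != -1:
            raise ValueError("node 0 must be the root")

    @property
    def n_nodes(self) -> int:
        return len(self.codes)

    @property
    def root(self) -> int:
        return 0

    def monosaccharide(self, node: int) -> Monosaccharide:
        return _CODE_TO_MONO[self.codes[node]]

    def edges(self) -> list[tuple[int, int]]:
        return [(p, i) for i, p in enumerate(self.parent) if p >= 0]

    def subtree_nodes(self, node: int) -> list[int]:
        out = [node]
        stack = list(self.children[node])
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return sorted(out)

    def depth(self, node: int) -> int:
        d = 0
        while self.parent[node] >= 0:
            node = self.parent[node]
            d += 1
        return d

    def mass(self) -> float:
        return sum(residue_mass(_CODE_TO_MONO[c]) for c in self.codes)

    def composition(self) -> GlycanComposition:
        return composition_of(self, range(self.n_nodes))

    def canonical(self) -> str:
        return serialize_canonical(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GlycanTree):
            return NotImplemented
        return serialize_canonical(self) == serialize_canonical(other)

    def __hash__(self) -> int:
        return hash(serialize_canonical(self))

    def __repr__(self) -> str:
        return f"GlycanTree({serialize_canonical(self)!r})"


def parse_glycan_struct(text: str) -> GlycanTree:
    """Parse a nested-parenthesis structure string into a :class:`GlycanTree`."""
    text = text.strip()
    if not text:
        raise GlycanParseError("empty structure string")
    codes: list[str] = []
    parent: list[int] = []
    stack: list[int] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "(":
            i += 1
            if i >= n:
                raise GlycanParseError(f"dangling '(' in {text!r}")
            code = text[i]
            if code not in _CODE_TO_MONO:
                raise GlycanParseError(
                    f"unknown monosaccharide code {code!r} in {text!r}"
                )
            node = len(codes)
            codes.append(code)
            parent.append(stack[-1] if stack else -1)
            if parent[node] == -1 and node != 0:
                raise GlycanParseError(f"multiple roots in {text!r}")
            stack.append(node)
            i += 1
        elif ch == ")":
            if not stack:
                raise GlycanParseError(f"unbalanced ')' in {text!r}")
            stack.pop()
            i += 1
            if not stack and i < n:
                raise GlycanParseError(f"trailing text after root in {text!r}")
        else:
            raise GlycanParseError(f"unexpected character {ch!r} in {text!r}")
    if stack:
        raise GlycanParseError(f"unbalanced '(' in {text!r}")
    if not codes:
        raise GlycanParseError(f"no nodes in {text!r}")
    return GlycanTree(codes=codes, parent=parent)


def _canonical_subtree(tree: GlycanTree, node: int) -> str:
    parts = sorted(_canonical_subtree(tree, c) for c in tree.children[node])
    return "(" + tree.codes[node] + "".join(parts) + ")"


def serialize_canonical(tree: GlycanTree) -> str:
    """Canonical structure string: one representative per unordered tree."""
    return _canonical_subtree(tree, tree.root)


def composition_of(tree: GlycanTree, nodes: Iterable[int]) -> GlycanComposition:
    """Monosaccharide composition of a node subset (empty subset allowed)."""
    counts: dict[str, int] = {}
    for v in nodes:
        c = tree.codes[v]
        counts[c] = counts.get(c, 0) + 1
    return GlycanComposition.from_dict(counts)


def enumerate_isomers(
    comp: GlycanComposition, space: Sequence[GlycanTree]
) -> list[GlycanTree]:
    """All structures in ``space`` with composition ``comp``, deduplicated.

    Deduplication is by canonical string; output ordered by canonical string
    for determinism.
    """
    seen: dict[str, GlycanTree] = {}
    for t in space:
        if t.composition() == comp:
            seen.setdefault(serialize_canonical(t), t)
    return [seen[k] for k in sorted(seen)]


class GlycanClass(Enum):
    high_mannose = "high_mannose"
    complex = "complex"
    hybrid = "hybrid"
    other = "other"


@dataclass(frozen=True)
class CoreAnnotation:
    """N-glycan core assignment and derived structural flags."""

    core_node_ids: frozenset[int]
    branch_roots: frozenset[int]
    core_fucose: bool
    bisecting: bool
    glycan_class: GlycanClass
    # arm mannoses (subset of core) -> their child branch roots
    arm_mannoses: tuple[int, ...] = ()

    @property
    def is_canonical(self) -> bool:
        return self.glycan_class is not GlycanClass.other


_EMPTY_ANNOTATION = CoreAnnotation(
    frozenset(), frozenset(), False, False, GlycanClass.other
)


def detect_core(tree: GlycanTree) -> CoreAnnotation:
    """Identify the chitobiose/trimannosyl core and classify the glycan.

    The core is the reducing-end HexNAc, its HexNAc child, the branching
    mannose (Hex) and the arm mannoses attached to it.  Fuc on either core
    HexNAc marks core fucosylation; HexNAc on the branching mannose marks a
    bisecting HexNAc.  Trees lacking the HexNAc-HexNAc-Hex prefix classify as
    ``other`` with an empty annotation rather than raising.
    """
    if tree.codes[tree.root] != "N":
        return _EMPTY_ANNOTATION
    root = tree.root
    # canonical choice when several HexNAc children exist
    n_children = sorted(
        (c for c in tree.children[root] if tree.codes[c] == "N"),
        key=lambda c: _canonical_subtree(tree, c),
    )
    if not n_children:
        return _EMPTY_ANNOTATION
    core_n2 = n_children[0]
    h_children = sorted(
        (c for c in tree.children[core_n2] if tree.codes[c] == "H"),
        key=lambda c: _canonical_subtree(tree, c),
    )
    if not h_children:
        return _EMPTY_ANNOTATION
    beta_man = h_children[0]

    core = {root, core_n2, beta_man}
    core_fucose = any(
        tree.codes[c] == "F"
        for node in (root, core_n2)
        for c in tree.children[node]
    )
    bisecting = any(tree.codes[c] == "N" for c in tree.children[beta_man])
    arm_mannoses = tuple(
        sorted(c for c in tree.children[beta_man] if tree.codes[c] == "H")
    )
    core.update(arm_mannoses)
    branch_roots: set[int] = set()
    arm_kinds: list[str] = []  # "empty" | "hex" | "antenna" per arm
    for arm in arm_mannoses:
        kids = tree.children[arm]
        branch_roots.update(kids)
        nodes_below = [v for k in kids for v in tree.subtree_nodes(k)]
        if not nodes_below:
            arm_kinds.append("empty")
        elif all(tree.codes[v] == "H" for v in nodes_below):
            arm_kinds.append("hex")
        else:
            arm_kinds.append("antenna")

    if "antenna" not in arm_kinds:
        cls = GlycanClass.high_mannose
    elif "hex" in arm_kinds:
        cls = GlycanClass.hybrid
    else:
        cls = GlycanClass.complex
    return CoreAnnotation(
        core_node_ids=frozenset(core),
        branch_roots=frozenset(branch_roots),
        core_fucose=core_fucose,
        bisecting=bisecting,
        glycan_class=cls,
        arm_mannoses=arm_mannoses,
    )


def read_glycan_database(path: str) -> list[GlycanTree]:
    """Read a glycan-structure database: one structure per line, '#' comments."""
    out: list[GlycanTree] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(parse_glycan_struct(line))
    return out
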