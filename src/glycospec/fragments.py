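"""Theoretical fragment enumeration for intact glycopeptides under HCD.

Three fragment families are produced:

* peptide backbone b/y ions (charges 1-2), including glycan-bearing variants
  of fragments that contain the glycosite: b/y + one HexNAc (``bN1``/``yN1``)
  and b/y + a cross-ring remnant of the reducing-end HexNAc (``bX``/``yX``);
* glycan Y ions (charges 1-3): the peptide retaining a root-containing
  connected part of the glycan after one or more glycosidic cleavages,
  down to the naked peptide Y0;
* glycan B (oxonium-type) ions (charge 1): branch fragments that do not
  contain the peptide, enumerated for complex/hybrid glycans only.

Structure-specific fragments that share a monosaccharide composition are not
distinguishable by mass; they are merged into composition fragments, and the
cleavage -> structure fragment -> composition fragment relation is exposed as
a tripartite fragmentation graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
from pyteomics import mass as _pt_mass

from .glycans import (
    CoreAnnotation,
    GlycanComposition,
    GlycanTree,
    composition_of,
    detect_core,
    serialize_canonical,
)
from .peptides import PROTON_MASS, PeptideSequence

__all__ = [
    "GlycopeptidePrecursor",
    "CleavageSite",
    "StructureFragment",
    "FragmentIon",
    "enumerate_cleavages",
    "enumerate_Y_fragments",
    "enumerate_B_fragments",
    "merge_isomeric_fragments",
    "build_fragmentation_graph",
    "peptide_fragments",
    "FragmentIndex",
    "CROSS_RING_MASS",
    "HEXNAC_MASS",
]

# Cross-ring remnant retained on the peptide after 0,2-ring cleavage of the
# reducing-end HexNAc (C4H5NO), the prevailing convention in glycoproteomics
# search engines.
CROSS_RING_MASS = _pt_mass.calculate_mass(formula="C4H5NO")
HEXNAC_MASS = _pt_mass.calculate_mass(formula="C8H13NO5")

Y_CHARGES = (1, 2, 3)
PEPTIDE_CHARGES = (1, 2)


@dataclass(frozen=True)
class GlycopeptidePrecursor:
    """A glycopeptide precursor: peptide + glycan structure + charge."""

    peptide: PeptideSequence
    glycan: GlycanTree
    charge: int

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("precursor charge must be >= 1")

    def neutral_mass(self) -> float:
        return self.peptide.neutral_mass() + self.glycan.mass()

    def mz(self) -> float:
        return (self.neutral_mass() + self.charge * PROTON_MASS) / self.charge

    def key(self) -> tuple[str, int, str, int]:
        return (
            self.peptide.modified_string(),
            self.peptide.glycosite,
            serialize_canonical(self.glycan),
            self.charge,
        )


@dataclass(frozen=True)
class CleavageSite:
    """A glycosidic cleavage splitting the tree into lost and retained nodes.

    ``root_attachment`` is the cleavage between the reducing-end HexNAc and
    the peptide, whose Y product is the naked peptide Y0.
    """

    kind: str  # "edge" | "root_attachment"
    edge: tuple[int, int] | None
    lost_ids: frozenset[int]
    retained_ids: frozenset[int]


@dataclass(frozen=True)
class StructureFragment:
    ion_class: str  # "Y" | "B"
    retained_ids: frozenset[int]
    cleavages: tuple[CleavageSite, ...]
    composition: GlycanComposition


@dataclass(frozen=True)
class FragmentIon:
    """A theoretical ion with m/z, ready for peak matching or export."""

    series: str  # b, y, bN1, yN1, bX, yX, Y, B
    ordinal: int | None  # backbone cleavage ordinal for peptide series
    composition: GlycanComposition | None  # for Y/B series
    charge: int
    mz: float


def enumerate_cleavages(tree: GlycanTree) -> list[CleavageSite]:
    """One cleavage per tree edge plus the root-attachment cleavage."""
    all_nodes = frozenset(range(tree.n_nodes))
    sites = [
        CleavageSite(
            kind="root_attachment",
            edge=None,
            lost_ids=all_nodes,
            retained_ids=frozenset(),
        )
    ]
    for p, c in tree.edges():
        lost = frozenset(tree.subtree_nodes(c))
        sites.append(
            CleavageSite(
                kind="edge",
                edge=(p, c),
                lost_ids=lost,
                retained_ids=all_nodes - lost,
            )
        )
    return sites


def _cleavage_by_edge(
    sites: Iterable[CleavageSite],
) -> dict[tuple[int, int] | None, CleavageSite]:
    return {s.edge: s for s in sites}


def _retained_variants(tree: GlycanTree, v: int) -> list[frozenset[int]]:
    """All retained node sets within subtree(v) that contain v."""
    opts: list[frozenset[int]] = [frozenset([v])]
    for c in tree.children[v]:
        child_opts = _retained_variants(tree, c)
        child_opts.append(frozenset())  # cut the child subtree entirely
        opts = [o | co for o in opts for co in child_opts]
    return opts


def boundary_cleavages(
    tree: GlycanTree,
    retained: frozenset[int],
    sites: Sequence[CleavageSite] | None = None,
) -> tuple[CleavageSite, ...]:
    """Cleavages whose edge crosses the retained/lost boundary.

    The empty retained set maps to the root-attachment cleavage.  Cleavages
    are returned in a canonical order: ascending by (depth of the cleaved
    edge, canonical serialization of the lost subtree).
    """
    if sites is None:
        sites = enumerate_cleavages(tree)
    by_edge = _cleavage_by_edge(sites)
    if not retained:
        return (by_edge[None],)
    crossing = [
        by_edge[(p, c)]
        for p, c in tree.edges()
        if (p in retained) != (c in retained)
    ]
    crossing.sort(key=lambda s: _cleavage_sort_key(tree, s))
    return tuple(crossing)


def _cleavage_sort_key(tree: GlycanTree, site: CleavageSite):
    if site.edge is None:
        return (-1, "")
    p, c = site.edge
    from .glycans import _canonical_subtree  # canonical lost-subtree string

    return (tree.depth(c), _canonical_subtree(tree, c))


def enumerate_Y_fragments(tree: GlycanTree) -> list[StructureFragment]:
    """All Y structure fragments: root-containing connected proper subsets.

    The intact glycan (no cleavage) is excluded; the empty fragment Y0 is
    included via the root-attachment cleavage.
    """
    sites = enumerate_cleavages(tree)
    all_nodes = frozenset(range(tree.n_nodes))
    frags: list[StructureFragment] = []
    for retained in _retained_variants(tree, tree.root):
        if retained == all_nodes:
            continue  # a fragment requires at least one cleavage
        frags.append(
            StructureFragment(
                ion_class="Y",
                retained_ids=retained,
                cleavages=boundary_cleavages(tree, retained, sites),
                composition=composition_of(tree, retained),
            )
        )
    frags.append(
        StructureFragment(
            ion_class="Y",
            retained_ids=frozenset(),
            cleavages=boundary_cleavages(tree, frozenset(), sites),
            composition=GlycanComposition(()),
        )
    )
    frags.sort(key=lambda f: (len(f.retained_ids), sorted(f.retained_ids)))
    return frags


def enumerate_B_fragments(
    tree: GlycanTree, core: CoreAnnotation | None = None
) -> list[StructureFragment]:
    """Branch (oxonium-type) B fragments for complex/hybrid glycans.

    For each non-oligomannose branch hanging off an arm mannose: the complete
    subtree rooted at every branch node, and each such subtree together with
    the adjacent arm mannose.  Oligomannose (all-Hex) branches are excluded,
    so high-mannose glycans yield no B fragments.  Deduplicated by retained
    node set.
    """
    if core is None:
        core = detect_core(tree)
    if not core.is_canonical:
        return []
    sites = enumerate_cleavages(tree)
    seen: dict[frozenset[int], StructureFragment] = {}
    for arm in core.arm_mannoses:
        for branch_root in tree.children[arm]:
            branch_nodes = tree.subtree_nodes(branch_root)
            if all(tree.codes[v] == "H" for v in branch_nodes):
                continue  # oligomannose branch
            for v in branch_nodes:
                sub = frozenset(tree.subtree_nodes(v))
                for retained in (sub, sub | {arm}):
                    if retained not in seen:
                        seen[retained] = StructureFragment(
                            ion_class="B",
                            retained_ids=retained,
                            cleavages=boundary_cleavages(tree, retained, sites),
                            composition=composition_of(tree, retained),
                        )
    frags = list(seen.values())
    frags.sort(key=lambda f: (len(f.retained_ids), sorted(f.retained_ids)))
    return frags


def merge_isomeric_fragments(
    frags: Sequence[StructureFragment],
) -> list[tuple[GlycanComposition, list[StructureFragment]]]:
    """Group structure fragments by monosaccharide composition.

    All inputs must share one ion class; every fragment lands in exactly one
    group.  Groups are ordered by (size, composition string).
    """
    classes = {f.ion_class for f in frags}
    if len(classes) > 1:
        raise ValueError("cannot merge fragments of mixed ion classes")
    groups: dict[str, list[StructureFragment]] = {}
    comp_by_key: dict[str, GlycanComposition] = {}
    for f in frags:
        key = str(f.composition)
        groups.setdefault(key, []).append(f)
        comp_by_key[key] = f.composition
    keys = sorted(groups, key=lambda k: (comp_by_key[k].total, k))
    return [(comp_by_key[k], groups[k]) for k in keys]


def build_fragmentation_graph(tree: GlycanTree, with_B: bool = False) -> nx.DiGraph:
    """Tripartite graph: cleavages -> structure fragments -> compositions.

    Node keys: ``("cleavage", edge_or_None)``, ``("structure", ion_class,
    retained frozenset)``, ``("composition", ion_class, comp_string)``.
    Edge weights (attention / isomer proportions) can be attached later.
    """
    g = nx.DiGraph()
    sites = enumerate_cleavages(tree)
    for s in sites:
        g.add_node(("cleavage", s.edge), layer="cleavage", site=s)
    frag_sets = {"Y": enumerate_Y_fragments(tree)}
    if with_B:
        frag_sets["B"] = enumerate_B_fragments(tree)
    for ion_class, frags in frag_sets.items():
        for f in frags:
            skey = ("structure", ion_class, f.retained_ids)
            g.add_node(skey, layer="structure", fragment=f)
            for s in f.cleavages:
                g.add_edge(("cleavage", s.edge), skey)
        for comp, members in merge_isomeric_fragments(frags):
            ckey = ("composition", ion_class, str(comp))
            g.add_node(ckey, layer="composition", composition=comp)
            for m in members:
                g.add_edge(("structure", ion_class, m.retained_ids), ckey)
    return g


def _b_mz(pep: PeptideSequence, n: int, z: int, extra: float = 0.0) -> float:
    return (pep.prefix_mass(n) + extra + z * PROTON_MASS) / z


def _y_mz(pep: PeptideSequence, n: int, z: int, extra: float = 0.0) -> float:
    from .peptides import WATER_MASS

    return (pep.suffix_mass(n) + WATER_MASS + extra + z * PROTON_MASS) / z


def peptide_fragments(pep: PeptideSequence) -> list[FragmentIon]:
    """Theoretical peptide-backbone ions, charges 1-2.

    For each backbone cleavage ``i`` (1..L-1) the naked b_i / y_{L-i} ions are
    produced; the glycan-bearing variants (one HexNAc, cross-ring remnant)
    only on the side containing the glycosite.
    """
    L = len(pep)
    if L < 2:
        return []
    out: list[FragmentIon] = []
    site = pep.glycosite
    for i in range(1, L):
        b_has_site = site < i
        for z in PEPTIDE_CHARGES:
            out.append(FragmentIon("b", i, None, z, _b_mz(pep, i, z)))
            out.append(FragmentIon("y", L - i, None, z, _y_mz(pep, L - i, z)))
            if b_has_site:
                out.append(
                    FragmentIon("bN1", i, None, z, _b_mz(pep, i, z, HEXNAC_MASS))
                )
                out.append(
                    FragmentIon("bX", i, None, z, _b_mz(pep, i, z, CROSS_RING_MASS))
                )
            else:
                out.append(
                    FragmentIon(
                        "yN1", L - i, None, z, _y_mz(pep, L - i, z, HEXNAC_MASS)
                    )
                )
                out.append(
                    FragmentIon(
                        "yX", L - i, None, z, _y_mz(pep, L - i, z, CROSS_RING_MASS)
                    )
                )
    return out


@dataclass
class FragmentIndex:
    """Theoretical fragment index of a precursor.

    Defines the fixed slot layout intensity vectors are aligned to:

    * peptide part: ``4*(L-1)`` slots ordered by backbone cleavage, then
      ``(b 1+, b 2+, y 1+, y 2+)``; glycan-bearing b/y variants share the slot
      of their naked ion (they collapse into the same predicted channel);
    * Y part: ``3 * n_Y_compositions`` slots, compositions ordered by
      (size, composition string), charges 1-3;
    * B part (optional): one slot per B composition, charge 1.
    """

    precursor: GlycopeptidePrecursor
    with_B: bool = False

    y_structures: list[StructureFragment] = field(init=False)
    y_groups: list[tuple[GlycanComposition, list[StructureFragment]]] = field(
        init=False
    )
    b_structures: list[StructureFragment] = field(init=False)
    b_groups: list[tuple[GlycanComposition, list[StructureFragment]]] = field(
        init=False
    )

    def __post_init__(self) -> None:
        tree = self.precursor.glycan
        self.y_structures = enumerate_Y_fragments(tree)
        self.y_groups = merge_isomeric_fragments(self.y_structures)
        if self.with_B:
            self.b_structures = enumerate_B_fragments(tree)
        else:
            self.b_structures = []
        self.b_groups = merge_isomeric_fragments(self.b_structures)

    # ---- sizes -----------------------------------------------------------
    @property
    def n_cleavages(self) -> int:
        return len(self.precursor.peptide) - 1

    @property
    def n_pep(self) -> int:
        return 4 * self.n_cleavages

    @property
    def n_y_comps(self) -> int:
        return len(self.y_groups)

    @property
    def n_y(self) -> int:
        return 3 * self.n_y_comps

    @property
    def n_b(self) -> int:
        return len(self.b_groups)

    @property
    def n_total(self) -> int:
        return self.n_pep + self.n_y + self.n_b

    # ---- slot addressing -------------------------------------------------
    def pep_slot(self, ordinal: int, series: str, charge: int) -> int:
        """Slot of a peptide ion; ``series`` is the naked family 'b' or 'y'."""
        offs = {"b": 0, "y": 2}[series] + (charge - 1)
        return 4 * (ordinal - 1) + offs

    def y_slot(self, comp_index: int, charge: int) -> int:
        return 3 * comp_index + (charge - 1)

    def y_comp_index(self) -> dict[str, int]:
        return {str(c): i for i, (c, _) in enumerate(self.y_groups)}

    def b_comp_index(self) -> dict[str, int]:
        return {str(c): i for i, (c, _) in enumerate(self.b_groups)}

    # ---- theoretical ions ------------------------------------------------
    def theoretical_ions(self) -> list[tuple[str, int, FragmentIon]]:
        """All matchable theoretical ions as (part, slot, ion).

        Peptide variants map to the slot of their naked b/y channel; the
        ordinal of a y-series ion is the y ordinal (L - cleavage).
        """
        pep = self.precursor.peptide
        rows: list[tuple[str, int, FragmentIon]] = []
        for ion in peptide_fragments(pep):
            series = "b" if ion.series.startswith("b") else "y"
            ordinal = ion.ordinal if series == "b" else len(pep) - ion.ordinal
            # ordinal here is the backbone cleavage index 1..L-1
            slot = self.pep_slot(ordinal, series, ion.charge)
            rows.append(("pep", slot, ion))
        pep_mass = pep.neutral_mass()
        for i, (comp, _members) in enumerate(self.y_groups):
            cm = comp.mass()
            for z in Y_CHARGES:
                mz = (pep_mass + cm + z * PROTON_MASS) / z
                rows.append(
                    ("Y", self.y_slot(i, z), FragmentIon("Y", None, comp, z, mz))
                )
        for i, (comp, _members) in enumerate(self.b_groups):
            mz = comp.mass() + PROTON_MASS
            rows.append(("B", i, FragmentIon("B", None, comp, 1, mz)))
        return rows
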