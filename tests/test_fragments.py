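"""Fragment enumeration, m/z computation and the fragmentation graph."""

import itertools

import numpy as np
import pytest
from pyteomics import mass as pt_mass

from glycospec.fragments import (
    CROSS_RING_MASS,
    FragmentIndex,
    GlycopeptidePrecursor,
    HEXNAC_MASS,
    build_fragmentation_graph,
    enumerate_B_fragments,
    enumerate_cleavages,
    enumerate_Y_fragments,
    merge_isomeric_fragments,
    peptide_fragments,
)
from glycospec.glycans import detect_core, parse_glycan_struct
from glycospec.peptides import PROTON_MASS, PeptideSequence

from conftest import random_tree


def brute_force_y_sets(tree):
    """Oracle: all connected, root-containing proper subsets by subset scan."""
    nodes = list(range(tree.n_nodes))
    out = set()
    for r in range(1, tree.n_nodes):
        for sub in itertools.combinations(nodes, r):
            s = set(sub)
            if tree.root not in s:
                continue
            if all(v == tree.root or tree.parent[v] in s for v in s):
                out.add(frozenset(s))
    return out


def closed_form_count(tree):
    def f(v):
        p = 1
        for c in tree.children[v]:
            p *= 1 + f(c)
        return p

    return f(tree.root) - 1


class TestCleavages:
    def test_core_has_five_sites(self, core_tree):
        sites = enumerate_cleavages(core_tree)
        assert len(sites) == 5
        assert sum(s.kind == "root_attachment" for s in sites) == 1

    def test_single_node(self):
        sites = enumerate_cleavages(parse_glycan_struct("(N)"))
        assert len(sites) == 1 and sites[0].kind == "root_attachment"

    def test_edge_count_plus_one(self):
        rng = np.random.default_rng(0)
        t = random_tree(rng, 8)
        assert len(enumerate_cleavages(t)) == 8

    def test_lost_retained_partition(self, core_tree):
        all_nodes = set(range(core_tree.n_nodes))
        for s in enumerate_cleavages(core_tree):
            assert set(s.lost_ids) | set(s.retained_ids) == all_nodes
            assert not set(s.lost_ids) & set(s.retained_ids)


class TestYFragments:
    def test_core_enumeration(self, core_tree):
        frags = enumerate_Y_fragments(core_tree)
        nonempty = [f for f in frags if f.retained_ids]
        assert len(nonempty) == 5 and len(frags) == 6
        comps = sorted(str(f.composition) for f in nonempty)
        assert comps == ["H(1)N(2)", "H(2)N(2)", "H(2)N(2)", "N(1)", "N(2)"]

    def test_single_node_only_y0(self):
        frags = enumerate_Y_fragments(parse_glycan_struct("(N)"))
        assert len(frags) == 1 and frags[0].retained_ids == frozenset()

    def test_linear_chain(self):
        frags = enumerate_Y_fragments(parse_glycan_struct("(N(N(H(H))))"))
        assert sum(1 for f in frags if f.retained_ids) == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_and_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        t = random_tree(rng, int(rng.integers(2, 13)))
        frags = enumerate_Y_fragments(t)
        sets = {f.retained_ids for f in frags if f.retained_ids}
        assert sets == brute_force_y_sets(t)
        assert len(sets) == closed_form_count(t)

    def test_boundary_cleavages_unique_and_crossing(self):
        rng = np.random.default_rng(42)
        t = random_tree(rng, 10)
        for f in enumerate_Y_fragments(t):
            if not f.retained_ids:
                assert [s.kind for s in f.cleavages] == ["root_attachment"]
                continue
            crossing = {
                (p, c)
                for p, c in t.edges()
                if (p in f.retained_ids) != (c in f.retained_ids)
            }
            assert {s.edge for s in f.cleavages} == crossing


class TestBFragments:
    def test_single_hexnac_branch(self):
        # core with one HexNAc antenna on an arm mannose
        t = parse_glycan_struct("(N(N(H(H(N))(H))))")
        frags = enumerate_B_fragments(t)
        comps = sorted(str(f.composition) for f in frags)
        assert comps == ["H(1)N(1)", "N(1)"]

    def test_hexnac_hex_branch(self):
        # antenna HexNAc-Hex: subtrees {H}, {N,H}; each also with the mannose
        t = parse_glycan_struct("(N(N(H(H(N(H)))(H))))")
        frags = enumerate_B_fragments(t)
        comps = sorted(str(f.composition) for f in frags)
        assert comps == ["H(1)", "H(1)N(1)", "H(2)", "H(2)N(1)"]

    def test_high_mannose_has_no_b_ions(self):
        t = parse_glycan_struct("(N(N(H(H(H)(H))(H(H)))))")
        assert enumerate_B_fragments(t) == []

    def test_hybrid_oligomannose_arm_excluded(self):
        t = parse_glycan_struct("(N(N(H(H(H))(H(N)))))")
        frags = enumerate_B_fragments(t)
        # only the HexNAc antenna contributes, never the mannose arm
        for f in frags:
            assert "N" in {t.codes[v] for v in f.retained_ids}

    def test_fragments_exclude_root_and_are_branch_connected(self):
        t = parse_glycan_struct("(N(F)(N(H(H(N(H))(N))(H(N)))))")
        core = detect_core(t)
        for f in enumerate_B_fragments(t, core):
            assert t.root not in f.retained_ids
            # connected once any attached arm mannose is contracted away
            rest = set(f.retained_ids) - set(core.arm_mannoses)
            roots = [v for v in rest if t.parent[v] not in rest]
            assert len(roots) == 1


class TestMergeIsomeric:
    def test_core_groups(self, core_tree):
        frags = enumerate_Y_fragments(core_tree)
        groups = merge_isomeric_fragments(frags)
        assert len(groups) == 5  # "", N1, N2, N2H1, N2H2(x2)
        sizes = {str(c): len(m) for c, m in groups}
        assert sizes["H(2)N(2)"] == 2
        assert sum(sizes.values()) == len(frags)

    def test_empty_composition_group(self, core_tree):
        frags = [f for f in enumerate_Y_fragments(core_tree) if not f.retained_ids]
        groups = merge_isomeric_fragments(frags)
        assert len(groups) == 1 and str(groups[0][0]) == ""

    def test_empty_input(self):
        assert merge_isomeric_fragments([]) == []

    def test_mixed_classes_rejected(self, core_tree):
        y = enumerate_Y_fragments(core_tree)
        b_tree = parse_glycan_struct("(N(N(H(H(N))(H))))")
        b = enumerate_B_fragments(b_tree)
        with pytest.raises(ValueError):
            merge_isomeric_fragments([y[0], b[0]])


class TestFragmentationGraph:
    def test_core_layer_sizes(self, core_tree):
        g = build_fragmentation_graph(core_tree, with_B=False)
        layers = {"cleavage": 0, "structure": 0, "composition": 0}
        for _n, d in g.nodes(data=True):
            layers[d["layer"]] += 1
        assert layers == {"cleavage": 5, "structure": 6, "composition": 5}

    def test_single_node(self):
        g = build_fragmentation_graph(parse_glycan_struct("(N)"))
        layers = [d["layer"] for _n, d in g.nodes(data=True)]
        assert sorted(layers) == ["cleavage", "composition", "structure"]

    def test_every_structure_connects(self):
        rng = np.random.default_rng(5)
        t = random_tree(rng, 9)
        g = build_fragmentation_graph(t)
        for node, d in g.nodes(data=True):
            if d["layer"] == "structure":
                assert g.in_degree(node) >= 1  # >=1 cleavage
                assert g.out_degree(node) == 1  # exactly 1 composition


class TestPeptideFragments:
    def test_y1_of_gly_gly(self):
        pep = PeptideSequence("GG", glycosite=0)
        ions = {(i.series, i.ordinal, i.charge): i.mz for i in peptide_fragments(pep)}
        assert ions[("y", 1, 1)] == pytest.approx(76.0393, abs=1e-4)

    def test_glycan_variants_follow_the_site(self):
        pep = PeptideSequence("GG", glycosite=0)
        series = {(i.series, i.ordinal) for i in peptide_fragments(pep)}
        assert ("bN1", 1) in series and ("bX", 1) in series
        assert ("yN1", 1) not in series and ("yX", 1) not in series

    def test_naked_ion_count(self):
        pep = PeptideSequence("LNSTAVK", glycosite=1)
        naked = [i for i in peptide_fragments(pep) if i.series in ("b", "y")]
        assert len(naked) == 2 * (len(pep) - 1) * 2

    def test_short_peptide_empty(self):
        assert peptide_fragments(PeptideSequence("G", glycosite=0)) == []

    def test_masses_against_pyteomics(self):
        pep = PeptideSequence("LNSTAVK", glycosite=1)
        ions = {(i.series, i.ordinal, i.charge): i.mz for i in peptide_fragments(pep)}
        for i in (1, 3, 6):
            for z in (1, 2):
                assert ions[("b", i, z)] == pytest.approx(
                    pt_mass.calculate_mass(
                        sequence="LNSTAVK"[:i], ion_type="b", charge=z
                    ),
                    abs=2e-3,
                )
                assert ions[("y", i, z)] == pytest.approx(
                    pt_mass.calculate_mass(
                        sequence="LNSTAVK"[-i:], ion_type="y", charge=z
                    ),
                    abs=2e-3,
                )


class TestFragmentMz:
    def test_hexnac_oxonium(self):
        t = parse_glycan_struct("(N(N(H(H(N))(H))))")
        idx = FragmentIndex(
            GlycopeptidePrecursor(PeptideSequence("LNSTAVK", 1), t, 2),
            with_B=True,
        )
        b_ions = {
            str(ion.composition): ion.mz
            for part, _s, ion in idx.theoretical_ions()
            if part == "B"
        }
        assert b_ions["N(1)"] == pytest.approx(204.08666, abs=1e-4)

    def test_y_ion_mass_additivity(self, simple_index):
        pep_mass = simple_index.precursor.peptide.neutral_mass()
        for part, _slot, ion in simple_index.theoretical_ions():
            if part != "Y":
                continue
            expected = (
                pep_mass + ion.composition.mass() + ion.charge * PROTON_MASS
            ) / ion.charge
            assert ion.mz == pytest.approx(expected, rel=1e-12)

    def test_y0_equals_naked_peptide(self, simple_index):
        pep_mass = simple_index.precursor.peptide.neutral_mass()
        y0 = [
            ion
            for part, _s, ion in simple_index.theoretical_ions()
            if part == "Y" and len(ion.composition) == 0 and ion.charge == 2
        ][0]
        assert y0.mz == pytest.approx((pep_mass + 2 * PROTON_MASS) / 2)

    def test_mz_increases_with_retained_composition(self, simple_index):
        mz_by_size = [
            (len(ion.composition), ion.mz)
            for part, _s, ion in simple_index.theoretical_ions()
            if part == "Y" and ion.charge == 1
        ]
        mz_by_size.sort()
        mzs = [m for _s, m in mz_by_size]
        assert all(a < b for a, b in zip(mzs, mzs[1:]))

    def test_variant_mass_offsets(self):
        pep = PeptideSequence("LNSTAVK", glycosite=1)
        ions = {(i.series, i.ordinal, i.charge): i.mz for i in peptide_fragments(pep)}
        assert ions[("bN1", 3, 1)] - ions[("b", 3, 1)] == pytest.approx(
            HEXNAC_MASS, abs=1e-9
        )
        assert ions[("bX", 3, 1)] - ions[("b", 3, 1)] == pytest.approx(
            CROSS_RING_MASS, abs=1e-9
        )
        assert CROSS_RING_MASS == pytest.approx(83.03711, abs=1e-5)
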