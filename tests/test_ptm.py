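"""Template registry, mutate/modify, chain growth and capped dipeptides."""

import numpy as np
import pytest

from ptmforge import ptm
from ptmforge.fixtures import make_toy_protein
from ptmforge.geometry import detect_bonds, dihedral
from ptmforge.ptm import (RegistryError, append, build_dipeptide, get_template,
                          list_modifications, modification_rule, modify,
                          mutate, prepend, PTM_CYSTEINE_CODES)
from ptmforge.structure import Protein, SiteMismatchError


class TestRegistry:
    def test_cys_block_matches_table(self):
        cys = {r for _, r in list_modifications("CYS")}
        assert cys == {"carbamylation", "cyanylation", "cysteinylation",
                       "glutathionylation", "methylation", "nitrosylation",
                       "phosphorylation", "sulfenylation", "sulfhydration",
                       "sulfinylation", "sulfonylation"}

    def test_full_registry_matches_table(self):
        expected = {
            "ARG": {"methylation", "symmetric demethylation",
                    "asymmetric demethylation", "phosphorylation"},
            "ASP": {"phosphorylation"},
            "CYS": {r for _, r in list_modifications("CYS")},
            "GLU": {"methylation"},
            "HIS": {"methylation", "phosphorylation"},
            "LYS": {"acetylation", "methylation", "dimethylation",
                    "trimethylation", "phosphorylation"},
            "SER": {"phosphorylation"},
            "THR": {"phosphorylation"},
            "TYR": {"phosphorylation"},
        }
        actual: dict = {}
        for aa, reaction in list_modifications():
            actual.setdefault(aa, set()).add(reaction)
        assert actual == expected

    def test_tyr_only_phosphorylation(self):
        assert [r for _, r in list_modifications("TYR")] == ["phosphorylation"]

    def test_gly_has_no_modifications(self):
        assert list_modifications("GLY") == []

    @pytest.mark.parametrize("alias,canonical", [
        ("carbamoylation", "carbamylation"),
        ("nitrosation", "nitrosylation"),
        ("symmetric dimethylation", "symmetric demethylation"),
    ])
    def test_aliases_resolve(self, alias, canonical):
        target = "CYS" if canonical in dict.fromkeys(
            r for _, r in list_modifications("CYS")) else "ARG"
        assert modification_rule(target, alias).reaction == canonical

    def test_every_product_template_is_bundled(self):
        for aa, reaction in list_modifications():
            rule = modification_rule(aa, reaction)
            assert get_template(rule.product_template).code == rule.product_template

    def test_all_ptm_cysteine_codes_available(self):
        for code in PTM_CYSTEINE_CODES:
            tpl = get_template(code)
            assert {"N", "CA", "C", "O", "CB", "SG"} <= set(tpl.atom_names)


class TestMutate:
    def test_met_mutation_preserves_backbone(self, tripeptide):
        out = mutate(tripeptide, "A:CYS1", "MET")
        res = out.chain("A").residues[0]
        assert res.name == "MET"
        assert {"CB", "CG", "SD", "CE"} <= set(res.atom_names)
        for name in ("N", "CA", "C", "O"):
            np.testing.assert_allclose(
                res.atom(name).position,
                tripeptide.chain("A").residues[0].atom(name).position,
                atol=1e-9)

    def test_other_residues_untouched(self, tripeptide):
        out = mutate(tripeptide, "A:CYS1", "MET")
        for orig, new in zip(tripeptide.chain("A").residues[1:],
                             out.chain("A").residues[1:]):
            np.testing.assert_allclose(new.coordinates(), orig.coordinates(),
                                       atol=1e-12)

    def test_identity_mutation_is_noop(self, tripeptide):
        out = mutate(tripeptide, "A:CYS1", "CYS")
        np.testing.assert_allclose(
            out.chain("A").residues[0].coordinates(),
            tripeptide.chain("A").residues[0].coordinates())

    def test_mutate_to_ptm_cysteine(self, tripeptide):
        out = mutate(tripeptide, "A:ALA2", "SNC")
        res = out.chain("A").residues[1]
        assert res.name == "SNC"
        assert {"SG", "ND", "OE"} <= set(res.atom_names)

    def test_unknown_template_rejected(self, tripeptide):
        with pytest.raises(KeyError):
            mutate(tripeptide, "A:CYS1", "ZZZ")

    def test_site_mismatch_rejected(self, tripeptide):
        with pytest.raises(SiteMismatchError):
            mutate(tripeptide, "A:SER1", "MET")

    def test_crowded_site_takes_minimum_clash_rotamer(self):
        """In a deliberately crowded pocket the scan keeps the least-clashing
        of the 144 chi1/chi2 combinations."""
        from ptmforge.geometry import count_clashes
        from ptmforge.ptm import _chi_scan, _residue_bond_graph, _set_chi
        import warnings as _w

        protein = make_toy_protein(8, ["GLY"] * 8)
        # ring of obstruction atoms around residue 4's side-chain region
        from ptmforge.structure import Atom, Chain, Residue
        center = protein.chain("A").residues[3].atom("CA").position
        blockers = Residue("BLK", 99)
        rng = np.random.default_rng(7)
        for k in range(40):
            offset = rng.normal(scale=2.5, size=3)
            blockers.atoms.append(Atom(f"C{k}", "C", center + offset))
        protein.chains.append(Chain("Z", [blockers]))
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            out = mutate(protein, "A:GLY4", "MET")
        res = out.chain("A").residues[3]
        template = get_template("MET")
        placed = count_clashes(out, [res.atom(n) for n in
                                     template.sidechain_names()],
                               exclude_residues=[res])
        # exhaustive rescan: no grid combination does better
        graph = _residue_bond_graph(res)
        chis = template.chis
        best = placed
        probe = out.copy()
        pres = probe.chain("A").residues[3]
        pgraph = _residue_bond_graph(pres)
        b1 = dihedral(*(pres.atom(n).position for n in chis[0]))
        b2 = dihedral(*(pres.atom(n).position for n in chis[1]))
        for i in range(12):
            _set_chi(pres, chis[0], pgraph, b1 + 30.0 * i)
            for j in range(12):
                _set_chi(pres, chis[1], pgraph, b2 + 30.0 * j)
                n = count_clashes(probe, [pres.atom(n) for n in
                                          template.sidechain_names()],
                                  exclude_residues=[pres])
                best = min(best, n)
        assert placed == best


class TestModify:
    def test_ser_acetylation_retains_ser_atoms(self, tripeptide):
        out = modify(tripeptide, "A:SER3", "acetylation")
        res = out.chain("A").residues[2]
        orig = tripeptide.chain("A").residues[2]
        assert res.name == "OAS"
        for name in orig.atom_names:
            np.testing.assert_allclose(res.atom(name).position,
                                       orig.atom(name).position, atol=1e-9)
        assert len(res.atoms) > len(orig.atoms)

    def test_nitrosylation_yields_bonded_sno(self):
        protein = Protein()
        protein = prepend(protein, chain="A", residue="CYS")
        out = modify(protein, "A:CYS1", "nitrosylation")
        res = out.chain("A").residues[0]
        assert res.name == "SNC"
        assert {"ND", "OE"} <= set(res.atom_names)
        names = res.atom_names
        bonds = {frozenset((names[i], names[j]))
                 for i, j in detect_bonds(res.atoms)}
        assert frozenset(("SG", "ND")) in bonds
        assert frozenset(("ND", "OE")) in bonds

    def test_invalid_pair_lists_valid_reactions(self, tripeptide):
        with pytest.raises(RegistryError, match="phosphorylation"):
            modify(tripeptide, "A:ALA2", "phosphorylation")

    def test_gly_phosphorylation_rejected(self):
        protein = make_toy_protein(1, ["GLY"])
        with pytest.raises(RegistryError):
            modify(protein, "A:GLY1", "phosphorylation")

    @pytest.mark.parametrize("reaction", [
        "carbamylation", "cyanylation", "cysteinylation", "glutathionylation",
        "methylation", "nitrosylation", "phosphorylation", "sulfenylation",
        "sulfhydration", "sulfinylation", "sulfonylation"])
    def test_every_cys_product_is_connected(self, reaction):
        protein = make_toy_protein(3, ["ALA", "CYS", "ALA"])
        out = modify(protein, "A:CYS2", reaction)
        res = out.chain("A").residues[1]
        names = res.atom_names
        bonds = detect_bonds(res.atoms)
        adj = {i: set() for i in range(len(names))}
        for i, j in bonds:
            adj[i].add(j)
            adj[j].add(i)
        seen = {0}
        stack = [0]
        while stack:
            for nxt in adj[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        assert seen == set(range(len(names)))

    def test_modify_never_moves_backbone(self, tripeptide):
        out = modify(tripeptide, "A:CYS1", "nitrosylation")
        res = out.chain("A").residues[0]
        for name in ("N", "CA", "C", "O"):
            np.testing.assert_allclose(
                res.atom(name).position,
                tripeptide.chain("A").residues[0].atom(name).position,
                atol=1e-12)


class TestChainGrowth:
    def test_prepend_on_empty_builds_fresh_residue(self):
        out = prepend(Protein(), chain="A", residue="CYS")
        assert len(out.chains) == 1
        res = out.chain("A").residues[0]
        assert res.name == "CYS" and res.number == 1
        assert {"N", "CA", "C", "O", "CB", "SG"} == set(res.atom_names)

    def test_caps_have_expected_atom_counts(self):
        protein = make_toy_protein(2, ["ALA", "ALA"])
        capped = prepend(protein, chain="A", residue="ACE")
        capped = append(capped, chain="A", residue="NME")
        residues = capped.chain("A").residues
        assert residues[0].name == "ACE" and len(residues[0].atoms) == 3
        assert residues[-1].name == "NME" and len(residues[-1].atoms) == 2

    def test_explicit_phi_psi_reproduced(self):
        protein = make_toy_protein(1, ["ALA"])
        grown = append(protein, chain="A", residue="ALA", phi=-60.0, psi=-45.0)
        grown = append(grown, chain="A", residue="ALA")
        r1, r2, r3 = grown.chain("A").residues
        phi2 = dihedral(r1.atom("C").position, r2.atom("N").position,
                        r2.atom("CA").position, r2.atom("C").position)
        assert phi2 == pytest.approx(-60.0, abs=1e-6)

    def test_default_is_beta_strand(self):
        protein = make_toy_protein(3)
        r1, r2, r3 = protein.chain("A").residues
        phi2 = dihedral(r1.atom("C").position, r2.atom("N").position,
                        r2.atom("CA").position, r2.atom("C").position)
        psi2 = dihedral(r2.atom("N").position, r2.atom("CA").position,
                        r2.atom("C").position, r3.atom("N").position)
        assert (phi2, psi2) == (pytest.approx(-135.0, abs=1e-6),
                                pytest.approx(135.0, abs=1e-6))

    def test_unknown_residue_rejected(self):
        with pytest.raises(KeyError):
            prepend(Protein(), chain="A", residue="QQQ")


class TestDipeptide:
    @pytest.mark.parametrize("conformation,expected", [
        ("alpha", (-60.0, -45.0)),
        ("beta", (-135.0, 135.0)),
    ])
    def test_backbone_torsions(self, conformation, expected):
        out = build_dipeptide("SNC", conformation)
        ace, central, nme = out.chain("A").residues
        phi = dihedral(ace.atom("C").position, central.atom("N").position,
                       central.atom("CA").position, central.atom("C").position)
        psi = dihedral(central.atom("N").position, central.atom("CA").position,
                       central.atom("C").position, nme.atom("N").position)
        assert phi == pytest.approx(expected[0], abs=1e-6)
        assert psi == pytest.approx(expected[1], abs=1e-6)

    def test_atom_counts_are_template_sums(self):
        out = build_dipeptide("SNC", "beta")
        counts = [len(r.atoms) for r in out.chain("A").residues]
        expected = [len(get_template(c).atoms) for c in ("ACE", "SNC", "NME")]
        assert counts == expected

    def test_unknown_code_rejected(self):
        with pytest.raises(KeyError):
            build_dipeptide("XYZ", "beta")
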