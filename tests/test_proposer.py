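"""Back-mutation proposal: evidence classes, coupling, closure."""

import pytest

from abgraft.grafting import apply_back_mutations, build_panel, graft
from abgraft.interface import interface_bsa
from abgraft.proposer import diff_framework, load_vernier_table, propose
from abgraft.schemes import CDR_REGIONS, SchemePosition, get_boundary_table
from abgraft.structure import AtomRecord, StructureModel, vdw_radius
from abgraft.synthetic import make_key_contact_complex


@pytest.fixture(scope="module")
def vernier():
    return load_vernier_table()


@pytest.fixture()
def v17_light(parental_light_kabat, by_gene):
    table = get_boundary_table("kabat", "kappa")
    return graft(parental_light_kabat, by_gene["IGKV1-16"], table).chain


@pytest.fixture()
def v14_heavy(parental_heavy_kabat, by_gene):
    table = get_boundary_table("kabat", "heavy")
    return graft(parental_heavy_kabat, by_gene["IGHV4-59"], table).chain


class TestVernierTable:
    def test_h71_is_the_canonical_vernier_position(self, vernier):
        assert vernier.contains("heavy", SchemePosition("kabat", 71))

    def test_all_positions_are_framework(self, vernier):
        for cc, nums in vernier.positions.items():
            boundary = get_boundary_table("kabat", cc)
            for n in nums:
                assert boundary.region_of_number(n) not in CDR_REGIONS


class TestDiffFramework:
    def test_identical_chains_empty(self, parental_light_kabat):
        assert diff_framework(parental_light_kabat, parental_light_kabat) == []

    def test_v17_light_diff_contains_60_and_66(self, parental_light_kabat, v17_light):
        diffs = {p.label: (a, b) for p, a, b in diff_framework(parental_light_kabat, v17_light)}
        assert diffs["60"] == ("K", "S")
        assert diffs["66"] == ("R", "G")

    def test_antisymmetric(self, parental_light_kabat, v17_light):
        fwd = diff_framework(parental_light_kabat, v17_light)
        rev = diff_framework(v17_light, parental_light_kabat)
        assert [(p, b, a) for p, a, b in fwd] == rev

    def test_cdr_differences_excluded(self, parental_light_kabat, v17_light):
        cdr_positions = {
            p for p, _ in parental_light_kabat.positions
            if parental_light_kabat.region_of[p] in CDR_REGIONS
        }
        for p, _, _ in diff_framework(parental_light_kabat, v17_light):
            assert p not in cdr_positions

    def test_scheme_mismatch_rejected(self, parental_light_kabat, parental_light_imgt):
        with pytest.raises(ValueError):
            diff_framework(parental_light_kabat, parental_light_imgt)


class TestPropose:
    def test_identical_sequences_propose_nothing(self, parental_light_kabat):
        assert propose(parental_light_kabat, parental_light_kabat) == []

    def test_interface_evidence_gives_direct_contact_proposals(
        self, parental_light_kabat, v17_light
    ):
        """L-S60K and L-G66R emerge with direct-contact evidence from the
        planted salt bridge / hydrogen bond in the synthetic complex."""
        model, _ = make_key_contact_complex()
        report = interface_bsa(model)
        pos_map = {
            pos: ("L", pos.number, pos.insertion_code or "")
            for pos, _ in parental_light_kabat.positions
        }
        props = propose(
            parental_light_kabat, v17_light,
            report=report, position_to_residue=pos_map, bsa_threshold=10.0,
        )
        by_label = {p.position.label: p for p in props}
        assert by_label["60"].evidence == "direct_contact"
        assert by_label["60"].mutation_label == "S60K"
        assert any(c.type == "salt_bridge" for c in by_label["60"].contacts)
        assert by_label["66"].mutation_label == "G66R"
        assert any(c.type == "hbond" for c in by_label["66"].contacts)

    def test_vernier_pair_71_78_with_coupling_note(self, parental_heavy_kabat, v14_heavy):
        """V71K and F78V both arise from the Vernier zone; a parental
        structure with their Cβ within 8 Å cross-annotates them."""

        def cb(resnum, xyz):
            return AtomRecord("H", resnum, "", "ALA", "CB", "C",
                              xyz[0], xyz[1], xyz[2], vdw_radius("C"))

        diff_positions = [p.number for p, _, _ in
                          diff_framework(parental_heavy_kabat, v14_heavy)]
        atoms = [cb(71, (0, 0, 0)), cb(78, (6.0, 0, 0))]
        # every other differing position far away (no accidental coupling)
        for i, n in enumerate(d for d in diff_positions if d not in (71, 78)):
            atoms.append(cb(n, (100.0 + 20 * i, 0, 0)))
        structure = StructureModel("parental", tuple(atoms))
        pos_map = {
            pos: ("H", pos.number, pos.insertion_code or "")
            for pos, _ in parental_heavy_kabat.positions
        }
        props = propose(
            parental_heavy_kabat, v14_heavy,
            position_to_residue=pos_map, parental_structure=structure,
        )
        by_label = {p.position.label: p for p in props}
        assert by_label["71"].mutation_label == "V71K"
        assert by_label["71"].evidence == "vernier"
        assert by_label["78"].mutation_label == "F78V"
        assert "71" in by_label["78"].partner_note
        assert "78" in by_label["71"].partner_note

    def test_proposals_subset_of_framework_diffs(self, parental_heavy_kabat, v14_heavy):
        diffs = {p for p, _, _ in diff_framework(parental_heavy_kabat, v14_heavy)}
        for prop in propose(parental_heavy_kabat, v14_heavy):
            assert prop.position in diffs

    def test_raising_threshold_never_adds_direct_proposals(
        self, parental_light_kabat, v17_light
    ):
        model, _ = make_key_contact_complex()
        report = interface_bsa(model)
        pos_map = {
            pos: ("L", pos.number, pos.insertion_code or "")
            for pos, _ in parental_light_kabat.positions
        }

        def direct_set(thr):
            return {
                p.position for p in propose(
                    parental_light_kabat, v17_light,
                    report=report, position_to_residue=pos_map, bsa_threshold=thr,
                )
                if "contact" in p.evidence
            }

        prev = direct_set(0.0)
        for thr in (5.0, 15.0, 40.0, 1e6):
            cur = direct_set(thr)
            assert cur <= prev
            prev = cur

    def test_closure_apply_then_repropose_empty(
        self, parental_heavy_kabat, parental_light_kabat, by_gene
    ):
        th = get_boundary_table("kabat", "heavy")
        tl = get_boundary_table("kabat", "kappa")
        cand = build_panel(
            [graft(parental_heavy_kabat, by_gene["IGHV2-26"], th)],
            [graft(parental_light_kabat, by_gene["IGKV1-16"], tl)],
            "V",
        )[0]
        hp = propose(parental_heavy_kabat, cand.heavy)
        lp = propose(parental_light_kabat, cand.light)
        muts = [p.as_back_mutation() for p in hp] + [p.as_back_mutation() for p in lp]
        reverted = apply_back_mutations(cand, muts)
        assert propose(parental_heavy_kabat, reverted.heavy) == []
        assert propose(parental_light_kabat, reverted.light) == []

    def test_ranking_orders_contact_evidence_first(
        self, parental_light_kabat, v17_light
    ):
        model, _ = make_key_contact_complex()
        report = interface_bsa(model)
        pos_map = {
            pos: ("L", pos.number, pos.insertion_code or "")
            for pos, _ in parental_light_kabat.positions
        }
        props = propose(
            parental_light_kabat, v17_light,
            report=report, position_to_residue=pos_map,
        )
        ranks = ["contact_and_vernier", "direct_contact", "vernier"]
        order = [ranks.index(p.evidence) for p in props]
        assert order == sorted(order)
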