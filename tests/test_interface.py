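"""SASA, buried surface area and contact detection against oracles."""

import numpy as np
import pytest

from abgraft.interface import (
    CHARGED_GROUPS,
    Contact,
    ContactConfig,
    detect_contacts,
    interface_bsa,
    is_apolar_carbon,
    is_hbond_acceptor,
    is_hbond_donor,
)
from abgraft.sasa import compute_sasa, sphere_points
from abgraft.structure import AtomRecord, StructureModel, read_structure, write_pdb
from abgraft.synthetic import (
    make_framework_bsa_complex,
    make_key_contact_complex,
    make_shell,
    make_toy_interface,
    make_two_sphere,
)


def bead(chain, resnum, resname, name, element, xyz, vdw=None):
    from abgraft.structure import vdw_radius

    return AtomRecord(chain, resnum, "", resname, name, element,
                      float(xyz[0]), float(xyz[1]), float(xyz[2]),
                      vdw if vdw is not None else vdw_radius(element))


# ---------------------------------------------------------------- SASA

class TestSasa:
    def test_single_carbon_closed_form(self):
        model = StructureModel("m", (bead("A", 1, "GLY", "CA", "C", (0, 0, 0)),))
        res = compute_sasa(model)
        assert res.per_atom[0] == pytest.approx(4 * np.pi * 3.1**2, rel=1e-12)

    @pytest.mark.parametrize("d", [0.5, 1.5, 2.5, 3.5, 4.5, 5.5, 6.0, 6.5])
    def test_two_sphere_cap_formula_within_1pct(self, d):
        model, truth = make_two_sphere(d)
        res = compute_sasa(model, n_points=960)
        for a in res.per_atom:
            assert a == pytest.approx(truth.payload["sasa_per_atom"], rel=0.01)

    def test_enclosed_atom_has_zero_sasa(self):
        model, truth = make_shell()
        assert compute_sasa(model).per_atom[0] == 0.0

    def test_monotone_under_added_atoms(self):
        base = StructureModel("m", (
            bead("A", 1, "GLY", "CA", "C", (0, 0, 0)),
            bead("A", 2, "GLY", "CA", "C", (4.0, 0, 0)),
        ))
        more = StructureModel("m2", base.atoms + (
            bead("A", 3, "GLY", "CA", "C", (2.0, 3.0, 0)),
        ))
        s0 = compute_sasa(base).per_atom
        s1 = compute_sasa(more).per_atom[:2]
        assert np.all(s1 <= s0 + 1e-9)

    def test_point_count_convergence(self):
        model, _ = make_toy_interface(4)
        lo = compute_sasa(model, n_points=960).per_residue()
        hi = compute_sasa(model, n_points=1920).per_residue()
        for key, v in lo.items():
            if v > 1.0:
                assert hi[key] == pytest.approx(v, rel=0.005)

    def test_unknown_element_raises(self):
        from abgraft.structure import vdw_radius

        with pytest.raises(KeyError):
            vdw_radius("Qq")

    def test_sphere_points_deterministic_unit_norm(self):
        p = sphere_points(960)
        assert np.allclose(np.linalg.norm(p, axis=1), 1.0)
        assert np.array_equal(p, sphere_points(960))


# ---------------------------------------------------------------- BSA

class TestInterfaceBsa:
    def test_separated_chains_bury_nothing(self):
        model, _ = make_toy_interface(0, separation=30.0)
        report = interface_bsa(model, contacts=False)
        assert report.total_bsa_side == (0.0, 0.0)

    def test_symmetric_dimer_sides_equal(self):
        atoms = []
        for i in range(6):
            atoms.append(bead("A", i + 1, "GLY", "CA", "C", (8.0 * i, 0, 0)))
            atoms.append(bead("B", i + 1, "GLY", "CA", "C", (8.0 * i, 0, 4.2)))
        model = StructureModel("dimer", tuple(atoms)).with_partition({"A"}, {"B"})
        report = interface_bsa(model, contacts=False)
        assert report.total_bsa_side[0] == pytest.approx(
            report.total_bsa_side[1], abs=1e-6
        )
        assert report.total_bsa_side[0] > 0

    def test_per_residue_bsa_nonnegative_and_sums_to_totals(self):
        model, _, _ = make_framework_bsa_complex()
        report = interface_bsa(model, contacts=False)
        for side in (0, 1):
            s = sum(
                v for k, v in report.per_residue_bsa.items()
                if report.side_of_residue[k] == side
            )
            assert s == pytest.approx(report.total_bsa_side[side])
        assert min(report.per_residue_bsa.values()) >= 0.0

    def test_region_fractions_sum_to_one(self):
        model, _, annotation = make_framework_bsa_complex()
        report = interface_bsa(model, region_annotation=annotation, contacts=False)
        fr = report.fraction_bsa_by_region_class
        assert fr["CDR"] + fr["framework"] == pytest.approx(1.0)

    def test_missing_partition_rejected(self):
        model, _ = make_two_sphere(4.0)
        with pytest.raises(ValueError):
            interface_bsa(model)


# ---------------------------------------------------------------- contacts

def brute_force_contacts(model: StructureModel, cfg: ContactConfig) -> set:
    """Independent all-pairs re-derivation of the typed-contact rules."""
    out = set()
    heavy = [a for a in model.atoms if a.element != "H"]
    # group-wise salt bridges
    charged = {}
    for a in heavy:
        if a.residue_name in CHARGED_GROUPS:
            sign, names = CHARGED_GROUPS[a.residue_name]
            if a.atom_name in names:
                charged.setdefault(a.residue_key, (sign, []))[1].append(a)
    salt_residue_pairs = set()
    keys = list(charged)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            ka, kb = keys[i], keys[j]
            (sa, aa), (sb, ab) = charged[ka], charged[kb]
            if sa * sb >= 0 or model.side_of(ka[0]) == model.side_of(kb[0]):
                continue
            ca = np.mean([x.coords for x in aa], axis=0)
            cb = np.mean([x.coords for x in ab], axis=0)
            if np.linalg.norm(ca - cb) <= cfg.salt_bridge_max_dist:
                salt_residue_pairs.add(frozenset((ka, kb)))
                out.add(("salt_bridge", frozenset((ka, kb))))
    for i in range(len(heavy)):
        for j in range(i + 1, len(heavy)):
            a, b = heavy[i], heavy[j]
            if model.side_of(a.chain_id) == model.side_of(b.chain_id):
                continue
            if frozenset((a.residue_key, b.residue_key)) in salt_residue_pairs:
                continue
            d = np.linalg.norm(a.coords - b.coords)
            if d <= cfg.hbond_max_dist and (
                (is_hbond_donor(a) and is_hbond_acceptor(b))
                or (is_hbond_donor(b) and is_hbond_acceptor(a))
            ):
                out.add(("hbond", frozenset(((a.residue_key, a.atom_name),
                                             (b.residue_key, b.atom_name)))))
            elif d <= cfg.hydrophobic_max_dist and is_apolar_carbon(a) and is_apolar_carbon(b):
                out.add(("hydrophobic", frozenset(((a.residue_key, a.atom_name),
                                                   (b.residue_key, b.atom_name)))))
            elif d <= a.vdw + b.vdw + cfg.vdw_slack:
                out.add(("vdw", frozenset(((a.residue_key, a.atom_name),
                                           (b.residue_key, b.atom_name)))))
    return out


def as_comparable(contacts: list[Contact]) -> set:
    out = set()
    for c in contacts:
        if c.type == "salt_bridge":
            out.add(("salt_bridge", frozenset((c.atom_a.residue_key, c.atom_b.residue_key))))
        else:
            out.add((c.type, frozenset(((c.atom_a.residue_key, c.atom_a.atom_name),
                                        (c.atom_b.residue_key, c.atom_b.atom_name)))))
    return out


class TestContacts:
    def test_planted_contacts_recovered_with_types(self):
        model, truth = make_toy_interface(8)
        found = detect_contacts(model)
        assert len(found) == 8
        got = {
            (c.type, c.atom_a.residue_number): round(c.distance, 3) for c in found
        }
        for t in truth.payload["contacts"]:
            assert got[(t["type"], t["atom_a"][1])] == pytest.approx(
                t["distance"], abs=1e-6
            )

    def test_far_apart_chains_have_no_contacts(self):
        model, _ = make_toy_interface(0, separation=30.0)
        assert detect_contacts(model) == []

    def test_salt_bridge_takes_precedence_over_hbond(self):
        # Lys NZ / Glu OE1 at 3.0 Å qualifies as both; must be salt_bridge
        model = StructureModel("m", (
            bead("A", 1, "LYS", "NZ", "N", (0, 0, 0)),
            bead("B", 1, "GLU", "OE1", "O", (0, 0, 3.0)),
        )).with_partition({"A"}, {"B"})
        (c,) = detect_contacts(model)
        assert c.type == "salt_bridge"

    def test_closest_pair_at_8A_yields_nothing(self):
        model = StructureModel("m", (
            bead("A", 1, "LYS", "NZ", "N", (0, 0, 0)),
            bead("B", 1, "GLU", "OE1", "O", (0, 0, 8.0)),
        )).with_partition({"A"}, {"B"})
        assert detect_contacts(model) == []

    def test_hbond_angle_rejected_with_explicit_hydrogens(self):
        # donor H pointing away from the acceptor: D-H...A angle ~0, rejected
        model = StructureModel("m", (
            bead("A", 1, "SER", "OG", "O", (0, 0, 0)),
            bead("A", 1, "SER", "HG", "H", (0, 0, -1.0)),
            bead("B", 1, "THR", "OG1", "O", (0, 0, 3.2)),
        )).with_partition({"A"}, {"B"})
        found = detect_contacts(model)
        assert all(c.type != "hbond" for c in found)
        # hydrogen between donor and acceptor: angle ~180, valid hbond
        model2 = StructureModel("m", (
            bead("A", 1, "SER", "OG", "O", (0, 0, 0)),
            bead("A", 1, "SER", "HG", "H", (0, 0, 1.0)),
            bead("B", 1, "THR", "OG1", "O", (0, 0, 3.2)),
        )).with_partition({"A"}, {"B"})
        assert any(c.type == "hbond" for c in detect_contacts(model2))

    @pytest.mark.parametrize("n_contacts", [0, 3, 8, 12])
    def test_matches_brute_force_oracle(self, n_contacts):
        model, _ = make_toy_interface(n_contacts, seed=n_contacts)
        cfg = ContactConfig()
        assert as_comparable(detect_contacts(model, cfg)) == brute_force_contacts(model, cfg)

    def test_oracle_equivalence_on_key_contact_complex(self):
        model, _ = make_key_contact_complex()
        cfg = ContactConfig()
        assert as_comparable(detect_contacts(model, cfg)) == brute_force_contacts(model, cfg)

    def test_deterministic_ordering(self):
        model, _ = make_toy_interface(6)
        a = detect_contacts(model)
        b = detect_contacts(model)
        assert [(c.type, c.distance) for c in a] == [(c.type, c.distance) for c in b]


class TestPdbRoundTrip:
    def test_toy_interface_survives_pdb_io(self, tmp_path):
        model, _ = make_toy_interface(4)
        path = tmp_path / "toy.pdb"
        write_pdb(path, model)
        back = read_structure(path).with_partition({"A"}, {"B"})
        assert len(back) == len(model)
        assert [c.type for c in detect_contacts(back)] == [
            c.type for c in detect_contacts(model)
        ]
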