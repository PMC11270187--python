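"""Synthetic fixtures with machine-readable ground truth.

Every generator is deterministic given its parameters and seed, and
returns a :class:`GroundTruth` alongside the fixture so that analysis
results can be checked against planted truth with no external data:

* template-derived antibody sequences with known per-residue scheme labels;
* toy multi-chain bead structures with analytically known SASA and planted
  typed contacts (written as valid PDB when exercised via the CLI, so the
  real I/O path is covered);
* Gaussian-jittered coordinate ensembles with known per-residue variance
  (a stand-in for an MD trajectory);
* 1:1 sensorgram dilution series with known rates, defaulting to the
  modelled assay design (two-fold series from 125 nM, 180 s phases);
* synthetic Fab-like interface complexes that emulate, at bead resolution,
  the structural hallmarks of the parental Fab–HLA-DR complex (framework
  BSA share near 44%, the L-K60 salt bridge and L-R66 main-chain hydrogen
  bond, and the HCDR3 displacement contrast between loosely and tightly
  supported grafts).

Bead "residues" carry real residue and atom names so contact-typing rules
apply unmodified.  The Fab-like complexes are synthetic stand-ins for the
deposited crystal structures, not models of them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .germline import GermlineEntry, load_default_library
from .kinetics import SensorgramSet, simulate_sensorgrams
from .numbering import AntibodySequence, NumberedChain, number_sequence
from .schemes import (
    CDR_REGIONS,
    REGION_ORDER,
    cdr_labels_for_length,
    get_boundary_table,
    get_template,
    j_consensus_fr4,
)
from .structure import AtomRecord, StructureModel, vdw_radius

FIXTURE_KINDS = (
    "sequence_set", "two_sphere", "toy_interface", "shell",
    "ensemble", "sensorgram_set",
)


@dataclass(frozen=True)
class GroundTruth:
    """Machine-readable truth payload accompanying a fixture."""

    kind: str
    payload: dict

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "payload": self.payload}, indent=2)


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")


# -- sequences ---------------------------------------------------------------

_SUB_ALPHABET = "ADEFGHIKLMNPQRSTVY"  # no C/W: anchors stay unambiguous


def full_length_chain(entry: GermlineEntry) -> AntibodySequence:
    """Germline V gene completed with the J-consensus FR4."""
    return AntibodySequence(
        entry.gene_name,
        entry.chain_class,
        entry.sequence + j_consensus_fr4(entry.chain_class),
    )


def _truth_labels(chain: NumberedChain) -> list[dict]:
    return [
        {
            "label": pos.label,
            "region": chain.region_of[pos],
            "residue": aa,
        }
        for pos, aa in chain.positions
    ]


def make_sequence_set(
    n: int,
    indel_rate: float = 0.0,
    mutation_rate: float = 0.0,
    seed: int = 0,
    bases: Optional[Sequence[AntibodySequence]] = None,
) -> tuple[list[AntibodySequence], GroundTruth]:
    """Template-derived sequences with ground-truth labels for both schemes.

    Substitutions (drawn from a C/W-free alphabet, never at conserved
    anchors) occur per residue at ``mutation_rate``; insertions/deletions
    occur only at positions that are CDR under *both* schemes, at most two
    per sequence.  Truth records every residue's Kabat and IMGT label and
    region, maintained through the edits with the schemes' canonical CDR
    fill rules.
    """
    for rate, name in ((indel_rate, "indel_rate"), (mutation_rate, "mutation_rate")):
        if not 0.0 <= rate <= 0.1:
            raise ValueError(f"{name} must be in [0, 0.1], got {rate}")
    rng = np.random.default_rng(seed)
    if bases is None:
        bases = [full_length_chain(e) for e in load_default_library()]
    numbered = {
        b.id: {s: number_sequence(b, s) for s in ("kabat", "imgt")} for b in bases
    }
    seqs: list[AntibodySequence] = []
    truth: dict[str, dict] = {}
    for i in range(n):
        base = bases[int(rng.integers(len(bases)))]
        rows = []  # per residue: [aa, kabat_region, imgt_region]
        anchors = set()
        for scheme in ("kabat", "imgt"):
            chain = numbered[base.id][scheme]
            template = get_template(scheme, base.chain_class)
            anchor_nums = {
                p.number for p in (*template.hard_anchors, *template.soft_anchors)
            }
            for idx, (pos, aa) in enumerate(chain.positions):
                if pos.number in anchor_nums and pos.insertion_code is None:
                    anchors.add(idx)
        kchain = numbered[base.id]["kabat"]
        ichain = numbered[base.id]["imgt"]
        for idx, (pos, aa) in enumerate(kchain.positions):
            rows.append([aa, kchain.region_of[pos], None])
        for idx, (pos, _) in enumerate(ichain.positions):
            rows[idx][2] = ichain.region_of[pos]

        # substitutions
        for idx in range(len(rows)):
            if idx in anchors:
                continue
            if rng.random() < mutation_rate:
                choices = [c for c in _SUB_ALPHABET if c != rows[idx][0]]
                rows[idx][0] = choices[int(rng.integers(len(choices)))]

        # indels: only where both schemes call it CDR, never at a run edge
        def _candidates():
            cand = []
            for idx in range(1, len(rows) - 1):
                if not (rows[idx][1].startswith("CDR") and rows[idx][2].startswith("CDR")):
                    continue
                prev_ok = rows[idx - 1][1] == rows[idx][1] and rows[idx - 1][2] == rows[idx][2]
                next_ok = rows[idx + 1][1] == rows[idx][1] and rows[idx + 1][2] == rows[idx][2]
                if prev_ok and next_ok:
                    cand.append(idx)
            return cand

        n_indels = 0
        for _ in range(len(_candidates())):
            if n_indels >= 2:
                break
            if rng.random() >= indel_rate:
                continue
            cand = _candidates()  # recompute: indices shift after each edit
            if not cand:
                break
            idx = cand[int(rng.integers(len(cand)))]
            if rng.random() < 0.5:
                del rows[idx]
            else:
                aa = _SUB_ALPHABET[int(rng.integers(len(_SUB_ALPHABET)))]
                rows.insert(idx, [aa, rows[idx][1], rows[idx][2]])
            n_indels += 1

        seq = "".join(r[0] for r in rows)
        sid = f"syn{i:03d}_{base.id}"
        aseq = AntibodySequence(sid, base.chain_class, seq)
        seqs.append(aseq)

        per_scheme = {}
        for si, scheme in enumerate(("kabat", "imgt")):
            boundary = get_boundary_table(scheme, base.chain_class)
            labels = []
            base_chain = numbered[base.id][scheme]
            base_fr_labels = {
                r: [p for p, _ in base_chain.region_items(r)]
                for r in REGION_ORDER
                if r not in CDR_REGIONS
            }
            col = 1 + si  # region column in rows
            for region in REGION_ORDER:
                idxs = [k for k, r in enumerate(rows) if r[col] == region]
                if not idxs:
                    continue
                if region in CDR_REGIONS:
                    pos_list = cdr_labels_for_length(
                        scheme, boundary.spans[region], len(idxs)
                    )
                else:
                    pos_list = base_fr_labels[region]
                for p, k in zip(pos_list, idxs):
                    labels.append(
                        {"label": p.label, "region": region, "residue": rows[k][0]}
                    )
            per_scheme[scheme] = labels
        truth[sid] = {
            "base": base.id,
            "chain_class": base.chain_class,
            "n_indels": n_indels,
            "labels": per_scheme,
        }
    return seqs, GroundTruth("sequence_set", truth)


# -- toy structures ----------------------------------------------------------

def _atom(chain, resnum, resname, name, element, xyz, icode="") -> AtomRecord:
    return AtomRecord(
        chain_id=chain,
        residue_number=resnum,
        insertion_code=icode,
        residue_name=resname,
        atom_name=name,
        element=element,
        x=float(xyz[0]), y=float(xyz[1]), z=float(xyz[2]),
        vdw=vdw_radius(element),
    )


def make_two_sphere(separation: float, element: str = "C") -> tuple[StructureModel, GroundTruth]:
    """Two identical atoms at a given separation, with analytic SASA truth.

    For expanded radius R = r_vdw + probe, each sphere's SASA is 4πR² when
    the spheres do not intersect and 2πR² + πR·d otherwise (equal spheres,
    spherical-cap formula).
    """
    r = vdw_radius(element)
    probe = 1.4
    R = r + probe
    if separation >= 2 * R:
        area = 4 * np.pi * R * R
    else:
        area = 2 * np.pi * R * R + np.pi * R * separation
    atoms = (
        _atom("A", 1, "GLY", "CA", element, (0, 0, 0)),
        _atom("A", 2, "GLY", "CA", element, (separation, 0, 0)),
    )
    model = StructureModel("two_sphere", atoms)
    truth = GroundTruth(
        "two_sphere",
        {
            "separation": separation,
            "probe_radius": probe,
            "expanded_radius": R,
            "sasa_per_atom": area,
        },
    )
    return model, truth


def make_shell(n_shell: int = 30) -> tuple[StructureModel, GroundTruth]:
    """A central atom fully enclosed by a tight shell: central SASA = 0."""
    from .sasa import sphere_points

    atoms = [_atom("A", 1, "GLY", "CA", "C", (0, 0, 0))]
    for k, p in enumerate(sphere_points(n_shell), start=2):
        atoms.append(_atom("A", k, "GLY", "CA", "C", 3.0 * p))
    model = StructureModel("shell", tuple(atoms))
    return model, GroundTruth("shell", {"buried_atom": ["A", 1, "CA"], "sasa": 0.0})


_CONTACT_RECIPES = (
    # (type, resname_a, atom_a, element_a, resname_b, atom_b, element_b, dist)
    ("salt_bridge", "LYS", "NZ", "N", "GLU", "OE1", "O", 3.0),
    ("hbond", "SER", "OG", "O", "THR", "OG1", "O", 2.9),
    ("hydrophobic", "LEU", "CD1", "C", "ALA", "CB", "C", 3.6),
    ("vdw", "ALA", "CB", "C", "SER", "CB", "C", 3.5),
)


def make_toy_interface(
    n_contacts: int, separation: float = 30.0, seed: int = 0
) -> tuple[StructureModel, GroundTruth]:
    """Two bead mini-chains with exactly ``n_contacts`` planted contacts.

    Planted pairs cycle through salt bridge, hydrogen bond, hydrophobic and
    vdW recipes at type-appropriate distances; remaining beads sit
    ``separation`` apart so they make no contacts (and no buried area when
    ``separation`` exceeds twice the largest expanded radius).
    """
    if n_contacts < 0:
        raise ValueError("n_contacts must be non-negative")
    min_sep = 2 * (1.8 + 1.4) + 0.2
    if separation < min_sep:
        raise ValueError(
            f"infeasible geometry: separation {separation} Å < {min_sep:.1f} Å "
            "would create unplanned contacts/burial"
        )
    atoms: list[AtomRecord] = []
    truth_contacts = []
    x = 0.0
    for k in range(n_contacts):
        ctype, rna, ana, ela, rnb, anb, elb, d = _CONTACT_RECIPES[
            k % len(_CONTACT_RECIPES)
        ]
        resn = k + 1
        atoms.append(_atom("A", resn, rna, ana, ela, (x, 0.0, 0.0)))
        atoms.append(_atom("B", resn, rnb, anb, elb, (x, 0.0, d)))
        truth_contacts.append(
            {
                "type": ctype,
                "atom_a": ["A", resn, ana],
                "atom_b": ["B", resn, anb],
                "distance": d,
            }
        )
        x += 12.0
    # inert far-apart beads (always present so both chains are non-empty)
    for j in range(3):
        atoms.append(_atom("A", 100 + j, "GLY", "CA", "C", (x + 12.0 * j, 0.0, 0.0)))
        atoms.append(
            _atom("B", 100 + j, "GLY", "CA", "C", (x + 12.0 * j + 6.0, 0.0, separation))
        )
    model = StructureModel(
        "toy_interface", tuple(atoms)
    ).with_partition({"A"}, {"B"})
    return model, GroundTruth(
        "toy_interface",
        {"n_contacts": n_contacts, "contacts": truth_contacts},
    )


def make_bead_chain(
    n_residues: int, chain_id: str = "A", start: int = 1, resname: str = "ALA"
) -> StructureModel:
    """A non-collinear zigzag of Cα beads (plus Cβ) for geometry fixtures."""
    atoms = []
    for i in range(n_residues):
        xyz = (3.8 * i, 1.5 * (i % 2), 0.8 * (i % 3))
        atoms.append(_atom(chain_id, start + i, resname, "CA", "C", xyz))
        atoms.append(
            _atom(chain_id, start + i, resname, "CB", "C",
                  (xyz[0], xyz[1] + 1.5, xyz[2] + 0.5))
        )
    return StructureModel("bead_chain", tuple(atoms))


def make_jittered_ensemble(
    base: StructureModel,
    sigma: float,
    n_frames: int,
    seed: int = 0,
    sigma_profile: Optional[dict] = None,
) -> tuple[list[StructureModel], GroundTruth]:
    """Gaussian-jittered copies of a base model with known per-residue σ.

    Each atom is displaced by isotropic N(0, σ²) per axis; ``sigma_profile``
    overrides σ for selected residue keys (to plant flexible-loop patterns).
    The expected Cα RMSF is σ√3.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if n_frames < 2:
        raise ValueError("need at least two frames")
    rng = np.random.default_rng(seed)
    profile = {}
    for a in base.atoms:
        s = sigma
        if sigma_profile and a.residue_key in sigma_profile:
            s = sigma_profile[a.residue_key]
        profile[a.residue_key] = s
    frames = []
    for t in range(n_frames):
        atoms = []
        for a in base.atoms:
            s = profile[a.residue_key]
            d = rng.normal(0.0, s, 3) if s > 0 else np.zeros(3)
            atoms.append(
                AtomRecord(
                    a.chain_id, a.residue_number, a.insertion_code,
                    a.residue_name, a.atom_name, a.element,
                    a.x + d[0], a.y + d[1], a.z + d[2], a.vdw,
                )
            )
        frames.append(StructureModel(str(t + 1), tuple(atoms)))
    truth = GroundTruth(
        "ensemble",
        {
            "n_frames": n_frames,
            "sigma_per_residue": {
                "|".join(map(str, k)): v for k, v in profile.items()
            },
            "expected_rmsf_factor": float(np.sqrt(3.0)),
        },
    )
    return frames, truth


# -- sensorgrams -------------------------------------------------------------

def make_sensorgram_set(
    kon: float = 1e5,
    koff: float = 1.5e-4,
    rmax: float = 1.0,
    top_concentration: float = 125e-9,
    n_dilutions: int = 7,
    dilution_factor: float = 2.0,
    t_assoc: float = 180.0,
    t_dissoc: float = 180.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[SensorgramSet, GroundTruth]:
    """A 1:1 dilution-series sensorgram set with known rates.

    Defaults follow the modelled assay: a two-fold serial dilution from
    125 nM, 180 s association and dissociation, and a low-nanomolar KD
    (1.5 nM with the default rates).
    """
    concs = [
        top_concentration / dilution_factor**i for i in range(n_dilutions)
    ]
    sset = simulate_sensorgrams(
        kon, koff, rmax, concs, t_assoc, t_dissoc, noise_sd, seed
    )
    truth = GroundTruth(
        "sensorgram_set",
        {
            "kon": kon, "koff": koff, "kd": koff / kon, "rmax": rmax,
            "concentrations": concs, "noise_sd": noise_sd,
        },
    )
    return sset, truth


# -- synthetic Fab-like complexes (stand-ins for the deposited structures) ---

def make_framework_bsa_complex() -> tuple[StructureModel, GroundTruth, dict]:
    """Synthetic Fab-like interface whose framework BSA share is ≈44%.

    Thirty identical buried atom pairs (antibody bead against antigen bead
    at 4.5 Å) are distributed so that Kabat-framework residues carry 13 of
    the 30 buried antibody atoms (43.3% of antibody-side BSA, emulating the
    ~44% framework share of the parental complex) and the light-chain
    framework residues 60 (Lys) and 66 (Arg) each carry two buried atoms —
    strictly the largest per-residue framework BSA, as in the parental
    Fab–antigen structure.  Returns (model, truth, region_annotation).
    """
    atoms: list[AtomRecord] = []
    annotation: dict = {}
    x = 0.0

    def add_pair(ab_chain, resnum, resname, atom_name, antigen_chain):
        nonlocal x
        atoms.append(_atom(ab_chain, resnum, resname, atom_name, "C", (x, 0.0, 0.0)))
        atoms.append(_atom(antigen_chain, int(x) + 1, "GLY", "CA", "C", (x, 0.0, 4.5)))
        x += 10.0

    # heavy-chain CDR units: Kabat CDR-H3 (95-101) and CDR-H1 (31-32)
    for resnum in (95, 96, 97, 98, 99, 100, 101, 31, 32):
        add_pair("H", resnum, "GLY", "CA", "C")
        annotation[("H", resnum, "")] = "CDR3" if resnum >= 95 else "CDR1"
    # light-chain CDR units: Kabat CDR-L1 (24-31)
    for resnum in (24, 25, 26, 27, 28, 29, 30, 31):
        add_pair("L", resnum, "GLY", "CA", "C")
        annotation[("L", resnum, "")] = "CDR1"
    # light-chain framework units (Kabat FR3), one buried atom each
    for resnum in (57, 58, 59, 61, 62, 67, 68, 69, 70):
        add_pair("L", resnum, "SER", "CB", "D")
        annotation[("L", resnum, "")] = "FR3"
    # K60 and R66: two buried atoms each -> top framework contributors
    for resnum, resname, names in ((60, "LYS", ("CE", "NZ")), (66, "ARG", ("CZ", "NH1"))):
        for name in names:
            atoms.append(
                _atom("L", resnum, resname, name, "C" if name[0] == "C" else "N",
                      (x, 0.0, 0.0))
            )
            atoms.append(_atom("D", int(x) + 1, "GLY", "CA", "C", (x, 0.0, 4.5)))
            x += 10.0
        annotation[("L", resnum, "")] = "FR3"
    model = StructureModel(
        "framework_bsa_complex", tuple(atoms)
    ).with_partition({"H", "L"}, {"C", "D"})
    truth = GroundTruth(
        "toy_interface",
        {
            "framework_buried_atoms": 13,
            "total_buried_atoms": 30,
            # nitrogen's smaller radius buries slightly less than 13/30
            "expected_framework_fraction": 0.43,
            "top_framework_residues": [["L", 60], ["L", 66]],
        },
    )
    return model, truth, annotation


def make_key_contact_complex() -> tuple[StructureModel, GroundTruth]:
    """Synthetic stand-in for the parental Fab light-chain antigen contacts.

    Plants the two hallmark interactions at bead resolution with the
    parental structure's residue labels: light-chain Lys60 NZ in a salt
    bridge with Glu65 of the antigen β chain (chain B), and Arg66 NH1
    hydrogen-bonded to the Pro81 main-chain carbonyl of the antigen α chain
    (chain A).
    """
    atoms = [
        # L-K60 side chain against B-E65 carboxylate (salt bridge, 3.0 Å)
        _atom("L", 60, "LYS", "CE", "C", (0.0, 0.0, 1.5)),
        _atom("L", 60, "LYS", "NZ", "N", (0.0, 0.0, 0.0)),
        _atom("B", 65, "GLU", "OE1", "O", (0.0, 0.0, -3.0)),
        _atom("B", 65, "GLU", "OE2", "O", (1.2, 0.0, -3.4)),
        _atom("B", 65, "GLU", "CD", "C", (0.6, 0.0, -4.0)),
        # L-R66 guanidinium donor to A-P81 backbone carbonyl (H-bond, 2.9 Å)
        _atom("L", 66, "ARG", "CZ", "C", (12.0, 0.0, 1.4)),
        _atom("L", 66, "ARG", "NH1", "N", (12.0, 0.0, 0.0)),
        _atom("A", 81, "PRO", "O", "O", (12.0, 0.0, -2.9)),
        _atom("A", 81, "PRO", "C", "C", (12.9, 0.0, -3.5)),
        _atom("A", 81, "PRO", "CA", "C", (12.9, 0.0, -5.0)),
    ]
    model = StructureModel(
        "key_contact_complex", tuple(atoms)
    ).with_partition({"L"}, {"A", "B"})
    truth = GroundTruth(
        "toy_interface",
        {
            "contacts": [
                {"type": "salt_bridge", "residue_a": ["L", 60], "residue_b": ["B", 65]},
                {"type": "hbond", "residue_a": ["L", 66], "residue_b": ["A", 81]},
            ]
        },
    )
    return model, truth


def make_hcdr3_displacement_set(
    loose_max_shift: float = 5.0, tight_max_shift: float = 0.25, seed: int = 0
) -> tuple[StructureModel, StructureModel, StructureModel, GroundTruth]:
    """Parental-like heavy chain plus two graft-like variants.

    The parental model carries Kabat-numbered Cα beads for framework
    stretches and the CDR-H3 loop (95–102).  The "loose" variant displaces
    the HCDR3 beads by up to ``loose_max_shift`` Å (a poorly supported
    graft, HCDR3 swung away as in the V14-type structure); the "tight"
    variant by at most ``tight_max_shift`` Å (a well-supported graft,
    V21-type).  Both variants additionally undergo arbitrary rigid motions,
    which framework-anchored superposition must remove.
    """
    rng = np.random.default_rng(seed)
    fr_residues = list(range(66, 95)) + list(range(103, 114))  # Kabat FR3+FR4
    cdr3_residues = list(range(95, 103))
    atoms = []
    for i, resnum in enumerate(fr_residues):
        xyz = (3.8 * i, 1.6 * (i % 2), 0.9 * (i % 3))
        atoms.append(_atom("H", resnum, "ALA", "CA", "C", xyz))
    base_x = 3.8 * len(fr_residues)
    for i, resnum in enumerate(cdr3_residues):
        xyz = (base_x + 3.0 * i, 6.0, 2.0 * (i % 2))
        atoms.append(_atom("H", resnum, "GLY", "CA", "C", xyz))
    parental = StructureModel("parental", tuple(atoms))

    def displaced(tag: str, max_shift: float, rot_seed: int):
        r = np.random.default_rng(rot_seed)
        shifts = {}
        new_atoms = []
        for a in parental.atoms:
            xyz = np.array([a.x, a.y, a.z])
            if a.residue_number in cdr3_residues:
                # ramp: largest displacement at the loop apex
                i = cdr3_residues.index(a.residue_number)
                apex = 1.0 - abs(i - 3.5) / 3.5
                mag = max_shift * (0.3 + 0.7 * apex)
                xyz = xyz + np.array([0.0, mag, 0.0])
                shifts[a.residue_number] = float(mag)
            else:
                shifts.setdefault(a.residue_number, 0.0)
            new_atoms.append(
                AtomRecord(
                    a.chain_id, a.residue_number, a.insertion_code,
                    a.residue_name, a.atom_name, a.element,
                    xyz[0], xyz[1], xyz[2], a.vdw,
                )
            )
        # arbitrary rigid motion
        from scipy.spatial.transform import Rotation

        R = Rotation.random(random_state=rot_seed).as_matrix()
        t = r.uniform(-20, 20, 3)
        moved = []
        for a in new_atoms:
            xyz = R @ np.array([a.x, a.y, a.z]) + t
            moved.append(
                AtomRecord(
                    a.chain_id, a.residue_number, a.insertion_code,
                    a.residue_name, a.atom_name, a.element,
                    xyz[0], xyz[1], xyz[2], a.vdw,
                )
            )
        return StructureModel(tag, tuple(moved)), shifts

    loose, loose_shifts = displaced("loose_graft", loose_max_shift, seed + 1)
    tight, tight_shifts = displaced("tight_graft", tight_max_shift, seed + 2)
    truth = GroundTruth(
        "toy_interface",
        {
            "framework_residues": fr_residues,
            "hcdr3_residues": cdr3_residues,
            "loose_shifts": loose_shifts,
            "tight_shifts": tight_shifts,
        },
    )
    return parental, loose, tight, truth


# -- dispatcher --------------------------------------------------------------

def make_fixture(spec: FixtureSpec):
    """Dispatch a :class:`FixtureSpec` to its generator."""
    p = dict(spec.parameters)
    if spec.kind == "sequence_set":
        return make_sequence_set(seed=spec.seed, **p)
    if spec.kind == "two_sphere":
        return make_two_sphere(**p)
    if spec.kind == "shell":
        return make_shell(**p)
    if spec.kind == "toy_interface":
        return make_toy_interface(seed=spec.seed, **p)
    if spec.kind == "ensemble":
        base = p.pop("base", None) or make_bead_chain(p.pop("n_residues", 20))
        return make_jittered_ensemble(base, seed=spec.seed, **p)
    if spec.kind == "sensorgram_set":
        return make_sensorgram_set(seed=spec.seed, **p)
    raise ValueError(spec.kind)
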