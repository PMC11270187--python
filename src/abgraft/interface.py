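"""Protein–protein interface analysis: buried surface area and contacts.

Per-residue BSA follows the side-alone-minus-complex convention: each
partition side's SASA is computed in isolation and in the complex, and the
loss is attributed per residue.  Typed contacts are detected from
heavy-atom geometry with the precedence salt_bridge > hbond > hydrophobic >
vdw; the cutoffs default to common practice and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .sasa import DEFAULT_N_POINTS, DEFAULT_PROBE_RADIUS, compute_sasa
from .structure import AtomRecord, ResidueKey, StructureModel

# -- residue chemistry (heavy-atom rules) ------------------------------------

# positively / negatively charged side-chain groups
CHARGED_GROUPS: dict[str, tuple[int, tuple[str, ...]]] = {
    "LYS": (+1, ("NZ",)),
    "ARG": (+1, ("NE", "NH1", "NH2")),
    "HIS": (+1, ("ND1", "NE2")),
    "ASP": (-1, ("OD1", "OD2")),
    "GLU": (-1, ("OE1", "OE2")),
}

_SIDECHAIN_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "ASN": {"ND2"},
    "GLN": {"NE2"}, "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"},
    "TRP": {"NE1"}, "HIS": {"ND1", "NE2"}, "CYS": {"SG"},
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}
# side-chain carbons bonded only to carbon/hydrogen
_APOLAR_CARBONS = {
    "ALA": {"CB"},
    "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "ILE": {"CB", "CG1", "CG2", "CD1"},
    "PRO": {"CB", "CG", "CD"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"},
    "MET": {"CB", "CG", "CE"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
    "LYS": {"CB", "CG", "CD"},
    "ARG": {"CB", "CG"},
    "GLU": {"CB", "CG"},
    "GLN": {"CB", "CG"},
    "ASP": {"CB"},
    "ASN": {"CB"},
    "HIS": {"CB"},
    "THR": {"CG2"},
    "CYS": {"CB"},
}


def is_hbond_donor(atom: AtomRecord) -> bool:
    if atom.atom_name == "N":  # backbone amide
        return True
    return atom.atom_name in _SIDECHAIN_DONORS.get(atom.residue_name, ())


def is_hbond_acceptor(atom: AtomRecord) -> bool:
    if atom.atom_name in ("O", "OXT"):  # backbone carbonyl / terminus
        return True
    return atom.atom_name in _SIDECHAIN_ACCEPTORS.get(atom.residue_name, ())


def is_apolar_carbon(atom: AtomRecord) -> bool:
    return atom.atom_name in _APOLAR_CARBONS.get(atom.residue_name, ())


@dataclass(frozen=True)
class ContactConfig:
    """Geometric cutoffs (Å / degrees) for typed contact detection."""

    hbond_max_dist: float = 3.5
    hbond_min_angle: float = 100.0  # donor angle, applied when H present
    salt_bridge_max_dist: float = 4.5  # charged-group centroid distance
    hydrophobic_max_dist: float = 4.0  # apolar carbon–carbon
    vdw_slack: float = 0.5  # added to sum of vdW radii

    def max_reach(self, max_radius: float) -> float:
        return max(
            self.hbond_max_dist,
            self.salt_bridge_max_dist,
            self.hydrophobic_max_dist,
            2 * max_radius + self.vdw_slack,
        )


CONTACT_TYPE_PRECEDENCE = ("salt_bridge", "hbond", "hydrophobic", "vdw")


@dataclass(frozen=True)
class Contact:
    """A typed atom–atom contact across the declared partition."""

    type: str
    atom_a: AtomRecord
    atom_b: AtomRecord
    distance: float
    angle: Optional[float] = None

    def involves_residue(self, key: ResidueKey) -> bool:
        return self.atom_a.residue_key == key or self.atom_b.residue_key == key


@dataclass(frozen=True)
class InterfaceReport:
    """Per-residue BSA and contacts across a two-sided chain partition.

    ``fraction_bsa_by_region_class`` is reported over side A (by convention
    the antibody side) when a region annotation is supplied, with classes
    ``CDR`` and ``framework`` summing to 1.
    """

    model: StructureModel
    per_residue_bsa: dict[ResidueKey, float]
    side_of_residue: dict[ResidueKey, int]
    total_bsa_side: tuple[float, float]
    contacts: tuple[Contact, ...] = ()
    region_annotation: Optional[dict[ResidueKey, str]] = None
    fraction_bsa_by_region_class: Optional[dict[str, float]] = None
    probe_radius: float = DEFAULT_PROBE_RADIUS
    n_sphere_points: int = DEFAULT_N_POINTS
    bsa_convention: str = "side-alone-minus-complex (PISA convention)"

    def buried_residues(self, side: Optional[int] = None, min_bsa: float = 1e-9):
        items = [
            (k, v)
            for k, v in self.per_residue_bsa.items()
            if v > min_bsa and (side is None or self.side_of_residue[k] == side)
        ]
        return sorted(items, key=lambda kv: -kv[1])


def _check_partition(model: StructureModel):
    if model.chain_partition is None:
        raise ValueError("model has no chain partition; declare interface sides")
    for cid in model.chain_ids():
        model.side_of(cid)  # raises for unassigned chains


def interface_bsa(
    complex_model: StructureModel,
    region_annotation: Optional[dict[ResidueKey, str]] = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    contacts: bool = True,
    contact_config: Optional["ContactConfig"] = None,
) -> InterfaceReport:
    """Per-residue buried surface area across the declared partition.

    BSA(residue) = SASA(residue, own side alone) − SASA(residue, complex),
    clamped at zero against numeric noise.  When ``region_annotation`` maps
    residues (of side A) to FR/CDR region names, the report includes the
    fraction of side-A BSA contributed by CDR vs framework residues.
    """
    _check_partition(complex_model)
    side_models = [
        complex_model.subset(group) for group in complex_model.chain_partition
    ]
    sasa_complex = compute_sasa(complex_model, probe_radius, n_points).per_residue()
    per_residue: dict[ResidueKey, float] = {}
    side_of: dict[ResidueKey, int] = {}
    totals = [0.0, 0.0]
    for side, sm in enumerate(side_models):
        alone = compute_sasa(sm, probe_radius, n_points).per_residue()
        for key, area in alone.items():
            bsa = max(0.0, area - sasa_complex.get(key, 0.0))
            if bsa < 1e-9:
                bsa = 0.0
            per_residue[key] = bsa
            side_of[key] = side
            totals[side] += bsa
    fractions = None
    if region_annotation is not None:
        cdr = fr = 0.0
        for key, bsa in per_residue.items():
            if side_of[key] != 0 or bsa == 0.0:
                continue
            region = region_annotation.get(key)
            if region is None:
                raise ValueError(
                    f"buried residue {key} of side A has no region annotation"
                )
            if region.startswith("CDR"):
                cdr += bsa
            else:
                fr += bsa
        tot = cdr + fr
        fractions = {
            "CDR": cdr / tot if tot else 0.0,
            "framework": fr / tot if tot else 0.0,
        }
    found = (
        tuple(detect_contacts(complex_model, contact_config or ContactConfig()))
        if contacts
        else ()
    )
    return InterfaceReport(
        model=complex_model,
        per_residue_bsa=per_residue,
        side_of_residue=side_of,
        total_bsa_side=(totals[0], totals[1]),
        contacts=found,
        region_annotation=region_annotation,
        fraction_bsa_by_region_class=fractions,
        probe_radius=probe_radius,
        n_sphere_points=n_points,
    )


def _charged_group_centroids(model: StructureModel):
    """(residue_key, sign, centroid, member atom indices) per charged group."""
    groups = []
    residues: dict[ResidueKey, list[int]] = {}
    for i, a in enumerate(model.atoms):
        residues.setdefault(a.residue_key, []).append(i)
    for key, idxs in residues.items():
        name = model.atoms[idxs[0]].residue_name
        if name not in CHARGED_GROUPS:
            continue
        sign, names = CHARGED_GROUPS[name]
        members = [i for i in idxs if model.atoms[i].atom_name in names]
        if not members:
            continue
        centroid = np.mean([model.atoms[i].coords for i in members], axis=0)
        groups.append((key, sign, centroid, members))
    return groups


def _donor_angle(
    model: StructureModel, donor: AtomRecord, acceptor: AtomRecord
) -> Optional[float]:
    """Smallest-deviation D–H…A angle using explicit hydrogens, if any."""
    hydrogens = [
        a
        for a in model.atoms
        if a.residue_key == donor.residue_key
        and a.element == "H"
        and float(np.linalg.norm(a.coords - donor.coords)) < 1.3
    ]
    if not hydrogens:
        return None
    best = None
    for h in hydrogens:
        v1 = donor.coords - h.coords
        v2 = acceptor.coords - h.coords
        cosang = float(
            np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        )
        ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        if best is None or ang > best:
            best = ang
    return best


def detect_contacts(
    model: StructureModel, config: Optional[ContactConfig] = None
) -> list[Contact]:
    """Typed cross-partition contacts, deterministically ordered.

    Each heavy-atom pair is typed by the first matching rule in the
    precedence salt_bridge > hbond > hydrophobic > vdw.  Salt bridges are
    recognized group-wise (oppositely charged side-chain groups whose
    centroids lie within the cutoff) and reported on the closest atom pair
    of the two groups.
    """
    cfg = config or ContactConfig()
    _check_partition(model)
    heavy = [(i, a) for i, a in enumerate(model.atoms) if a.element != "H"]
    if not heavy:
        return []
    sides = {i: model.side_of(a.chain_id) for i, a in heavy}

    # group-wise salt-bridge membership
    groups = _charged_group_centroids(model)
    salt_pairs: set[tuple[int, int]] = set()
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            ka, sa, ca, ma = groups[gi]
            kb, sb, cb, mb = groups[gj]
            if sa * sb >= 0:
                continue
            if model.side_of(ka[0]) == model.side_of(kb[0]):
                continue
            if float(np.linalg.norm(ca - cb)) > cfg.salt_bridge_max_dist:
                continue
            for i in ma:
                for j in mb:
                    salt_pairs.add((min(i, j), max(i, j)))

    idxs = [i for i, _ in heavy]
    coords = np.array([[a.x, a.y, a.z] for _, a in heavy])
    tree = cKDTree(coords)
    reach = cfg.max_reach(max(a.vdw for _, a in heavy))
    contacts: list[Contact] = []
    seen_salt_groups: set[tuple[ResidueKey, ResidueKey]] = set()
    for ii, jj in sorted(tree.query_pairs(reach)):
        i, j = idxs[ii], idxs[jj]
        if sides[i] == sides[j]:
            continue
        a, b = model.atoms[i], model.atoms[j]
        if sides[i] == 1:  # orient: atom_a from side A
            a, b = b, a
        d = float(np.linalg.norm(a.coords - b.coords))
        pair = (min(i, j), max(i, j))
        ctype = None
        angle = None
        if pair in salt_pairs:
            gk = (a.residue_key, b.residue_key)
            if gk in seen_salt_groups:
                continue  # one contact per salt-bridge group pair
            # report the closest atom pair of the two groups
            best = None
            for pi, pj in salt_pairs:
                aa, bb = model.atoms[pi], model.atoms[pj]
                if {aa.residue_key, bb.residue_key} != {a.residue_key, b.residue_key}:
                    continue
                dd = float(np.linalg.norm(aa.coords - bb.coords))
                if best is None or dd < best[0]:
                    if model.side_of(aa.chain_id) == 1:
                        aa, bb = bb, aa
                    best = (dd, aa, bb)
            seen_salt_groups.add(gk)
            d, a, b = best
            ctype = "salt_bridge"
        else:
            hbond_ok = False
            if d <= cfg.hbond_max_dist and (
                (is_hbond_donor(a) and is_hbond_acceptor(b))
                or (is_hbond_donor(b) and is_hbond_acceptor(a))
            ):
                angle_ab = _donor_angle(model, a, b) if is_hbond_donor(a) else None
                angle_ba = _donor_angle(model, b, a) if is_hbond_donor(b) else None
                candidates = [
                    ang for ang in (angle_ab, angle_ba) if ang is not None
                ]
                if candidates:
                    angle = max(candidates)
                    hbond_ok = angle >= cfg.hbond_min_angle
                else:
                    hbond_ok = True  # no hydrogens: distance-only criterion
            if hbond_ok:
                ctype = "hbond"
            elif (
                d <= cfg.hydrophobic_max_dist
                and is_apolar_carbon(a)
                and is_apolar_carbon(b)
            ):
                ctype = "hydrophobic"
            elif d <= a.vdw + b.vdw + cfg.vdw_slack:
                ctype = "vdw"
        if ctype is None:
            continue
        contacts.append(Contact(ctype, a, b, d, angle))
    contacts.sort(
        key=lambda c: (
            c.atom_a.chain_id, c.atom_a.residue_number, c.atom_a.insertion_code,
            c.atom_a.atom_name,
            c.atom_b.chain_id, c.atom_b.residue_number, c.atom_b.insertion_code,
            c.atom_b.atom_name,
        )
    )
    return contacts
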