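"""Framework back-mutation proposal.

The decision procedure mirrors structure-guided humanization practice:
framework positions where the humanized chain deviates from the parental
one are proposed for reversion when the parental residue either (a)
participates in the antigen interface directly — per-residue BSA at or
above a threshold, or at least one cross-interface contact — or (b) sits
in the Vernier zone, the framework shell that shapes CDR conformation.
Spatially coupled proposals (Cβ–Cβ proximity in the parental structure,
e.g. the heavy 71/78 steric pair) are cross-annotated, since reverting one
without the other can be ineffective.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .grafting import BackMutation
from .interface import Contact, InterfaceReport
from .numbering import NumberedChain
from .schemes import CDR_REGIONS, SchemePosition, get_boundary_table
from .structure import ResidueKey, StructureModel

DEFAULT_BSA_THRESHOLD = 10.0  # Å²; separates emphasized residues from grazing contacts
DEFAULT_COUPLING_CUTOFF = 8.0  # Å, Cβ–Cβ

EVIDENCE_RANK = {"contact_and_vernier": 0, "direct_contact": 1, "vernier": 2}


@dataclass(frozen=True)
class VernierTable:
    """Framework positions that indirectly shape CDR conformation."""

    scheme: str
    positions: dict[str, frozenset[int]]  # chain_class -> position numbers
    provenance: str

    def contains(self, chain_class: str, pos: SchemePosition) -> bool:
        return (
            pos.insertion_code is None
            and pos.number in self.positions.get(chain_class, frozenset())
        )


def load_vernier_table() -> VernierTable:
    """The bundled Vernier-zone table (Kabat numbering, with citation)."""
    with resources.files("abgraft.data").joinpath("vernier_zone.json").open() as fh:
        raw = json.load(fh)
    positions = {cc: frozenset(v) for cc, v in raw["positions"].items()}
    table = VernierTable(raw["scheme"], positions, raw["provenance"])
    # invariant: Vernier positions are framework positions under Kabat
    for cc, nums in table.positions.items():
        boundary = get_boundary_table(table.scheme, cc)
        for n in nums:
            if boundary.region_of_number(n) in CDR_REGIONS:
                raise ValueError(f"Vernier position {cc} {n} falls inside a CDR")
    return table


@dataclass(frozen=True)
class BackMutationProposal:
    """A proposed framework reversion with its evidence class."""

    chain: str  # "heavy" | "light"
    position: SchemePosition
    parental_aa: str
    humanized_aa: str
    evidence: str  # direct_contact | vernier | contact_and_vernier
    bsa: Optional[float] = None
    contacts: tuple[Contact, ...] = ()
    partner_note: Optional[str] = None

    def __post_init__(self):
        if self.parental_aa == self.humanized_aa:
            raise ValueError("proposal requires differing residues")
        if self.evidence not in EVIDENCE_RANK:
            raise ValueError(f"unknown evidence class {self.evidence!r}")
        if "contact" in self.evidence and not (
            (self.bsa is not None and self.bsa > 0) or self.contacts
        ):
            raise ValueError("direct-contact evidence requires BSA or contacts")

    @property
    def mutation_label(self) -> str:
        return f"{self.humanized_aa}{self.position.label}{self.parental_aa}"

    def as_back_mutation(self) -> BackMutation:
        return BackMutation(
            chain=self.chain,
            position=self.position,
            from_aa=self.humanized_aa,
            to_aa=self.parental_aa,
        )


def diff_framework(
    parental: NumberedChain, humanized: NumberedChain
) -> list[tuple[SchemePosition, str, str]]:
    """Framework positions where the two chains differ.

    Only positions present in both chains are compared; CDR positions are
    excluded.  Swapping the arguments swaps the residue columns.
    """
    if parental.scheme != humanized.scheme:
        raise ValueError(
            f"scheme mismatch: {parental.scheme} vs {humanized.scheme}"
        )
    if parental.chain_class != humanized.chain_class:
        raise ValueError("chain class mismatch")
    pmap = dict(parental.framework_items())
    hmap = dict(humanized.framework_items())
    out = [
        (pos, pmap[pos], hmap[pos])
        for pos in sorted(set(pmap) & set(hmap))
        if pmap[pos] != hmap[pos]
    ]
    return out


def _cbeta_coords(
    structure: StructureModel, residue_key: ResidueKey
) -> Optional[np.ndarray]:
    fallback = None
    for a in structure.atoms:
        if a.residue_key != residue_key:
            continue
        if a.atom_name == "CB":
            return a.coords
        if a.atom_name == "CA":
            fallback = a.coords  # glycine: use Cα
    return fallback


def propose(
    parental: NumberedChain,
    humanized: NumberedChain,
    report: Optional[InterfaceReport] = None,
    vernier: Optional[VernierTable] = None,
    bsa_threshold: float = DEFAULT_BSA_THRESHOLD,
    position_to_residue: Optional[dict[SchemePosition, ResidueKey]] = None,
    parental_structure: Optional[StructureModel] = None,
    coupling_cutoff: float = DEFAULT_COUPLING_CUTOFF,
) -> list[BackMutationProposal]:
    """Propose framework back-mutations for a humanized chain.

    A framework difference becomes a proposal iff the parental residue
    carries interface evidence (BSA ≥ ``bsa_threshold`` or ≥1 contact in
    ``report``, via ``position_to_residue``) or its position is in the
    Vernier table.  Proposals are ranked contact_and_vernier >
    direct_contact (by BSA) > vernier; spatially coupled pairs (Cβ–Cβ ≤
    ``coupling_cutoff`` in ``parental_structure``) carry partner notes.
    """
    if vernier is None:
        vernier = load_vernier_table()
    if vernier.scheme != parental.scheme:
        raise ValueError(
            f"Vernier table is {vernier.scheme}-numbered but chains use "
            f"{parental.scheme}; renumber first"
        )
    diffs = diff_framework(parental, humanized)
    chain_label = "heavy" if parental.chain_class == "heavy" else "light"
    if report is not None and position_to_residue is None:
        raise ValueError(
            "an interface report requires position_to_residue to map scheme "
            "positions onto structure residues"
        )
    proposals: list[BackMutationProposal] = []
    for pos, p_aa, h_aa in diffs:
        bsa = None
        res_contacts: tuple[Contact, ...] = ()
        if report is not None:
            key = position_to_residue.get(pos)
            if key is not None:
                bsa = report.per_residue_bsa.get(key)
                res_contacts = tuple(
                    c for c in report.contacts if c.involves_residue(key)
                )
        direct = (bsa is not None and bsa >= bsa_threshold) or bool(res_contacts)
        in_vernier = vernier.contains(parental.chain_class, pos)
        if direct and in_vernier:
            evidence = "contact_and_vernier"
        elif direct:
            evidence = "direct_contact"
        elif in_vernier:
            evidence = "vernier"
        else:
            continue
        proposals.append(
            BackMutationProposal(
                chain=chain_label,
                position=pos,
                parental_aa=p_aa,
                humanized_aa=h_aa,
                evidence=evidence,
                bsa=bsa,
                contacts=res_contacts,
            )
        )

    if parental_structure is not None and position_to_residue is not None:
        coords = {}
        for prop in proposals:
            key = position_to_residue.get(prop.position)
            if key is not None:
                c = _cbeta_coords(parental_structure, key)
                if c is not None:
                    coords[prop.position] = c
        annotated = []
        for prop in proposals:
            partners = [
                other.position.label
                for other in proposals
                if other.position != prop.position
                and prop.position in coords
                and other.position in coords
                and float(
                    np.linalg.norm(coords[prop.position] - coords[other.position])
                )
                <= coupling_cutoff
            ]
            if partners:
                prop = BackMutationProposal(
                    chain=prop.chain,
                    position=prop.position,
                    parental_aa=prop.parental_aa,
                    humanized_aa=prop.humanized_aa,
                    evidence=prop.evidence,
                    bsa=prop.bsa,
                    contacts=prop.contacts,
                    partner_note=f"coupled to position {', '.join(partners)}",
                )
            annotated.append(prop)
        proposals = annotated

    proposals.sort(
        key=lambda p: (
            EVIDENCE_RANK[p.evidence],
            -(p.bsa if p.bsa is not None else 0.0),
            p.position.number,
            p.position.insertion_code or "",
        )
    )
    return proposals


def proposals_to_json(proposals: Sequence[BackMutationProposal]) -> str:
    return json.dumps(
        [
            {
                "chain": p.chain,
                "position": p.position.label,
                "scheme": p.position.scheme,
                "parental_aa": p.parental_aa,
                "humanized_aa": p.humanized_aa,
                "mutation": p.mutation_label,
                "evidence": p.evidence,
                "bsa": p.bsa,
                "n_contacts": len(p.contacts),
                "partner_note": p.partner_note,
            }
            for p in proposals
        ],
        indent=2,
    )
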