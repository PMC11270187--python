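"""Structure container and PDB/mmCIF I/O (gemmi-backed).

The in-memory model is deliberately small: a flat list of
:class:`AtomRecord` per model, plus an optional two-group chain partition
declaring the interface sides (e.g. Fab chains vs antigen chains).  Altlocs
keep the highest-occupancy conformer; waters and non-protein hetero atoms
are excluded by default (opt-in flag to include, e.g. coordinated ions).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

ResidueKey = tuple[str, int, str]  # (chain_id, residue_number, insertion_code)


def _load_radii() -> dict[str, float]:
    with resources.files("abgraft.data").joinpath("vdw_radii.json").open() as fh:
        return {k.upper(): float(v) for k, v in json.load(fh)["radii"].items()}


_VDW = _load_radii()


def vdw_radius(element: str) -> float:
    """Bundled van der Waals radius for an element symbol."""
    try:
        return _VDW[element.upper()]
    except KeyError:
        raise KeyError(
            f"no van der Waals radius for element {element!r}; "
            "supply an override radius"
        ) from None


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, coordinates (Å) and van der Waals radius (Å)."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    vdw: float

    def __post_init__(self):
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")
        if self.vdw <= 0:
            raise ValueError(f"vdw radius must be positive, got {self.vdw}")

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class StructureModel:
    """One coordinate model with an optional two-sided chain partition."""

    model_id: str
    atoms: tuple[AtomRecord, ...]
    chain_partition: Optional[tuple[frozenset[str], frozenset[str]]] = None

    def __post_init__(self):
        if self.chain_partition is not None:
            a, b = self.chain_partition
            if not a or not b:
                raise ValueError("partition groups must be non-empty")
            if a & b:
                raise ValueError(f"partition groups overlap: {sorted(a & b)}")
        seen = set()
        for at in self.atoms:
            key = (at.chain_id, at.residue_number, at.insertion_code, at.atom_name)
            if key in seen:
                raise ValueError(f"duplicate atom {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms])

    def radii(self) -> np.ndarray:
        return np.array([a.vdw for a in self.atoms])

    def chain_ids(self) -> list[str]:
        out = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def subset(self, chain_ids: Iterable[str]) -> "StructureModel":
        wanted = set(chain_ids)
        return StructureModel(
            model_id=self.model_id,
            atoms=tuple(a for a in self.atoms if a.chain_id in wanted),
        )

    def with_partition(self, side_a: Iterable[str], side_b: Iterable[str]) -> "StructureModel":
        return replace(
            self, chain_partition=(frozenset(side_a), frozenset(side_b))
        )

    def residues(self) -> dict[ResidueKey, list[AtomRecord]]:
        out: dict[ResidueKey, list[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, []).append(a)
        return out

    def residue_names(self) -> dict[ResidueKey, str]:
        return {a.residue_key: a.residue_name for a in self.atoms}

    def side_of(self, chain_id: str) -> int:
        if self.chain_partition is None:
            raise ValueError("model has no chain partition")
        if chain_id in self.chain_partition[0]:
            return 0
        if chain_id in self.chain_partition[1]:
            return 1
        raise ValueError(f"chain {chain_id!r} not in either partition group")


def _pick_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy conformer per atom name."""
    best: dict[str, gemmi.Atom] = {}
    for at in res:
        cur = best.get(at.name)
        if cur is None or at.occ > cur.occ:
            best[at.name] = at
    return list(best.values())


def _convert_model(
    model: gemmi.Model,
    include_hetero: bool,
    include_hydrogens: bool,
    radius_overrides: Optional[dict[str, float]],
) -> StructureModel:
    atoms = []
    for chain in model:
        for res in chain:
            if res.is_water():
                continue
            if res.het_flag == "H" and not include_hetero:
                continue
            for at in _pick_altloc(res):
                elem = at.element.name.upper()
                if elem == "H" and not include_hydrogens:
                    continue
                if radius_overrides and elem in radius_overrides:
                    r = radius_overrides[elem]
                else:
                    r = vdw_radius(elem)
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        residue_name=res.name,
                        atom_name=at.name,
                        element=elem,
                        x=at.pos.x, y=at.pos.y, z=at.pos.z,
                        vdw=r,
                    )
                )
    return StructureModel(model_id=str(model.num), atoms=tuple(atoms))


def read_structure(
    path,
    include_hetero: bool = False,
    include_hydrogens: bool = False,
    radius_overrides: Optional[dict[str, float]] = None,
) -> StructureModel:
    """Read the first model of a PDB or mmCIF file."""
    return read_ensemble(
        path, include_hetero, include_hydrogens, radius_overrides
    )[0]


def read_ensemble(
    path,
    include_hetero: bool = False,
    include_hydrogens: bool = False,
    radius_overrides: Optional[dict[str, float]] = None,
) -> list[StructureModel]:
    """Read all models (e.g. a multi-model PDB coordinate ensemble)."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    models = [
        _convert_model(m, include_hetero, include_hydrogens, radius_overrides)
        for m in st
    ]
    if not models:
        raise ValueError(f"no models in {path}")
    return models


def write_pdb(path, models: Sequence[StructureModel] | StructureModel) -> None:
    """Write one or more models as a (multi-model) PDB file."""
    if isinstance(models, StructureModel):
        models = [models]
    st = gemmi.Structure()
    st.name = "abgraft"
    for k, model in enumerate(models, start=1):
        gm = gemmi.Model(k)
        chains: dict[str, gemmi.Chain] = {}
        for a in model.atoms:
            ch = chains.get(a.chain_id)
            if ch is None:
                ch = gemmi.Chain(a.chain_id)
                chains[a.chain_id] = ch
            if (
                len(ch) == 0
                or ch[-1].seqid.num != a.residue_number
                or (ch[-1].seqid.icode or "").strip() != a.insertion_code
            ):
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
                ch.add_residue(res)
            res = ch[-1]
            at = gemmi.Atom()
            at.name = a.atom_name
            at.element = gemmi.Element(a.element.capitalize())
            at.pos = gemmi.Position(a.x, a.y, a.z)
            at.occ = 1.0
            res.add_atom(at)
        for ch in chains.values():
            gm.add_chain(ch)
        st.add_model(gm)
    st.write_pdb(str(path))
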