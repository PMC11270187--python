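"""Rigid superposition, per-residue RMSD and ensemble RMSF.

Superposition uses the Kabsch least-squares algorithm on a fit selection
(framework Cα by default in the humanization workflow); per-residue RMSD is
then reported over all mapped residues, so displacement of loops excluded
from the fit (e.g. HCDR3) is measured in the frame of the stable scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .structure import AtomRecord, ResidueKey, StructureModel


class SuperpositionError(ValueError):
    pass


def kabsch(
    reference: np.ndarray, mobile: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation + translation mapping mobile onto reference.

    Returns (R, t) with det(R) = +1 such that ``mobile @ R.T + t`` minimizes
    the RMSD to ``reference``.
    """
    if reference.shape != mobile.shape or reference.shape[0] < 3:
        raise SuperpositionError("need >=3 paired atoms of equal count")
    ref_c = reference.mean(axis=0)
    mob_c = mobile.mean(axis=0)
    A = (reference - ref_c).T @ (mobile - mob_c)
    U, S, Vt = np.linalg.svd(A)
    if S[1] < 1e-10:
        raise SuperpositionError("degenerate (collinear) fit selection")
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    t = ref_c - R @ mob_c
    return R, t


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, orthonormal, det=+1
    translation: np.ndarray  # Å
    fit_atom_count: int
    fit_rmsd: float
    per_residue_rmsd: dict[ResidueKey, float]  # keyed by reference residue

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _atom_lookup(model: StructureModel) -> dict[tuple[ResidueKey, str], AtomRecord]:
    return {(a.residue_key, a.atom_name): a for a in model.atoms}


def superpose(
    reference: StructureModel,
    mobile: StructureModel,
    fit_residues: Optional[Iterable[ResidueKey]] = None,
    residue_map: Optional[dict[ResidueKey, ResidueKey]] = None,
    fit_atom_names: Sequence[str] = ("CA",),
    rmsd_atom_names: Sequence[str] = ("CA",),
) -> SuperpositionResult:
    """Superpose ``mobile`` onto ``reference`` and report per-residue RMSD.

    ``fit_residues`` are reference residue keys used for the rigid fit
    (all mapped residues when omitted); ``residue_map`` maps reference
    residue keys to mobile keys (identity when omitted).  Per-residue RMSD
    is computed over ``rmsd_atom_names`` for every mapped residue after the
    transform.
    """
    ref_atoms = _atom_lookup(reference)
    mob_atoms = _atom_lookup(mobile)
    ref_keys = sorted({a.residue_key for a in reference.atoms})
    if residue_map is None:
        residue_map = {k: k for k in ref_keys}
    fit_set = set(fit_residues) if fit_residues is not None else set(residue_map)

    ref_fit, mob_fit = [], []
    for rkey in sorted(fit_set):
        mkey = residue_map.get(rkey)
        if mkey is None:
            continue
        for name in fit_atom_names:
            ra = ref_atoms.get((rkey, name))
            ma = mob_atoms.get((mkey, name))
            if ra is not None and ma is not None:
                ref_fit.append(ra.coords)
                mob_fit.append(ma.coords)
    if len(ref_fit) < 3:
        raise SuperpositionError(
            f"only {len(ref_fit)} mapped fit atoms; need at least 3"
        )
    ref_fit = np.array(ref_fit)
    mob_fit = np.array(mob_fit)
    R, t = kabsch(ref_fit, mob_fit)
    fit_rmsd = float(
        np.sqrt(((mob_fit @ R.T + t - ref_fit) ** 2).sum(axis=1).mean())
    )

    per_res: dict[ResidueKey, float] = {}
    for rkey, mkey in residue_map.items():
        sq = []
        for name in rmsd_atom_names:
            ra = ref_atoms.get((rkey, name))
            ma = mob_atoms.get((mkey, name))
            if ra is None or ma is None:
                continue
            moved = R @ ma.coords + t
            sq.append(((moved - ra.coords) ** 2).sum())
        if sq:
            per_res[rkey] = float(np.sqrt(np.mean(sq)))
    return SuperpositionResult(
        rotation=R,
        translation=t,
        fit_atom_count=len(ref_fit),
        fit_rmsd=fit_rmsd,
        per_residue_rmsd=per_res,
    )


@dataclass(frozen=True)
class EnsembleRmsf:
    """Per-residue root-mean-square fluctuation over an ensemble (Å)."""

    per_residue: dict[ResidueKey, float]
    n_frames: int
    atom_selection: str


def ensemble_rmsf(
    frames: Sequence[StructureModel],
    atom_name: str = "CA",
    align: bool = True,
    align_iterations: int = 2,
) -> EnsembleRmsf:
    """RMSF of each selected atom's residue across ensemble frames.

    RMSF_i = sqrt(mean_t |x_i(t) − x̄_i|²), optionally after iteratively
    superposing every frame onto the ensemble mean (default on, as for MD
    trajectory analysis; disable for pre-aligned ensembles).
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    keys0 = [a.residue_key for a in frames[0].atoms if a.atom_name == atom_name]
    if not keys0:
        raise ValueError(f"no atoms named {atom_name!r} in first frame")
    coords = []
    for f in frames:
        sel = [a for a in f.atoms if a.atom_name == atom_name]
        keys = [a.residue_key for a in sel]
        if keys != keys0:
            raise ValueError("frames have mismatching atom topology on selection")
        coords.append(np.array([[a.x, a.y, a.z] for a in sel]))
    X = np.array(coords)  # (T, N, 3)
    if align:
        for _ in range(align_iterations):
            mean = X.mean(axis=0)
            for ti in range(X.shape[0]):
                R, t = kabsch(mean, X[ti])
                X[ti] = X[ti] @ R.T + t
    mean = X.mean(axis=0)
    rmsf = np.sqrt(((X - mean) ** 2).sum(axis=2).mean(axis=0))
    return EnsembleRmsf(
        per_residue={k: float(v) for k, v in zip(keys0, rmsf)},
        n_frames=len(frames),
        atom_selection=atom_name,
    )
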