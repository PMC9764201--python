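"""Structural quality metrics for NMR ensembles.

Two light-weight metrics validate a solution-NMR ensemble:

* coordinate precision — each model is superposed (Kabsch least-squares
  rigid-body fit) onto the iteratively refined mean structure over a
  backbone selection, and the RMSD to the mean is averaged over models;
  the mean pairwise inter-model RMSD is reported alongside, since
  depositions differ in which convention they quote;
* RDC agreement — the five independent elements of the Saupe alignment
  tensor are fitted to measured residual dipolar couplings by linear
  least squares (SVD), back-calculated couplings follow from the tensor,
  and the quality factor is Q = RMS(D_meas - D_calc) / RMS(D_meas).

PDB ensembles (MODEL/ENDMDL records) are read through gemmi.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "AtomRecord",
    "Model",
    "Ensemble",
    "RDCSet",
    "BACKBONE_ATOMS",
    "kabsch",
    "superpose",
    "ensemble_rmsd",
    "fit_alignment_tensor",
    "q_factor",
    "read_pdb_ensemble",
]

#: Backbone selection used for precision statistics.
BACKBONE_ATOMS = ("N", "CA", "C", "O")
#: Heavy backbone without carbonyl oxygen, the other common convention.
BACKBONE_ATOMS_NO_O = ("N", "CA", "C")

AtomRecord = Tuple[int, str, np.ndarray]


@dataclass
class Model:
    """One structural model: parallel arrays of residue index, atom name, xyz (A)."""

    res_ids: np.ndarray
    atom_names: List[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.atom_names) != self.res_ids.size or self.coords.shape[0] != self.res_ids.size:
            raise ValueError("res_ids, atom_names and coords must align")

    def select(self, residues: Optional[Tuple[int, int]] = None,
               atoms: Optional[Sequence[str]] = None) -> np.ndarray:
        """Boolean mask for an inclusive residue range and atom-name set."""
        mask = np.ones(self.res_ids.size, dtype=bool)
        if residues is not None:
            lo, hi = residues
            mask &= (self.res_ids >= lo) & (self.res_ids <= hi)
        if atoms is not None:
            aset = set(atoms)
            mask &= np.array([a in aset for a in self.atom_names])
        return mask


@dataclass
class Ensemble:
    """Ordered models sharing one atom set after selection."""

    models: List[Model]

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("empty ensemble")


@dataclass
class RDCSet:
    """Measured couplings (Hz) with internuclear unit vectors.

    ``d_calc`` is filled by :func:`fit_alignment_tensor`.
    """

    vectors: np.ndarray  # (n, 3) unit vectors
    d_meas: np.ndarray  # Hz
    d_calc: Optional[np.ndarray] = None
    residues: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float).reshape(-1, 3)
        self.d_meas = np.asarray(self.d_meas, dtype=float)
        if self.vectors.shape[0] != self.d_meas.size:
            raise ValueError("vectors and d_meas must align")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-length internuclear vector")
        self.vectors = self.vectors / norms[:, None]


# ------------------------------------------------------------- superposition


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid-body fit of ``mobile`` onto ``reference``.

    Returns (rotation 3x3, translation 3, rmsd).  Proper rotations only
    (the reflection branch of the SVD is corrected by the determinant
    sign).
    """
    p = np.asarray(mobile, float)
    q = np.asarray(reference, float)
    if p.shape != q.shape or p.shape[0] < 3:
        raise ValueError("need >= 3 matched atoms with identical shapes")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    h = p0.T @ q0
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) selection: rotation undefined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = p0 @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q0) ** 2, axis=1))))
    trans = qc - rot @ pc
    return rot, trans, rmsd


def superpose(mobile: Model, reference: Model,
              residues: Optional[Tuple[int, int]] = None,
              atoms: Optional[Sequence[str]] = None) -> tuple[Model, float]:
    """Superpose ``mobile`` onto ``reference`` over a selection.

    Atoms are matched by (residue index, atom name); the fitted transform
    is applied to all atoms of ``mobile``.  Returns the transformed model
    and the RMSD over the matched selection.
    """
    key_m = {(r, a): i for i, (r, a) in enumerate(zip(mobile.res_ids, mobile.atom_names))}
    sel_ref = reference.select(residues, atoms)
    idx_m, idx_r = [], []
    for i in np.flatnonzero(sel_ref):
        k = (int(reference.res_ids[i]), reference.atom_names[i])
        if k in key_m:
            idx_m.append(key_m[k])
            idx_r.append(i)
    if len(idx_m) < 3:
        raise ValueError("fewer than 3 matched atoms in selection")
    rot, trans, rmsd = kabsch(mobile.coords[idx_m], reference.coords[idx_r])
    moved = Model(mobile.res_ids.copy(), list(mobile.atom_names),
                  mobile.coords @ rot.T + trans)
    return moved, rmsd


def ensemble_rmsd(
    ens: Ensemble,
    residues: Tuple[int, int] = (85, 149),
    atoms: Sequence[str] = BACKBONE_ATOMS,
    max_iter: int = 10,
) -> tuple[float, float]:
    """(mean pairwise RMSD, mean RMSD to the mean structure) over a selection.

    All models are superposed onto an iteratively recomputed mean
    structure of the selection; both precision conventions are returned
    so either can be compared with a deposition's quoted value.
    """
    sel = ens.models[0].select(residues, atoms)
    if not np.any(sel):
        raise ValueError("selection is empty")
    coords = []
    for m in ens.models:
        msel = m.select(residues, atoms)
        if msel.sum() != sel.sum():
            raise ValueError("models do not share the selected atom set")
        coords.append(m.coords[msel])
    coords = np.array(coords)  # (M, N, 3)
    if coords.shape[0] < 2:
        raise ValueError("need >= 2 models for precision metrics")

    mean = coords[0]
    for _ in range(max_iter):
        fitted = []
        for c in coords:
            rot, trans, _ = kabsch(c, mean)
            fitted.append(c @ rot.T + trans)
        fitted = np.array(fitted)
        new_mean = fitted.mean(axis=0)
        if np.max(np.abs(new_mean - mean)) < 1e-10:
            mean = new_mean
            break
        mean = new_mean

    to_mean = float(np.mean([
        np.sqrt(np.mean(np.sum((f - mean) ** 2, axis=1))) for f in fitted
    ]))
    m = coords.shape[0]
    pair = [kabsch(coords[i], coords[j])[2] for i in range(m) for j in range(i + 1, m)]
    return float(np.mean(pair)), to_mean


# ------------------------------------------------------------------ RDC / Q


def _design_matrix(vectors: np.ndarray) -> np.ndarray:
    vx, vy, vz = vectors.T
    return np.column_stack([
        vx * vx - vz * vz,
        vy * vy - vz * vz,
        2.0 * vx * vy,
        2.0 * vx * vz,
        2.0 * vy * vz,
    ])


def fit_alignment_tensor(rdc: RDCSet) -> tuple[np.ndarray, np.ndarray]:
    """SVD least-squares fit of the Saupe alignment tensor.

    ``D_i = sum_ab S_ab v_ia v_ib`` with S symmetric and traceless leaves
    five independent elements, linear in the measured couplings.
    Returns the 3x3 Saupe matrix and the back-calculated couplings
    (also stored on ``rdc.d_calc``).
    """
    if rdc.d_meas.size < 5:
        raise ValueError("need at least 5 restraints to fit the tensor")
    a = _design_matrix(rdc.vectors)
    if np.linalg.matrix_rank(a) < 5:
        raise ValueError("rank-deficient design matrix: degenerate vector set")
    x, *_ = np.linalg.lstsq(a, rdc.d_meas, rcond=None)
    sxx, syy, sxy, sxz, syz = x
    saupe = np.array([
        [sxx, sxy, sxz],
        [sxy, syy, syz],
        [sxz, syz, -sxx - syy],
    ])
    d_calc = a @ x
    rdc.d_calc = d_calc
    return saupe, d_calc


def q_factor(rdc: RDCSet) -> float:
    """``Q = RMS(D_meas - D_calc) / RMS(D_meas)``; 0 for perfect agreement."""
    if rdc.d_calc is None:
        raise ValueError("d_calc missing: fit the alignment tensor first")
    rms_meas = np.sqrt(np.mean(rdc.d_meas**2))
    if rms_meas == 0:
        raise ValueError("all-zero measured couplings")
    return float(np.sqrt(np.mean((rdc.d_meas - rdc.d_calc) ** 2)) / rms_meas)


# ------------------------------------------------------------------------- I/O


def read_pdb_ensemble(path, chain: Optional[str] = None) -> Ensemble:
    """Read a multi-MODEL PDB file into an :class:`Ensemble` (altloc A preferred)."""
    import gemmi

    st = gemmi.read_structure(str(path))
    st.remove_alternative_conformations()
    models = []
    for gm in st:
        res_ids: list[int] = []
        names: list[str] = []
        xyz: list[list[float]] = []
        for ch in gm:
            if chain is not None and ch.name != chain:
                continue
            for res in ch:
                for atom in res:
                    res_ids.append(res.seqid.num)
                    names.append(atom.name)
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        models.append(Model(np.array(res_ids), names, np.array(xyz)))
    return Ensemble(models)
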