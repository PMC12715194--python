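"""Coordinate-ensemble descriptors of channel cold response.

Works on ensembles of Calpha snapshots of a homotetrameric channel
(optionally with water oxygens) and computes the descriptors used to
localise the cold-sensing module:

* minimal-RMSD rigid superposition of every snapshot onto a reference
  (Kabsch algorithm, proper rotations only);
* per-residue root mean square fluctuation,
  ``RMSF_n = sqrt(1/M * sum_m |r_mn - <r_n>|^2)``, averaged over the
  four equivalent subunit positions;
* the fractional RMSF change between a cold and a warm ensemble,
  ``(RMSF_cold - RMSF_warm)/RMSF_cold``, with a significance band
  (default +/-20%) separating specific changes from nonspecific thermal
  scaling;
* the per-residue radial distance to the channel axis ("radial Rg"),
  whose cold-minus-warm change is negative where residues pack inward;
* first-hydration-shell water-contact counts (water oxygens within a
  strict distance cutoff of the residue Calpha, default 3.5 A) and their
  cold-minus-warm change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateFitError

logger = logging.getLogger(__name__)

DEFAULT_WATER_CUTOFF = 3.5  # Angstrom, first hydration shell
SIGNIFICANCE_BAND = 0.20


@dataclass
class CoordinateEnsemble:
    """Aligned Calpha snapshots of a multi-subunit protein.

    ``coords`` has shape (M, S, N, 3): M snapshots, S subunits, N
    residues per subunit, in Angstrom.  ``waters`` is an optional list of
    (W_m, 3) water-oxygen coordinate arrays, one per snapshot.
    ``reference`` defaults to the first snapshot; ``axis`` is the channel
    symmetry axis (default z).
    """

    coords: np.ndarray
    waters: list[np.ndarray] | None = None
    reference: np.ndarray | None = None
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 4 or self.coords.shape[-1] != 3:
            raise ValueError("coords must have shape (M, S, N, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("need at least one snapshot")
        if self.reference is None:
            self.reference = self.coords[0].copy()
        self.reference = np.asarray(self.reference, dtype=float)
        if self.reference.shape != self.coords.shape[1:]:
            raise ValueError("reference shape must match a single snapshot")
        if self.waters is not None and len(self.waters) != self.coords.shape[0]:
            raise ValueError("need one water array per snapshot")
        self.axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(self.axis)
        if norm == 0:
            raise ValueError("channel axis must have nonzero length")
        self.axis = self.axis / norm

    @property
    def n_snapshots(self) -> int:
        return self.coords.shape[0]

    @property
    def n_subunits(self) -> int:
        return self.coords.shape[1]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[2]


@dataclass
class RMSFProfile:
    """Per-residue RMSF (A), averaged over equivalent subunit positions."""

    rmsf: np.ndarray                      # (N,)
    per_subunit: np.ndarray | None = None  # (S, N)


def kabsch_transform(moving: np.ndarray, reference: np.ndarray):
    """Optimal proper rotation R and translation t mapping moving -> reference.

    Minimises RMSD over rigid transforms; reflections are excluded by the
    determinant correction, so a mirror-image cloud keeps a documented
    residual instead of being inverted.  Degenerate (collinear or
    coincident) reference configurations raise.
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("need matching (n>=3, 3) coordinate arrays")
    qc = Q - Q.mean(axis=0)
    if np.linalg.matrix_rank(qc, tol=1e-8) < 2:
        raise DegenerateFitError("reference points are collinear or coincident")
    pc = P - P.mean(axis=0)
    H = pc.T @ qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    Rm = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - Rm @ P.mean(axis=0)
    return Rm, t


def superimpose(ensemble: CoordinateEnsemble) -> CoordinateEnsemble:
    """Rigidly align every snapshot (and its waters) onto the reference.

    The superposition uses all Calpha atoms and is computed once against
    the fixed reference, not iteratively against the ensemble mean.
    """
    M, S, N, _ = ensemble.coords.shape
    ref_flat = ensemble.reference.reshape(S * N, 3)
    out = np.empty_like(ensemble.coords)
    new_waters = None if ensemble.waters is None else []
    for m in range(M):
        flat = ensemble.coords[m].reshape(S * N, 3)
        Rm, t = kabsch_transform(flat, ref_flat)
        out[m] = (flat @ Rm.T + t).reshape(S, N, 3)
        if new_waters is not None:
            w = ensemble.waters[m]
            new_waters.append(w @ Rm.T + t if w.size else w.copy())
    return CoordinateEnsemble(coords=out, waters=new_waters,
                              reference=ensemble.reference.copy(),
                              axis=ensemble.axis.copy())


def rmsf(ensemble: CoordinateEnsemble) -> RMSFProfile:
    """Per-residue RMSF about the ensemble mean position.

    The fluctuation is computed independently at each subunit position
    and the S equivalent values are then averaged, matching the treatment
    of a homotetramer as four samples of the same residue.
    """
    mean = ensemble.coords.mean(axis=0, keepdims=True)       # (1, S, N, 3)
    dev = ensemble.coords - mean
    msf = np.mean(np.sum(dev ** 2, axis=-1), axis=0)          # (S, N)
    per_subunit = np.sqrt(msf)
    return RMSFProfile(rmsf=per_subunit.mean(axis=0), per_subunit=per_subunit)


def fractional_rmsf_change(cold: RMSFProfile, warm: RMSFProfile,
                           band: float = SIGNIFICANCE_BAND):
    """(RMSF_cold - RMSF_warm)/RMSF_cold with a significance mask.

    Returns ``(fraction, significant)``; residues whose cold RMSF is zero
    get NaN and are never flagged significant.
    """
    c = np.asarray(cold.rmsf, dtype=float)
    w = np.asarray(warm.rmsf, dtype=float)
    if c.shape != w.shape:
        raise ValueError("profiles cover different residue sets")
    frac = np.full_like(c, np.nan)
    ok = c > 0
    if not ok.all():
        logger.warning("fractional_rmsf_change: %d residue(s) with zero cold "
                       "RMSF left undefined", int((~ok).sum()))
    frac[ok] = (c[ok] - w[ok]) / c[ok]
    significant = np.abs(np.nan_to_num(frac)) > band
    significant &= ok
    return frac, significant


def radial_rg(ensemble: CoordinateEnsemble) -> np.ndarray:
    """Per-residue mean distance to the channel axis in the normal plane.

    The axis passes through the per-snapshot Calpha centroid along
    ``ensemble.axis``; distances are averaged over snapshots and the
    equivalent subunit copies.
    """
    coords = ensemble.coords
    centroid = coords.reshape(coords.shape[0], -1, 3).mean(axis=1)  # (M, 3)
    rel = coords - centroid[:, None, None, :]
    axial = np.tensordot(rel, ensemble.axis, axes=([-1], [0]))      # (M, S, N)
    perp = rel - axial[..., None] * ensemble.axis
    dist = np.linalg.norm(perp, axis=-1)                            # (M, S, N)
    return dist.mean(axis=(0, 1))


def delta_radial_rg(cold: CoordinateEnsemble, warm: CoordinateEnsemble) -> np.ndarray:
    """Cold-minus-warm radial profile; negative where residues pack inward."""
    rc, rw = radial_rg(cold), radial_rg(warm)
    if rc.shape != rw.shape:
        raise ValueError("ensembles cover different residue sets")
    return rc - rw


def count_water_contacts(ensemble: CoordinateEnsemble, snapshot: int, residue: int,
                         cutoff: float = DEFAULT_WATER_CUTOFF) -> float:
    """Waters within ``cutoff`` (strict <) of a residue's Calpha.

    Counts per subunit copy and returns the subunit average for snapshot
    ``snapshot``.  Returns 0 with a warning when the model has no waters.
    """
    counts = water_contact_counts(ensemble, cutoff=cutoff,
                                  snapshots=[snapshot])
    return float(counts[0, residue])


def water_contact_counts(ensemble: CoordinateEnsemble,
                         cutoff: float = DEFAULT_WATER_CUTOFF,
                         snapshots=None) -> np.ndarray:
    """Subunit-averaged water-contact counts, shape (M_sel, N)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    idx = range(ensemble.n_snapshots) if snapshots is None else snapshots
    idx = list(idx)
    out = np.zeros((len(idx), ensemble.n_residues))
    if ensemble.waters is None:
        logger.warning("water_contact_counts: ensemble carries no waters; "
                       "returning zero counts")
        return out
    for row, m in enumerate(idx):
        w = ensemble.waters[m]
        if w.size == 0:
            continue
        tree = cKDTree(w)
        ca = ensemble.coords[m].reshape(-1, 3)  # (S*N, 3)
        # strict inequality: shrink the query radius by one ulp-scale step
        neighbour_lists = tree.query_ball_point(ca, r=cutoff)
        counts = np.zeros(len(ca))
        for i, neigh in enumerate(neighbour_lists):
            if not neigh:
                continue
            d = np.linalg.norm(w[neigh] - ca[i], axis=1)
            counts[i] = int(np.sum(d < cutoff))
        out[row] = counts.reshape(ensemble.n_subunits, ensemble.n_residues).mean(axis=0)
    return out


def mean_water_contacts(ensemble: CoordinateEnsemble,
                        cutoff: float = DEFAULT_WATER_CUTOFF) -> np.ndarray:
    """Snapshot-averaged per-residue water-contact counts, shape (N,)."""
    return water_contact_counts(ensemble, cutoff=cutoff).mean(axis=0)


def delta_water_contacts(cold: CoordinateEnsemble, warm: CoordinateEnsemble,
                         cutoff: float = DEFAULT_WATER_CUTOFF) -> np.ndarray:
    """Cold-minus-warm mean water-contact counts per residue."""
    c = mean_water_contacts(cold, cutoff=cutoff)
    w = mean_water_contacts(warm, cutoff=cutoff)
    if c.shape != w.shape:
        raise ValueError("ensembles cover different residue sets")
    return c - w


# ---------------------------------------------------------------------------
# multi-model PDB I/O (Calpha records per subunit chain, waters as HOH O)

def write_pdb(ensemble: CoordinateEnsemble, path) -> None:
    """Write the ensemble as a multi-model PDB file.

    Subunits become chains A, B, ...; residues are written as Calpha-only
    ALA records; waters as HOH oxygen HETATM records on chain W.  The
    water count must be constant across snapshots (fixed atom table).
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    M, S, N, _ = ensemble.coords.shape
    n_wat = 0 if ensemble.waters is None else len(ensemble.waters[0])
    if ensemble.waters is not None:
        if any(len(w) != n_wat for w in ensemble.waters):
            raise ValueError("PDB export needs a constant water count per model")
    n_atoms = S * N + n_wat
    arrays = []
    for m in range(M):
        arr = struc.AtomArray(n_atoms)
        pos = np.concatenate(
            [ensemble.coords[m].reshape(-1, 3)] +
            ([ensemble.waters[m]] if n_wat else []))
        arr.coord = pos
        chain = np.concatenate(
            [np.repeat([chr(ord("A") + s) for s in range(S)], N)] +
            ([np.full(n_wat, "W")] if n_wat else []))
        arr.chain_id = chain
        arr.res_id = np.concatenate(
            [np.tile(np.arange(1, N + 1), S)] +
            ([np.arange(1, n_wat + 1)] if n_wat else []))
        arr.res_name = np.concatenate(
            [np.full(S * N, "ALA")] + ([np.full(n_wat, "HOH")] if n_wat else []))
        arr.atom_name = np.concatenate(
            [np.full(S * N, "CA")] + ([np.full(n_wat, "O")] if n_wat else []))
        arr.element = np.concatenate(
            [np.full(S * N, "C")] + ([np.full(n_wat, "O")] if n_wat else []))
        arr.hetero = np.concatenate(
            [np.zeros(S * N, bool)] + ([np.ones(n_wat, bool)] if n_wat else []))
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def read_pdb(path, axis=(0.0, 0.0, 1.0)) -> CoordinateEnsemble:
    """Read a multi-model Calpha/HOH PDB back into an ensemble."""
    import biotite.structure.io.pdb as pdbio

    pdb_file = pdbio.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None)
    is_water = stack.res_name == "HOH"
    ca = stack[..., (stack.atom_name == "CA") & ~is_water]
    chains = sorted(set(ca.chain_id[~np.isin(ca.chain_id, ["W"])]))
    S = len(chains)
    M = ca.stack_depth()
    per_chain = [ca.coord[:, ca.chain_id == c, :] for c in chains]
    N = per_chain[0].shape[1]
    coords = np.stack(per_chain, axis=1)  # (M, S, N, 3)
    waters = None
    wat = stack[..., is_water & (stack.atom_name == "O")]
    if wat.array_length() > 0:
        waters = [wat.coord[m] for m in range(M)]
    return CoordinateEnsemble(coords=coords, waters=waters,
                              axis=np.asarray(axis, dtype=float))


def profiles_table(cold: CoordinateEnsemble, warm: CoordinateEnsemble,
                   cutoff: float = DEFAULT_WATER_CUTOFF,
                   band: float = SIGNIFICANCE_BAND,
                   align: bool = True):
    """Full per-residue descriptor table comparing a cold and warm ensemble."""
    import pandas as pd

    if align:
        cold = superimpose(cold)
        warm = superimpose(warm)
    rc, rw = rmsf(cold), rmsf(warm)
    frac, sig = fractional_rmsf_change(rc, rw, band=band)
    drg = delta_radial_rg(cold, warm)
    dw = delta_water_contacts(cold, warm, cutoff=cutoff)
    return pd.DataFrame({
        "residue": np.arange(1, cold.n_residues + 1),
        "rmsf_cold": rc.rmsf,
        "rmsf_warm": rw.rmsf,
        "frac_change": frac,
        "significant": sig,
        "radial_rg_delta": drg,
        "delta_waters": dw,
    })
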