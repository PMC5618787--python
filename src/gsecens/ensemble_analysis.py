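"""Ensemble statistics over trajectories.

Superposition-based measures (RMSF, PCA, RMSD clustering) follow the
conventions of the standard MD toolchains: least-squares rigid-body
fitting to a reference frame, Cartesian-coordinate covariance PCA, and
GROMOS-style iterative centroid clustering at a fixed RMSD cutoff.
Hydrogen bonds use the geometric criterion (donor–acceptor distance plus
donor-hydrogen-acceptor angle); density maps render atoms as isotropic
Gaussians at a nominal resolution, matching the convention of molmap-style
map generators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure_io import Trajectory
from .order_params import GeometryError

__all__ = [
    "PCAResult",
    "ClusterResult",
    "HBondCriteria",
    "DensityMap",
    "superpose",
    "apply_transform",
    "pairwise_rmsd_matrix",
    "rmsf",
    "histogram",
    "pca",
    "porcupine",
    "gromos_cluster",
    "hbond_occupancy",
    "density_map",
]


# ---------------------------------------------------------------------------
# rigid-body superposition
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray,
              fit_indices: np.ndarray | None = None
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid fit of ``mobile`` onto ``reference`` (Kabsch).

    Returns ``(rotation, translation, rmsd)`` with
    ``fitted = mobile @ rotation.T + translation`` minimizing the RMSD over
    ``fit_indices`` (all atoms by default). The rotation is proper
    (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (N, 3) arrays")
    idx = np.arange(mobile.shape[0]) if fit_indices is None else np.asarray(fit_indices, dtype=int)
    if idx.size < 3:
        raise GeometryError("need at least 3 fit atoms")
    M = mobile[idx]
    Rf = reference[idx]
    mc, rc = M.mean(axis=0), Rf.mean(axis=0)
    M0, R0 = M - mc, Rf - rc
    sv = np.linalg.svd(R0, compute_uv=False)
    if sv[1] < 1e-10 * max(sv[0], 1.0):
        raise GeometryError("fit atoms are (near-)collinear; rotation ill-defined")
    H = M0.T @ R0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    rot = Vt.T @ D @ U.T
    trans = rc - rot @ mc
    fitted = M @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - Rf) ** 2, axis=1))))
    return rot, trans, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ np.asarray(rotation).T + translation


def _fit_frames(traj_coords: np.ndarray, ref: np.ndarray,
                fit_indices: np.ndarray | None) -> np.ndarray:
    out = np.empty_like(traj_coords)
    for f in range(traj_coords.shape[0]):
        rot, trans, _ = superpose(traj_coords[f], ref, fit_indices)
        out[f] = apply_transform(traj_coords[f], rot, trans)
    return out


def pairwise_rmsd_matrix(coords: np.ndarray,
                         fit_indices: np.ndarray | None = None) -> np.ndarray:
    """Symmetric matrix of pairwise superposed RMSDs (nm)."""
    F = coords.shape[0]
    out = np.zeros((F, F))
    for i in range(F):
        for j in range(i + 1, F):
            _, _, r = superpose(coords[j], coords[i], fit_indices)
            out[i, j] = out[j, i] = r
    return out


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

def rmsf(traj: Trajectory, selection: np.ndarray | None = None,
         fit_indices: np.ndarray | None = None, normalize: bool = False) -> np.ndarray:
    """Per-atom root mean square fluctuation after superposition.

    Frames are fitted to the first frame on ``fit_indices``; the RMSF of
    atom *i* is the RMS deviation from its time-averaged position. With
    ``normalize=True`` values are divided by their maximum (range (0, 1],
    maximum exactly 1), the convention used for color-coded flexibility
    maps.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    fitted = _fit_frames(traj.coords, traj.coords[0], fit_indices)
    if selection is not None:
        fitted = fitted[:, np.asarray(selection, dtype=int)]
    mean = fitted.mean(axis=0)
    vals = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))
    if normalize:
        m = vals.max()
        if m == 0:
            raise ValueError("cannot normalize an all-zero RMSF profile")
        vals = vals / m
    return vals


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------

def histogram(*columns: np.ndarray, bins=50, range=None):
    """Normalized 1-D or 2-D density histogram.

    Returns ``(density, edges)`` for one column or
    ``(density, xedges, yedges)`` for two; densities integrate to 1.
    """
    cols = [np.asarray(c, dtype=float).ravel() for c in columns]
    if not cols or any(c.size == 0 for c in cols):
        raise ValueError("histogram needs at least one non-empty sample column")
    if len(cols) == 1:
        dens, edges = np.histogram(cols[0], bins=bins, range=range, density=True)
        return dens, edges
    if len(cols) == 2:
        dens, xe, ye = np.histogram2d(cols[0], cols[1], bins=bins, range=range, density=True)
        return dens, xe, ye
    raise ValueError("histogram supports 1 or 2 columns")


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Eigen-decomposition of the Cartesian coordinate covariance.

    ``eigenvalues`` (nm^2, descending) and ``variance_fraction`` cover every
    nontrivial mode; ``eigenvectors`` (rows, unit 3N-vectors) and
    ``projections`` (frames x kept) are retained for the leading
    ``n_components`` only.
    """

    mean_coords: np.ndarray        # (N, 3) nm
    eigenvalues: np.ndarray        # all modes, nm^2
    variance_fraction: np.ndarray  # all modes, sums to 1
    eigenvectors: np.ndarray       # (kept, 3N)
    projections: np.ndarray        # (frames, kept), centered
    atom_indices: np.ndarray       # selection the decomposition was made on

    @property
    def n_kept(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


def pca(traj: Trajectory, selection: np.ndarray | None = None,
        fit_indices: np.ndarray | None = None, n_components: int = 10,
        ref_frame: int = 0) -> PCAResult:
    """PCA of superposed Cartesian coordinates.

    Frames are least-squares fitted to ``ref_frame`` on ``fit_indices``
    (default: the analyzed selection) before the covariance of the
    flattened 3N coordinates of ``selection`` is decomposed.
    """
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    sel = (np.arange(traj.n_atoms) if selection is None
           else np.asarray(selection, dtype=int))
    if sel.size == 0:
        raise ValueError("empty selection")
    fit_idx = sel if fit_indices is None else np.asarray(fit_indices, dtype=int)
    fitted = _fit_frames(traj.coords, traj.coords[ref_frame], fit_idx)
    X = fitted[:, sel].reshape(traj.n_frames, -1)
    mean = X.mean(axis=0)
    C = X - mean
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    lam = np.clip(s**2 / (traj.n_frames - 1), 0.0, None)
    total = lam.sum()
    frac = lam / total if total > 0 else np.zeros_like(lam)
    kept = min(n_components, Vt.shape[0])
    proj = C @ Vt[:kept].T
    return PCAResult(mean_coords=mean.reshape(-1, 3), eigenvalues=lam,
                     variance_fraction=frac, eigenvectors=Vt[:kept],
                     projections=proj, atom_indices=sel)


def porcupine(result: PCAResult, component: int, scale: float = 1.0
              ) -> tuple[np.ndarray, np.ndarray]:
    """Arrow field for one principal component.

    Returns per-atom base points (the mean structure) and displacement
    vectors ``scale * eigenvector`` reshaped to (N, 3) — the porcupine
    representation of a collective motion.
    """
    if not 0 <= component < result.n_kept:
        raise IndexError(f"component {component} not retained (kept {result.n_kept})")
    vecs = scale * result.eigenvectors[component].reshape(-1, 3)
    return result.mean_coords.copy(), vecs


# ---------------------------------------------------------------------------
# GROMOS clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    cutoff: float                 # nm
    membership: np.ndarray        # frame -> cluster id (0-based, by discovery)
    centroids: list[int]          # one representative frame index per cluster
    sizes: list[int]              # descending

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)


def gromos_cluster(traj_or_coords, selection: np.ndarray | None = None,
                   cutoff: float = 0.2,
                   rmsd_matrix: np.ndarray | None = None) -> ClusterResult:
    """GROMOS iterative centroid clustering at an RMSD cutoff.

    Repeatedly takes the unassigned frame with the most unassigned
    neighbors within ``cutoff`` (superposed RMSD) as a cluster centroid
    and removes it together with its neighbors. Ties are broken by the
    lowest frame index, making the result bit-reproducible.
    """
    coords = traj_or_coords.coords if isinstance(traj_or_coords, Trajectory) else \
        np.asarray(traj_or_coords, dtype=float)
    if coords.ndim != 3 or coords.shape[0] == 0:
        raise ValueError("need a non-empty (frames, atoms, 3) coordinate stack")
    sel = None if selection is None else np.asarray(selection, dtype=int)
    sub = coords if sel is None else coords[:, sel]
    if rmsd_matrix is None:
        rmsd_matrix = pairwise_rmsd_matrix(sub)
    F = coords.shape[0]
    neigh = rmsd_matrix <= cutoff
    np.fill_diagonal(neigh, True)
    unassigned = np.ones(F, dtype=bool)
    membership = np.full(F, -1, dtype=int)
    centroids: list[int] = []
    sizes: list[int] = []
    cid = 0
    while unassigned.any():
        counts = (neigh & unassigned).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neigh[center] & unassigned)
        membership[members] = cid
        centroids.append(center)
        sizes.append(int(members.size))
        unassigned[members] = False
        cid += 1
    return ClusterResult(cutoff=float(cutoff), membership=membership,
                         centroids=centroids, sizes=sizes)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition.

    Present when the donor–acceptor distance is within ``d_max`` (nm) and
    the donor–hydrogen–acceptor angle is at least ``angle_min`` degrees
    (the 3.0 Å / 150-degree rule).
    """

    d_max: float = 0.30
    angle_min: float = 150.0

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be > 0")
        if not 0 < self.angle_min <= 180:
            raise ValueError("angle_min must be in (0, 180]")


def hbond_occupancy(traj: Trajectory, donor_triples,
                    criteria: HBondCriteria = HBondCriteria(),
                    window: tuple[int, int] | None = None) -> np.ndarray:
    """Fraction of window frames in which each hydrogen bond is present.

    ``donor_triples`` is a sequence of atom-index triples (donor,
    hydrogen, acceptor). A ``None`` hydrogen switches that triple to a
    distance-only criterion (with a warning) for topologies without
    hydrogens, e.g. coarse bead models or heavy-atom cryo-EM coordinates.
    ``window`` is a half-open frame range; occupancy over e.g. the final
    stretch of a run is obtained by passing that range.
    """
    lo, hi = (0, traj.n_frames) if window is None else window
    if not (0 <= lo < hi <= traj.n_frames):
        raise ValueError(f"empty or out-of-range window ({lo}, {hi})")
    coords = traj.coords[lo:hi]
    out = np.empty(len(donor_triples))
    for k, (d, h, a) in enumerate(donor_triples):
        D, A = coords[:, d], coords[:, a]
        dist_ok = np.linalg.norm(D - A, axis=1) <= criteria.d_max
        if h is None:
            warnings.warn("no hydrogen in donor triple; using distance-only criterion",
                          stacklevel=2)
            present = dist_ok
        else:
            Hc = coords[:, h]
            v1 = D - Hc
            v2 = A - Hc
            cosang = np.sum(v1 * v2, axis=1) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            present = dist_ok & (ang >= criteria.angle_min)
        out[k] = present.mean()
    return out


# ---------------------------------------------------------------------------
# density maps
# ---------------------------------------------------------------------------

@dataclass
class DensityMap:
    origin: np.ndarray     # nm, corner of voxel (0,0,0)
    voxel: float           # nm
    grid: np.ndarray       # (nx, ny, nz), non-negative
    resolution: float      # nm

    def integral(self) -> float:
        return float(self.grid.sum() * self.voxel**3)

    def write_ccp4(self, path) -> None:
        """Write as a CCP4/MRC map (gemmi backend, Angstrom units)."""
        import gemmi

        m = gemmi.Ccp4Map()
        m.grid = gemmi.FloatGrid(np.asarray(self.grid, dtype=np.float32))
        a = self.grid.shape[0] * self.voxel * 10.0
        b = self.grid.shape[1] * self.voxel * 10.0
        c = self.grid.shape[2] * self.voxel * 10.0
        m.grid.unit_cell = gemmi.UnitCell(a, b, c, 90, 90, 90)
        m.grid.spacegroup = gemmi.SpaceGroup("P1")
        m.update_ccp4_header()
        m.write_ccp4_map(str(path))


def density_map(coords: np.ndarray, weights: np.ndarray | None = None,
                resolution: float = 0.8, voxel: float = 0.1,
                sigma_factor: float = 0.225) -> DensityMap:
    """Gaussian-rendered density map of one conformation.

    Each atom contributes an isotropic normalized Gaussian of width
    ``sigma = sigma_factor * resolution`` scaled by its weight; the grid
    is padded by 4 sigma so the integrated density equals the total
    weight to well within 1%.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (N, 3)")
    if not resolution > voxel > 0:
        raise ValueError("need resolution > voxel > 0")
    w = np.ones(coords.shape[0]) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (coords.shape[0],):
        raise ValueError("weights must be per-atom")
    sigma = sigma_factor * resolution
    pad = 4.0 * sigma
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = np.ceil((hi - lo) / voxel).astype(int) + 1
    # center the grid on the data midpoint so symmetric inputs give
    # symmetric maps
    center = 0.5 * (lo + hi)
    lo = center - voxel * (shape - 1) / 2.0
    grid = np.zeros(shape)
    axes = [lo[k] + voxel * np.arange(shape[k]) for k in range(3)]
    norm = (2.0 * np.pi) ** 1.5 * sigma**3
    for p, wi in zip(coords, w):
        i_lo = np.ceil((p - pad - lo) / voxel).astype(int)
        i_hi = np.floor((p + pad - lo) / voxel).astype(int)
        sl = [slice(max(i_lo[k], 0), min(i_hi[k] + 1, shape[k])) for k in range(3)]
        gs = [np.exp(-((axes[k][sl[k]] - p[k]) ** 2) / (2.0 * sigma**2)) for k in range(3)]
        grid[sl[0], sl[1], sl[2]] += (wi / norm) * (
            gs[0][:, None, None] * gs[1][None, :, None] * gs[2][None, None, :])
    return DensityMap(origin=lo, voxel=float(voxel), grid=grid,
                      resolution=float(resolution))
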