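"""Per-frame geometric order parameters.

The order parameters characterizing the complex's functional states:

* ``dd_Asp`` — distance (nm) between the catalytic aspartate side-chain
  gamma carbons on TM6 and TM7 of presenilin; short distances permit the
  aspartate–water hydrogen-bond network of the active protease.
* ``T_TM_<helix>`` — tilt (degrees) of each transmembrane helix axis
  relative to the membrane normal (+z for pre-oriented systems).
* ``dd_PS-NCT`` — distance (nm) between the center of geometry of the
  catalytic subunit and that of the nicastrin large lobe (ECD up/down
  translation).
* ``dih_NCT`` — signed four-point dihedral (degrees) quantifying the
  left/right rotation of the nicastrin extracellular lobe.
* ``axis_length`` — distance (nm) between anchor residues at the lower
  intracellular and upper extracellular extremes of the complex (the
  major-axis length separating compact / intermediate / extended forms).

Helix axes are estimated as the dominant principal direction of the
centered C-alpha coordinates (best-fit line); ``fit_rmsd`` exposes the
quality of the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure_io import Selector, Structure, Trajectory, TopologyMap, resolve_selection

__all__ = [
    "HelixAxis",
    "CurvatureProfile",
    "OrderParameterSeries",
    "GeometryError",
    "fit_helix_axis",
    "tilt_angle",
    "pair_distance",
    "dihedral_angle",
    "curvature_profile",
    "compute_op_series",
]


class GeometryError(ValueError):
    """Degenerate or insufficient geometry for the requested measurement."""


@dataclass(frozen=True)
class HelixAxis:
    centroid: np.ndarray      # (3,), nm
    direction: np.ndarray     # unit vector, direction.z >= 0
    fit_rmsd: float           # RMS perpendicular distance of points to the line, nm


@dataclass(frozen=True)
class CurvatureProfile:
    helix: str
    window: int
    step: int
    window_starts: np.ndarray      # residue offset of each window
    window_axes: np.ndarray        # (n_windows, 3) local axis directions
    kink_angles: np.ndarray        # (n_windows - 1,) degrees, in [0, 180)


@dataclass
class OrderParameterSeries:
    """Per-frame values of named scalar order parameters."""

    names: list[str]
    values: np.ndarray  # (n_frames, n_names)
    times: np.ndarray   # ns

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values must be (frames, len(names))")
        if self.times.shape != (self.values.shape[0],):
            raise ValueError("times length must equal frame count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("order-parameter series contains non-finite values")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "time_ns", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "OrderParameterSeries":
        df = pd.read_csv(path)
        times = df.pop("time_ns").to_numpy() if "time_ns" in df else np.arange(len(df), dtype=float)
        return cls(names=list(df.columns), values=df.to_numpy(dtype=float), times=times)


def fit_helix_axis(ca_coords: np.ndarray) -> HelixAxis:
    """Best-fit line through C-alpha coordinates.

    Direction is the dominant right singular vector of the centered
    coordinates, sign-fixed so the z-component is non-negative (ties broken
    toward positive x, then y).
    """
    X = np.asarray(ca_coords, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise GeometryError("expected (M, 3) coordinates")
    if X.shape[0] < 4:
        raise GeometryError(f"need at least 4 points to fit a helix axis, got {X.shape[0]}")
    centroid = X.mean(axis=0)
    C = X - centroid
    if np.allclose(C, 0.0, atol=1e-12):
        raise GeometryError("all points coincide; axis undefined")
    _, s, vt = np.linalg.svd(C, full_matrices=False)
    d = vt[0]
    # sign convention: point "up" along the membrane normal
    for comp in (2, 0, 1):
        if abs(d[comp]) > 1e-12:
            if d[comp] < 0:
                d = -d
            break
    perp = C - np.outer(C @ d, d)
    fit_rmsd = float(np.sqrt(np.mean(np.sum(perp**2, axis=1))))
    return HelixAxis(centroid=centroid, direction=d / np.linalg.norm(d), fit_rmsd=fit_rmsd)


def tilt_angle(axis: HelixAxis | np.ndarray, normal=(0.0, 0.0, 1.0)) -> float:
    """Tilt (degrees, in [0, 90]) of a helix axis from the membrane normal.

    Uses ``arccos(|d . n|)`` so the result is independent of the axis sign
    convention.
    """
    d = axis.direction if isinstance(axis, HelixAxis) else np.asarray(axis, dtype=float)
    n = np.asarray(normal, dtype=float)
    nn = np.linalg.norm(n)
    if nn == 0:
        raise GeometryError("membrane normal must be nonzero")
    dd = np.linalg.norm(d)
    if dd == 0:
        raise GeometryError("axis direction must be nonzero")
    c = abs(float(d @ n) / (dd * nn))
    return float(np.degrees(np.arccos(min(c, 1.0))))


def pair_distance(coords: np.ndarray, selA: np.ndarray, selB: np.ndarray,
                  mode: str = "centroid") -> float:
    """Euclidean distance (nm) between two selections in one frame.

    ``mode='single-atom'`` requires each selection to hold exactly one
    atom; ``mode='centroid'`` uses the unweighted mean coordinate (center
    of geometry). No periodic-boundary wrapping: intra-complex distances
    on whole, centered molecules.
    """
    coords = np.asarray(coords, dtype=float)
    a = np.atleast_1d(np.asarray(selA, dtype=int))
    b = np.atleast_1d(np.asarray(selB, dtype=int))
    if a.size == 0 or b.size == 0:
        raise GeometryError("empty selection in pair_distance")
    if mode == "single-atom":
        if a.size != 1 or b.size != 1:
            raise GeometryError("single-atom mode requires 1-atom selections")
        pa, pb = coords[a[0]], coords[b[0]]
    elif mode == "centroid":
        pa, pb = coords[a].mean(axis=0), coords[b].mean(axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(np.linalg.norm(pa - pb))


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed dihedral (degrees, in (-180, 180]) defined by four points.

    IUPAC sign convention: looking along p2 -> p3, a clockwise rotation of
    the far bond relative to the near bond is positive.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n == 0:
        raise GeometryError("central bond p2->p3 has zero length")
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise GeometryError("collinear points: dihedral undefined")
    x = float(n1 @ n2)
    y = float(np.cross(n1, n2) @ b2) / b2n
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def place_fourth_point(p1, p2, p3, dihedral_deg: float,
                       distance: float = 1.0, angle_deg: float = 90.0) -> np.ndarray:
    """Construct p4 at a prescribed dihedral to the plane of p1-p2-p3.

    ``distance`` is |p4 - p3| and ``angle_deg`` the bond angle p2-p3-p4.
    Closed-form inverse of :func:`dihedral_angle`; used by the synthetic
    generator to realize exact ground-truth dihedrals.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    b2 = p3 - p2
    u = b2 / np.linalg.norm(b2)
    v = (p1 - p2) - ((p1 - p2) @ u) * u  # in-plane reference, points toward p1 side
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        raise GeometryError("p1, p2, p3 collinear; dihedral reference undefined")
    v = v / nv
    w = np.cross(u, v)
    th = np.radians(angle_deg)
    phi = np.radians(dihedral_deg)
    # local frame at p3: u along bond, v at dihedral 0 (cis to p1)
    d = (np.cos(np.pi - th) * u
         + np.sin(np.pi - th) * (np.cos(phi) * v + np.sin(phi) * w))
    return p3 + distance * d


def curvature_profile(ca_coords: np.ndarray, helix: str = "",
                      window: int = 9, step: int | None = None) -> CurvatureProfile:
    """Windowed local-axis fit along a helix; kink angles between windows.

    Each window of ``window`` consecutive residues gets a best-fit axis;
    the kink angle between consecutive windows is the unsigned angle
    between their axis directions, with each direction oriented along the
    overall end-to-end vector so straight helices report angles near 0.
    By default windows are contiguous (``step = window``), so a sharp bend
    between two windows is reported at its full angle; pass a smaller
    ``step`` for a sliding profile. The default window of 9 residues
    (about 2.5 helical turns) keeps the discrete-helix axis-fit wobble of
    an ideal straight helix below ~1.5 degrees.
    """
    X = np.asarray(ca_coords, dtype=float)
    if window < 4:
        raise GeometryError("window must be >= 4 residues")
    if step is None:
        step = window
    if step < 1:
        raise ValueError("step must be >= 1")
    if X.shape[0] < window:
        raise GeometryError(
            f"helix of {X.shape[0]} residues shorter than window {window}")
    e2e = X[-1] - X[0]
    starts = np.arange(0, X.shape[0] - window + 1, step)
    axes = np.empty((starts.size, 3))
    for k, s0 in enumerate(starts):
        d = fit_helix_axis(X[s0:s0 + window]).direction
        if np.linalg.norm(e2e) > 0 and d @ e2e < 0:
            d = -d
        axes[k] = d
    kinks = np.empty(max(starts.size - 1, 0))
    for k in range(starts.size - 1):
        c = np.clip(axes[k] @ axes[k + 1], -1.0, 1.0)
        kinks[k] = np.degrees(np.arccos(c))
    return CurvatureProfile(helix=helix, window=window, step=step,
                            window_starts=starts, window_axes=axes, kink_angles=kinks)


def _resolve_point(s: Structure, sel: Selector, tmap: TopologyMap,
                   coords: np.ndarray) -> np.ndarray:
    idx = resolve_selection(s, sel, tmap)
    return coords[idx].mean(axis=0)


def catalytic_dyad_distance(s: Structure, resid_a: int = 257, resid_b: int = 385,
                            atom: str = "CG", resname: str = "ASP"
                            ) -> tuple[float, str]:
    """Distance (nm) between the catalytic aspartate side-chain gamma
    carbons, located chain-agnostically.

    Scans every chain for a residue pair (``resid_a``, ``resid_b``) of
    ``resname`` carrying ``atom`` and returns ``(distance_nm, chain_id)``
    for the unique chain holding both — the presenilin subunit in
    deposited structures of the protease complex, whatever its chain
    label. Raises ``GeometryError`` when no (or more than one) chain
    qualifies.
    """
    hits = []
    for chain in sorted(set(s.chains)):
        m = (s.chains == chain) & (s.names == atom) & (s.resnames == resname)
        ia = np.flatnonzero(m & (s.resids == resid_a))
        ib = np.flatnonzero(m & (s.resids == resid_b))
        if ia.size == 1 and ib.size == 1:
            hits.append((chain, float(np.linalg.norm(s.coords[ia[0]] - s.coords[ib[0]]))))
    if len(hits) != 1:
        raise GeometryError(
            f"expected exactly one chain with {resname}{resid_a}/{resname}{resid_b} "
            f"{atom} atoms, found {[h[0] for h in hits]}")
    chain, dist = hits[0]
    return dist, chain


def compute_op_series(traj: Trajectory, tmap: TopologyMap) -> OrderParameterSeries:
    """Evaluate every configured order parameter on every frame.

    Columns (when the topology map defines the corresponding selections):
    ``dd_Asp``, one ``T_TM_<name>`` per helix, ``dd_PS-NCT``, ``dih_NCT``,
    ``axis_length``.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    top = traj.topology
    names: list[str] = []
    getters = []

    if tmap.catalytic_pair is not None:
        ia = resolve_selection(top, tmap.catalytic_pair[0], tmap)
        ib = resolve_selection(top, tmap.catalytic_pair[1], tmap)
        if ia.size != 1 or ib.size != 1:
            raise ValueError("catalytic_pair selectors must resolve to single atoms")
        names.append("dd_Asp")
        getters.append(lambda c, ia=ia, ib=ib: pair_distance(c, ia, ib, mode="single-atom"))

    helix_idx = {h: resolve_selection(top, tmap.helix_selector(h), tmap)
                 for h in tmap.helices}
    for h, idx in helix_idx.items():
        names.append(f"T_TM_{h}")
        getters.append(lambda c, idx=idx: tilt_angle(fit_helix_axis(c[idx]),
                                                     tmap.membrane_normal))

    if tmap.nct_large_lobe is not None and "PS1" in tmap.subunits:
        ps1_idx = np.flatnonzero(tmap.subunits["PS1"].mask(top))
        lobe_idx = resolve_selection(top, tmap.nct_large_lobe, tmap)
        names.append("dd_PS-NCT")
        getters.append(lambda c, a=ps1_idx, b=lobe_idx: pair_distance(c, a, b, mode="centroid"))

    if tmap.dih_anchors is not None:
        anchor_idx = [resolve_selection(top, a, tmap) for a in tmap.dih_anchors]
        names.append("dih_NCT")
        getters.append(lambda c, ai=anchor_idx: dihedral_angle(
            *(c[idx].mean(axis=0) for idx in ai)))

    if tmap.axis_endpoints is not None:
        lo_idx = resolve_selection(top, tmap.axis_endpoints[0], tmap)
        hi_idx = resolve_selection(top, tmap.axis_endpoints[1], tmap)
        names.append("axis_length")
        getters.append(lambda c, a=lo_idx, b=hi_idx: pair_distance(c, a, b, mode="centroid"))

    if not names:
        raise ValueError("topology map defines no order parameters")

    values = np.empty((traj.n_frames, len(names)))
    for f in range(traj.n_frames):
        c = traj.coords[f]
        for j, g in enumerate(getters):
            try:
                values[f, j] = g(c)
            except Exception as exc:
                raise type(exc)(f"frame {f}, order parameter {names[j]}: {exc}") from exc
    return OrderParameterSeries(names=names, values=values, times=traj.times.copy())
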