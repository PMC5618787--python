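"""Synthetic helix-bundle structures and two-state pseudo-trajectories.

The generator emulates, at benchmark scale, the geometry that the analysis
stack measures on a four-subunit intramembrane protease: a bundle of
transmembrane helices (the catalytic subunit) carrying a pair of
"catalytic" side-chain beads, plus an extracellular-domain (ECD) blob
whose height and rotation mimic nicastrin's up/down translation and
left/right rotation. Frames switch between two hidden conformational
states (1 = inactive: long catalytic distance; 2 = active: short
catalytic distance) following a two-state Markov chain, with i.i.d.
Gaussian positional noise on every atom.

Ground truth is exact by construction:

* the catalytic beads are placed exactly ``dd_asp_nm`` apart;
* each helix is built so that the best-fit line through its beads is
  *exactly* its nominal axis (the tiny axial correlation of a discrete
  helix is sheared out), so a helix tilted by ``t`` degrees measures a
  tilt of exactly ``t``;
* the ECD lobe centroid sits exactly ``ecd_height_nm`` above the
  catalytic subunit's center of geometry, and the fourth dihedral anchor
  is placed by closed-form inversion so the four-point dihedral equals
  ``ecd_dih_deg`` exactly.

Randomness comes from a single named, seedable generator
(``numpy.random.Generator`` with PCG64), recorded in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structure_io import Selector, Structure, SubunitDef, TopologyMap, Trajectory
from .order_params import compute_op_series, place_fourth_point

__all__ = [
    "StateParams",
    "SynthConfig",
    "GroundTruth",
    "default_config",
    "build_ideal_bundle",
    "synthetic_topology_map",
    "simulate_two_state_trajectory",
    "ground_truth",
    "truth_table",
]

RNG_NAME = "numpy.random.Generator(PCG64)"


@dataclass(frozen=True)
class StateParams:
    """Geometry of one conformational state."""

    tilt_deg: dict[str, float]      # per-helix tilt from the membrane normal
    dd_asp_nm: float                # catalytic bead separation
    ecd_height_nm: float            # ECD lobe centroid height above bundle COG
    ecd_dih_deg: float              # four-point ECD rotation dihedral


@dataclass(frozen=True)
class SynthConfig:
    n_helices: int = 9
    residues_per_helix: int = 20
    rise_nm: float = 0.15               # ideal alpha-helix rise per residue
    helix_radius_nm: float = 0.23       # C-alpha radius of the ideal helix
    turn_deg_per_res: float = 100.0     # 3.6 residues per turn
    bundle_radius_nm: float = 1.4       # helix axes sit on this circle
    state_params: dict[int, StateParams] = field(default_factory=dict)
    transition: tuple[tuple[float, float], tuple[float, float]] = (
        (0.97, 0.03), (0.07, 0.93))     # stationary occupancy of state 2 = 0.3
    noise_sigma_nm: float = 0.05
    n_frames: int = 10_000
    seed: int = 0
    dt_ns: float = 1.0
    # ECD / anchor plumbing
    lobe_n_beads: int = 24
    lobe_radius_nm: float = 0.8
    tm_rod_beads: int = 10
    distal_arm_nm: float = 1.5

    def validate(self) -> None:
        if set(self.state_params) != {1, 2}:
            raise ValueError("state_params must define exactly states 1 and 2")
        keys1 = set(self.state_params[1].tilt_deg)
        keys2 = set(self.state_params[2].tilt_deg)
        expected = {f"TM{i}" for i in range(1, self.n_helices + 1)}
        if keys1 != expected or keys2 != expected:
            raise ValueError("both states must give one tilt per helix TM1..TMn")
        T = np.asarray(self.transition, dtype=float)
        if T.shape != (2, 2) or np.any(T < 0) or np.any(T > 1) or \
                not np.allclose(T.sum(axis=1), 1.0):
            raise ValueError("transition must be a 2x2 row-stochastic matrix")
        if self.noise_sigma_nm < 0:
            raise ValueError("noise_sigma_nm must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.residues_per_helix < 4:
            raise ValueError("residues_per_helix must be >= 4")

    @property
    def membrane_height_nm(self) -> float:
        return (self.residues_per_helix - 1) * self.rise_nm

    def stationary(self) -> np.ndarray:
        (_, p12), (p21, _) = self.transition
        if p12 + p21 == 0:
            return np.array([1.0, 0.0])  # absorbing start in state 1
        return np.array([p21 / (p12 + p21), p12 / (p12 + p21)])


def default_config(**overrides) -> SynthConfig:
    """Benchmark conditions mirroring the studied complex's scales.

    Inactive state 1: catalytic distance 1.0 nm, ECD "up" (5.2 nm) and
    rotated right (+30 deg). Active state 2: catalytic distance 0.45 nm
    (below the 0.5 nm hydrogen-bond-competent criterion), ECD "down"
    (4.3 nm) and rotated left (-50 deg). The catalytic helices TM6/TM7
    change tilt between states; the rest of the bundle stays near-vertical.
    """
    n = overrides.get("n_helices", 9)
    base = {f"TM{i}": 10.0 for i in range(1, n + 1)}
    tilt1, tilt2 = dict(base), dict(base)
    if n >= 6:
        tilt1["TM6"], tilt2["TM6"] = 25.0, 12.0
    if n >= 7:
        tilt1["TM7"], tilt2["TM7"] = 20.0, 8.0
    cfg = SynthConfig(state_params={
        1: StateParams(tilt_deg=tilt1, dd_asp_nm=1.0, ecd_height_nm=5.2, ecd_dih_deg=30.0),
        2: StateParams(tilt_deg=tilt2, dd_asp_nm=0.45, ecd_height_nm=4.3, ecd_dih_deg=-50.0),
    })
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# geometry construction
# ---------------------------------------------------------------------------

def _ideal_helix_points(P: int, rise: float, radius: float, turn_deg: float,
                        phase: float) -> np.ndarray:
    """Centered ideal helix along +z whose best-fit line is exactly +z.

    The small correlation between the axial coordinate and the in-plane
    coordinates of a finite discrete helix is removed by an affine shear,
    so the dominant principal direction of the point cloud coincides with
    the helix axis to machine precision.
    """
    j = np.arange(P, dtype=float)
    om = np.radians(turn_deg)
    X = np.column_stack([radius * np.cos(om * j + phase),
                         radius * np.sin(om * j + phase),
                         rise * j])
    X -= X.mean(axis=0)
    z = X[:, 2]
    zz = float(z @ z)
    for k in (0, 1):
        X[:, k] -= (float(X[:, k] @ z) / zz) * z
    return X


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n, dtype=float)
    ga = np.pi * (3.0 - np.sqrt(5.0))
    zc = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - zc**2)
    pts = np.column_stack([r * np.cos(ga * k), r * np.sin(ga * k), zc])
    return pts - pts.mean(axis=0)  # exact zero centroid


_DISTAL_OFFSETS = np.array([[0.20, 0.0, 0.0],
                            [-0.10, 0.15, 0.0],
                            [-0.10, -0.15, 0.0]])  # centroid exactly 0


def _state_coords(cfg: SynthConfig, state: int) -> np.ndarray:
    """Noise-free coordinates of every atom for one conformational state."""
    sp = cfg.state_params[state]
    P = cfg.residues_per_helix
    H = cfg.membrane_height_nm
    rows = []
    # --- bundle helices (chain A) ---
    for h in range(cfg.n_helices):
        theta = 2.0 * np.pi * h / cfg.n_helices
        center = np.array([cfg.bundle_radius_nm * np.cos(theta),
                           cfg.bundle_radius_nm * np.sin(theta), H / 2.0])
        X = _ideal_helix_points(P, cfg.rise_nm, cfg.helix_radius_nm,
                                cfg.turn_deg_per_res, phase=theta)
        tilt = sp.tilt_deg[f"TM{h + 1}"]
        tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
        R = Rotation.from_rotvec(np.radians(tilt) * tangent)
        rows.append(R.apply(X) + center)
    # --- catalytic beads (exactly dd apart, mid-membrane); only bundles
    # large enough to have the catalytic helices TM6/TM7 carry them ---
    if cfg.n_helices >= 7:
        cat = np.array([[+sp.dd_asp_nm / 2.0, 0.0, H / 2.0],
                        [-sp.dd_asp_nm / 2.0, 0.0, H / 2.0]])
        rows.append(cat)
    # --- intracellular base anchor bead ---
    base = np.array([[0.0, 0.0, -0.5]])
    rows.append(base)
    ps1 = np.vstack(rows)
    g = ps1.mean(axis=0)  # catalytic-subunit center of geometry

    # --- NCT TM rod (chain B) ---
    x_t = cfg.bundle_radius_nm + 1.0
    zr = np.linspace(0.0, H, cfg.tm_rod_beads)
    rod = np.column_stack([np.full_like(zr, x_t), np.zeros_like(zr), zr])
    p1, p2 = rod[0], rod[-1]
    # --- large lobe: centroid exactly ecd_height above the bundle COG ---
    p3 = g + np.array([0.0, 0.0, sp.ecd_height_nm])
    lobe = p3 + cfg.lobe_radius_nm * _fibonacci_sphere(cfg.lobe_n_beads)
    # --- distal arm: realizes the configured dihedral exactly ---
    p4 = place_fourth_point(p1, p2, p3, sp.ecd_dih_deg,
                            distance=cfg.distal_arm_nm, angle_deg=90.0)
    distal = p4 + _DISTAL_OFFSETS
    # --- extracellular top anchor bead ---
    top = (p3 + np.array([0.0, 0.0, 1.0]))[None, :]
    return np.vstack([ps1, rod, lobe, distal, top])


def _topology_arrays(cfg: SynthConfig):
    P = cfg.residues_per_helix
    names, resids, chains, resnames, elements = [], [], [], [], []

    def add(n, resid, chain, resname="GLY", element="C"):
        names.append(n); resids.append(resid); chains.append(chain)
        resnames.append(resname); elements.append(element)

    for h in range(cfg.n_helices):
        for j in range(P):
            add("CA", h * P + j + 1, "A")
    if cfg.n_helices >= 7:
        mid6 = 5 * P + (P + 1) // 2   # mid residue of TM6
        mid7 = 6 * P + (P + 1) // 2   # mid residue of TM7
        add("CG", mid6, "A", resname="ASP")
        add("CG", mid7, "A", resname="ASP")
    else:
        mid6 = mid7 = None
    base_resid = cfg.n_helices * P + 1
    add("CA", base_resid, "A")
    for j in range(cfg.tm_rod_beads):
        add("CA", j + 1, "B")
    lobe_first = cfg.tm_rod_beads + 1
    for j in range(cfg.lobe_n_beads):
        add("CA", lobe_first + j, "B")
    distal_first = lobe_first + cfg.lobe_n_beads
    for j in range(len(_DISTAL_OFFSETS)):
        add("CA", distal_first + j, "B")
    top_resid = distal_first + len(_DISTAL_OFFSETS)
    add("CA", top_resid, "B")
    meta = {"mid6": mid6, "mid7": mid7, "base_resid": base_resid,
            "lobe_first": lobe_first, "lobe_last": distal_first - 1,
            "distal_first": distal_first, "distal_last": top_resid - 1,
            "top_resid": top_resid}
    return (np.arange(1, len(names) + 1), np.array(names, dtype=object),
            np.array(elements, dtype=object), np.array(resids, dtype=int),
            np.array(resnames, dtype=object), np.array(chains, dtype=object), meta)


def build_ideal_bundle(cfg: SynthConfig | None = None, state: int = 1) -> Structure:
    """Noise-free single structure of the bundle in one state (default 1)."""
    cfg = cfg or default_config()
    cfg.validate()
    serials, names, elements, resids, resnames, chains, _ = _topology_arrays(cfg)
    coords = _state_coords(cfg, state)
    return Structure(serials, names, elements, resids, resnames, chains, coords,
                     provenance=f"synthetic ideal bundle, state {state}")


def synthetic_topology_map(cfg: SynthConfig | None = None) -> TopologyMap:
    """Topology map naming every region of the synthetic bundle."""
    cfg = cfg or default_config()
    P = cfg.residues_per_helix
    *_, meta = _topology_arrays(cfg)
    subunits = {
        "PS1": SubunitDef(chain="A", ranges=((1, meta["base_resid"]),)),
        "NCT": SubunitDef(chain="B", ranges=((1, meta["top_resid"]),)),
    }
    helices = {f"TM{h + 1}": ("PS1", h * P + 1, (h + 1) * P)
               for h in range(cfg.n_helices)}
    return TopologyMap(
        subunits=subunits,
        helices=helices,
        catalytic_pair=(None if meta["mid6"] is None else
                        (Selector("PS1", resid=meta["mid6"], atom="CG"),
                         Selector("PS1", resid=meta["mid7"], atom="CG"))),
        nct_large_lobe=Selector("NCT", first=meta["lobe_first"], last=meta["lobe_last"]),
        dih_anchors=(Selector("NCT", resid=1, atom="CA"),
                     Selector("NCT", resid=cfg.tm_rod_beads, atom="CA"),
                     Selector("NCT", first=meta["lobe_first"], last=meta["lobe_last"]),
                     Selector("NCT", first=meta["distal_first"], last=meta["distal_last"])),
        axis_endpoints=(Selector("PS1", resid=meta["base_resid"], atom="CA"),
                        Selector("NCT", resid=meta["top_resid"], atom="CA")),
    )


# ---------------------------------------------------------------------------
# ground truth and simulation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Test oracle: hidden state path and expected order-parameter values."""

    labels: np.ndarray | None              # per-frame state in {1, 2}; None for closed form
    expected: dict[int, dict[str, float]]  # state -> OP name -> exact noise-free value
    occupancy: dict[int, float]            # realized (simulation) or stationary
    rng: str = RNG_NAME
    seed: int | None = None

    def __post_init__(self):
        occ = sum(self.occupancy.values())
        if abs(occ - 1.0) > 1e-9:
            raise ValueError("occupancies must sum to 1")
        if self.labels is not None and not np.all(np.isin(self.labels, (1, 2))):
            raise ValueError("labels must be in {1, 2}")


def _expected_ops(cfg: SynthConfig) -> dict[int, dict[str, float]]:
    tmap = synthetic_topology_map(cfg)
    serials, names, elements, resids, resnames, chains, _ = _topology_arrays(cfg)
    out: dict[int, dict[str, float]] = {}
    for state in (1, 2):
        coords = _state_coords(cfg, state)
        top = Structure(serials, names, elements, resids, resnames, chains, coords)
        series = compute_op_series(Trajectory(top, coords[None]), tmap)
        out[state] = {name: float(series[name][0]) for name in series.names}
    return out


def ground_truth(cfg: SynthConfig | None = None) -> GroundTruth:
    """Exact per-state expected order-parameter values (no simulation).

    Expected values are evaluated on the deterministically constructed
    noise-free state geometries; by construction dd_Asp, helix tilts,
    dd_PS-NCT and dih_NCT equal the configured state parameters exactly.
    Occupancy is the stationary distribution of the switching chain.
    """
    cfg = cfg or default_config()
    cfg.validate()
    pi = cfg.stationary()
    return GroundTruth(labels=None, expected=_expected_ops(cfg),
                       occupancy={1: float(pi[0]), 2: float(pi[1])}, seed=None)


def simulate_two_state_trajectory(cfg: SynthConfig | None = None
                                  ) -> tuple[Trajectory, GroundTruth]:
    """Sample a hidden two-state Markov path and emit noisy frames.

    Each frame is the rigid noise-free geometry of its state plus i.i.d.
    isotropic Gaussian displacement of every atom (no within-state
    kinetics). Fully reproducible for a fixed ``cfg.seed``.
    """
    cfg = cfg or default_config()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    T = np.asarray(cfg.transition, dtype=float)
    labels = np.empty(cfg.n_frames, dtype=int)
    state = 1 + int(rng.random() < cfg.stationary()[1])
    for f in range(cfg.n_frames):
        labels[f] = state
        state = 1 + int(rng.random() < T[state - 1, 1])

    serials, names, elements, resids, resnames, chains, _ = _topology_arrays(cfg)
    state_xyz = {s: _state_coords(cfg, s) for s in (1, 2)}
    n_atoms = state_xyz[1].shape[0]
    coords = np.empty((cfg.n_frames, n_atoms, 3))
    for s in (1, 2):
        coords[labels == s] = state_xyz[s]
    if cfg.noise_sigma_nm > 0:
        coords += rng.normal(0.0, cfg.noise_sigma_nm, size=coords.shape)

    top = Structure(serials, names, elements, resids, resnames, chains,
                    state_xyz[1], provenance=f"synthetic two-state trajectory (seed {cfg.seed})")
    traj = Trajectory(top, coords, times=np.arange(cfg.n_frames) * cfg.dt_ns)
    occ2 = float(np.mean(labels == 2))
    gt = GroundTruth(labels=labels, expected=_expected_ops(cfg),
                     occupancy={1: 1.0 - occ2, 2: occ2}, seed=cfg.seed)
    return traj, gt


def truth_table(gt: GroundTruth) -> pd.DataFrame:
    """Per-frame truth as a flat table (frame, state, expected OP values)."""
    if gt.labels is None:
        raise ValueError("closed-form ground truth has no per-frame labels")
    df = pd.DataFrame({"frame": np.arange(len(gt.labels)), "state": gt.labels})
    op_names = list(next(iter(gt.expected.values())))
    for name in op_names:
        df[name] = [gt.expected[int(s)][name] for s in gt.labels]
    return df
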