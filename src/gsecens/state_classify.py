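"""Frame-by-frame functional-state assignment from order parameters.

Thresholds follow the literature landmarks for the complex: the catalytic
subunit is in the active state 2 when the catalytic aspartate distance
``dd_Asp`` drops below 0.5 nm (the hydrogen-bond-competent geometry); the
nicastrin ECD is "up" above 5.0 nm and "down" below 4.5 nm of
``dd_PS-NCT``; negative ``dih_NCT`` is leftward rotation (the preferred
lobe orientation sits near -50 degrees). Classification is instantaneous
geometry — no temporal smoothing is applied by default.

Boundary behavior is fixed and documented: values exactly at a threshold
go to the inactive / lower / rightward label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Thresholds",
    "StateLabels",
    "classify_ps1_state",
    "classify_nct_vertical",
    "classify_nct_rotation",
    "classify_length_state",
    "classify_all",
    "majority_filter",
    "state_summary",
]


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for every label family.

    ``dd_asp_active_upper_fluct`` is diagnostic only: the active state is
    reported to fluctuate without exceeding this distance, but it plays no
    role in the classification itself. ``length_edges`` may be ``"auto"``
    to fit a 3-component Gaussian mixture to the major-axis lengths.
    """

    dd_asp_active: float = 0.5            # nm; state 2 iff dd_Asp strictly below
    dd_asp_active_upper_fluct: float = 0.75  # nm; diagnostic envelope of state 2
    nct_up: float = 5.0                   # nm; "up" strictly above
    nct_down: float = 4.5                 # nm; "down" strictly below
    rotation_zero: float = 0.0            # deg; left strictly below
    length_edges: tuple[float, float] | str = "auto"

    def __post_init__(self):
        if self.dd_asp_active <= 0:
            raise ValueError("dd_asp_active must be > 0")
        if not self.nct_down < self.nct_up:
            raise ValueError("need nct_down < nct_up")
        if not isinstance(self.length_edges, str):
            e1, e2 = self.length_edges
            if not e1 < e2:
                raise ValueError("length edges must be strictly increasing")


def _require_nonempty(series: np.ndarray) -> np.ndarray:
    s = np.asarray(series, dtype=float)
    if s.size == 0:
        raise ValueError("empty order-parameter series")
    return s


def classify_ps1_state(dd_asp: np.ndarray, thr: Thresholds = Thresholds()) -> np.ndarray:
    """Active/inactive catalytic-subunit state from the aspartate distance.

    Label 2 (active) iff ``dd_asp < dd_asp_active`` (strict; a frame
    exactly at the threshold is inactive state 1).
    """
    s = _require_nonempty(dd_asp)
    return np.where(s < thr.dd_asp_active, 2, 1)


def classify_nct_vertical(dd_ps_nct: np.ndarray,
                          thr: Thresholds = Thresholds()) -> np.ndarray:
    """ECD up/intermediate/down from the subunit-lobe distance."""
    s = _require_nonempty(dd_ps_nct)
    out = np.full(s.shape, "intermediate", dtype=object)
    out[s > thr.nct_up] = "up"
    out[s < thr.nct_down] = "down"
    return out


def classify_nct_rotation(dih_nct: np.ndarray,
                          thr: Thresholds = Thresholds()) -> np.ndarray:
    """ECD left/right rotation; negative dihedral = left, 0 goes right."""
    s = _require_nonempty(dih_nct)
    return np.where(s < thr.rotation_zero, "left", "right").astype(object)


_LENGTH_LABELS = np.array(["compact", "intermediate", "extended"], dtype=object)


def _auto_length_edges(s: np.ndarray, seed: int = 0) -> tuple[float, float]:
    """Posterior-crossover edges of a 3-component 1-D Gaussian mixture.

    Means are initialized at the 1/6, 3/6, 5/6 quantiles (deterministic);
    on non-convergence or collapsed components the quantile terciles are
    used instead, with a warning.
    """
    from sklearn.mixture import GaussianMixture

    x = s.reshape(-1, 1)
    means_init = np.quantile(s, [1 / 6, 3 / 6, 5 / 6]).reshape(-1, 1)
    try:
        gm = GaussianMixture(n_components=3, means_init=means_init,
                             random_state=seed, n_init=1, max_iter=500)
        gm.fit(x)
        converged = gm.converged_
    except Exception:
        converged = False
    if converged:
        order = np.argsort(gm.means_.ravel())
        grid = np.linspace(s.min(), s.max(), 4096)
        post = gm.predict_proba(grid.reshape(-1, 1))[:, order]
        hard = np.argmax(post, axis=1)
        changes = np.flatnonzero(np.diff(hard) > 0)
        if len(changes) >= 2 and len(np.unique(hard)) == 3:
            e1 = float(0.5 * (grid[changes[0]] + grid[changes[0] + 1]))
            e2 = float(0.5 * (grid[changes[-1]] + grid[changes[-1] + 1]))
            return e1, e2
    warnings.warn("3-component mixture fit failed or collapsed; "
                  "falling back to quantile terciles", stacklevel=3)
    e1, e2 = np.quantile(s, [1 / 3, 2 / 3])
    return float(e1), float(e2)


def classify_length_state(axis_length: np.ndarray,
                          thr: Thresholds = Thresholds(),
                          seed: int = 0) -> np.ndarray:
    """Compact / intermediate / extended from the complex major-axis length.

    With explicit ``length_edges`` (e1, e2): compact strictly below e1,
    extended strictly above e2, intermediate otherwise. With ``"auto"``,
    edges come from a seeded 3-component Gaussian-mixture fit
    (>= 100 samples required).
    """
    s = _require_nonempty(axis_length)
    if isinstance(thr.length_edges, str):
        if thr.length_edges != "auto":
            raise ValueError(f"unknown length_edges mode {thr.length_edges!r}")
        if s.size < 100:
            raise ValueError("auto length edges need at least 100 samples")
        e1, e2 = _auto_length_edges(s, seed=seed)
    else:
        e1, e2 = thr.length_edges
    bins = np.ones(s.shape, dtype=int)     # edge values belong to intermediate
    bins[s < e1] = 0
    bins[s > e2] = 2
    return _LENGTH_LABELS[bins]


@dataclass
class StateLabels:
    """Per-frame categorical assignments plus the thresholds that made them."""

    ps1_state: np.ndarray           # {1, 2}
    nct_vertical: np.ndarray        # {"up", "intermediate", "down"}
    nct_rotation: np.ndarray        # {"left", "right"}
    global_form: np.ndarray | None  # {"compact", "intermediate", "extended"}
    thresholds: Thresholds = field(default_factory=Thresholds)

    def families(self) -> dict[str, np.ndarray]:
        fams = {"ps1_state": self.ps1_state,
                "nct_vertical": self.nct_vertical,
                "nct_rotation": self.nct_rotation}
        if self.global_form is not None:
            fams["global_form"] = self.global_form
        return fams

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"frame": np.arange(len(self.ps1_state))})
        for name, arr in self.families().items():
            df[name] = arr
        return df


def classify_all(series, thr: Thresholds = Thresholds(), seed: int = 0) -> StateLabels:
    """Classify every family available in an order-parameter series."""
    return StateLabels(
        ps1_state=classify_ps1_state(series["dd_Asp"], thr),
        nct_vertical=classify_nct_vertical(series["dd_PS-NCT"], thr),
        nct_rotation=classify_nct_rotation(series["dih_NCT"], thr),
        global_form=(classify_length_state(series["axis_length"], thr, seed=seed)
                     if "axis_length" in series.names else None),
        thresholds=thr,
    )


def majority_filter(labels: np.ndarray, k: int) -> np.ndarray:
    """Optional odd-window majority vote over consecutive frames."""
    if k % 2 != 1 or k < 1:
        raise ValueError("window k must be odd and >= 1")
    if k == 1:
        return np.asarray(labels).copy()
    lab = np.asarray(labels)
    half = k // 2
    out = lab.copy()
    for i in range(lab.size):
        w = lab[max(0, i - half):i + half + 1]
        vals, counts = np.unique(w, return_counts=True)
        out[i] = vals[np.argmax(counts)]
    return out


def state_summary(labels: StateLabels) -> pd.DataFrame:
    """Occupancy fractions and consecutive-frame transition counts per family."""
    rows = []
    for family, arr in labels.families().items():
        n = len(arr)
        if n == 0:
            raise ValueError(f"empty label family {family}")
        transitions = int(np.sum(arr[1:] != arr[:-1]))
        vals, counts = np.unique(arr.astype(str), return_counts=True)
        for v, c in zip(vals, counts):
            rows.append({"family": family, "label": v,
                         "occupancy": c / n, "transitions": transitions})
    return pd.DataFrame(rows)
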