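"""Coordinate I/O, atom selections and the topology map.

All coordinates are stored internally in **nanometres**; PDB files are
Angstrom and converted on read/write. Residue numbers are taken verbatim
from the file (author numbering, 1-based) — no renumbering is ever applied,
so catalytic residues keep their literature numbering (e.g. PS1 Asp257 and
Asp385).

Input structures are assumed pre-oriented with the membrane normal along
+z (the OPM convention); no orientation step is performed here.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

ANG_PER_NM = 10.0

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "Selector",
    "SubunitDef",
    "TopologyMap",
    "SelectionError",
    "TopologyError",
    "FormatError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "resolve_selection",
    "fetch_pdb",
]


class FormatError(ValueError):
    """File parsed but violates the expected structural contract."""


class SelectionError(KeyError):
    """A selector does not resolve to the required atoms."""


class TopologyError(ValueError):
    """Trajectory frames inconsistent with the supplied topology."""


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    resid: int
    resname: str
    chain: str
    coords: np.ndarray  # (3,), nm


class Structure:
    """A topology-bearing set of atoms with one coordinate per atom.

    Parallel numpy arrays keep selection and geometry fast; the ``atoms``
    iterator exposes per-atom records for convenience.
    """

    def __init__(
        self,
        serials: np.ndarray,
        names: np.ndarray,
        elements: np.ndarray,
        resids: np.ndarray,
        resnames: np.ndarray,
        chains: np.ndarray,
        coords: np.ndarray,
        box: np.ndarray | None = None,
        provenance: str = "<memory>",
    ):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
            raise FormatError("Structure needs an (N, 3) coordinate array with N >= 1")
        if not np.all(np.isfinite(coords)):
            raise FormatError("non-finite coordinates")
        n = coords.shape[0]
        for arr, label in ((serials, "serials"), (names, "names"), (elements, "elements"),
                           (resids, "resids"), (resnames, "resnames"), (chains, "chains")):
            if len(arr) != n:
                raise FormatError(f"{label} length {len(arr)} != atom count {n}")
        if box is not None:
            box = np.asarray(box, dtype=float)
            if box.shape != (3,) or np.any(box <= 0):
                raise FormatError("box must be a positive 3-vector (nm)")
        self.serials = np.asarray(serials, dtype=int)
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.resids = np.asarray(resids, dtype=int)
        self.resnames = np.asarray(resnames, dtype=object)
        self.chains = np.asarray(chains, dtype=object)
        self.coords = coords
        self.box = box
        self.provenance = provenance

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_atoms

    @property
    def atoms(self) -> Iterator[Atom]:
        for i in range(self.n_atoms):
            yield Atom(int(self.serials[i]), str(self.names[i]), str(self.elements[i]),
                       int(self.resids[i]), str(self.resnames[i]), str(self.chains[i]),
                       self.coords[i])

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates (nm)."""
        return Structure(self.serials, self.names, self.elements, self.resids,
                         self.resnames, self.chains, np.asarray(coords, dtype=float),
                         box=self.box, provenance=self.provenance)


class Trajectory:
    """An ordered stack of frames sharing one topology.

    ``coords`` is (n_frames, n_atoms, 3) in nm; ``times`` in ns,
    non-decreasing. When the source format carries no time records, times
    default to the frame index.
    """

    def __init__(self, topology: Structure, coords: np.ndarray,
                 times: np.ndarray | None = None):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise TopologyError("trajectory coords must be (frames, atoms, 3)")
        if coords.shape[0] == 0:
            raise TopologyError("trajectory must contain at least one frame")
        if coords.shape[1] != topology.n_atoms:
            raise TopologyError(
                f"frame atom count {coords.shape[1]} != topology atom count {topology.n_atoms}")
        if times is None:
            times = np.arange(coords.shape[0], dtype=float)
        times = np.asarray(times, dtype=float)
        if times.shape != (coords.shape[0],):
            raise TopologyError("times length must equal frame count")
        if np.any(np.diff(times) < 0):
            raise TopologyError("frame times must be non-decreasing")
        self.topology = topology
        self.coords = coords
        self.times = times

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Selector:
    """Names a set of atoms inside one subunit.

    Two shapes are accepted:

    * single atom — ``resid`` and ``atom`` set (must resolve to exactly one
      atom);
    * residue range — ``first``/``last`` set, optionally restricted to one
      atom name per residue (``atom``, e.g. ``CA``).
    """

    subunit: str
    resid: int | None = None
    first: int | None = None
    last: int | None = None
    atom: str | None = None

    def __post_init__(self):
        single = self.resid is not None
        ranged = self.first is not None or self.last is not None
        if single == ranged:
            raise ValueError("selector must set either resid or first/last")
        if ranged and (self.first is None or self.last is None or self.last < self.first):
            raise ValueError("range selector needs first <= last")
        if single and self.atom is None:
            raise ValueError("single-atom selector needs an atom name")

    @property
    def is_single(self) -> bool:
        return self.resid is not None

    @classmethod
    def from_dict(cls, d: Mapping) -> "Selector":
        return cls(subunit=d["subunit"], resid=d.get("resid"),
                   first=d.get("first"), last=d.get("last"), atom=d.get("atom"))

    def to_dict(self) -> dict:
        out = {"subunit": self.subunit}
        if self.resid is not None:
            out["resid"] = int(self.resid)
        else:
            out["first"], out["last"] = int(self.first), int(self.last)
        if self.atom is not None:
            out["atom"] = self.atom
        return out


@dataclass(frozen=True)
class SubunitDef:
    chain: str
    ranges: tuple[tuple[int, int], ...]  # inclusive author-numbered resid ranges

    def mask(self, s: Structure) -> np.ndarray:
        m = s.chains == self.chain
        in_range = np.zeros(s.n_atoms, dtype=bool)
        for lo, hi in self.ranges:
            in_range |= (s.resids >= lo) & (s.resids <= hi)
        return m & in_range


@dataclass
class TopologyMap:
    """Names every region the analysis references.

    ``helices`` maps a TM-helix name to (subunit, first_resid, last_resid);
    ``catalytic_pair`` are two single-atom selectors (the catalytic Asp
    side-chain gamma carbons); ``dih_anchors`` are the four points of the
    nicastrin-rotation dihedral; ``axis_endpoints`` are the lower
    intracellular and upper extracellular anchor selections of the complex
    major axis.
    """

    subunits: dict[str, SubunitDef]
    helices: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    catalytic_pair: tuple[Selector, Selector] | None = None
    nct_large_lobe: Selector | None = None
    dih_anchors: tuple[Selector, Selector, Selector, Selector] | None = None
    axis_endpoints: tuple[Selector, Selector] | None = None
    membrane_normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        self.membrane_normal = np.asarray(self.membrane_normal, dtype=float)
        nrm = np.linalg.norm(self.membrane_normal)
        if nrm == 0:
            raise ValueError("membrane_normal must be nonzero")
        self.membrane_normal = self.membrane_normal / nrm
        for name, (sub, lo, hi) in self.helices.items():
            if sub not in self.subunits:
                raise ValueError(f"helix {name}: unknown subunit {sub}")
            if hi < lo:
                raise ValueError(f"helix {name}: empty residue range")

    # -- config file round trip -------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "TopologyMap":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "TopologyMap":
        subunits = {
            name: SubunitDef(chain=str(d["chain"]),
                             ranges=tuple((int(a), int(b)) for a, b in d["ranges"]))
            for name, d in doc["subunits"].items()
        }
        helices = {name: (d["subunit"], int(d["first"]), int(d["last"]))
                   for name, d in doc.get("helices", {}).items()}

        def sel(key, n=None):
            if key not in doc or doc[key] is None:
                return None
            v = doc[key]
            if isinstance(v, Mapping):
                return Selector.from_dict(v)
            out = tuple(Selector.from_dict(x) for x in v)
            if n is not None and len(out) != n:
                raise ValueError(f"{key}: expected {n} selectors, got {len(out)}")
            return out

        return cls(
            subunits=subunits,
            helices=helices,
            catalytic_pair=sel("catalytic_pair", 2),
            nct_large_lobe=sel("nct_large_lobe"),
            dih_anchors=sel("dih_anchors", 4),
            axis_endpoints=sel("axis_endpoints", 2),
            membrane_normal=np.asarray(doc.get("membrane_normal", [0.0, 0.0, 1.0]), dtype=float),
        )

    def to_dict(self) -> dict:
        doc: dict = {
            "subunits": {n: {"chain": d.chain, "ranges": [list(r) for r in d.ranges]}
                         for n, d in self.subunits.items()},
            "helices": {n: {"subunit": s, "first": a, "last": b}
                        for n, (s, a, b) in self.helices.items()},
            "membrane_normal": [float(x) for x in self.membrane_normal],
        }
        if self.catalytic_pair:
            doc["catalytic_pair"] = [s.to_dict() for s in self.catalytic_pair]
        if self.nct_large_lobe:
            doc["nct_large_lobe"] = self.nct_large_lobe.to_dict()
        if self.dih_anchors:
            doc["dih_anchors"] = [s.to_dict() for s in self.dih_anchors]
        if self.axis_endpoints:
            doc["axis_endpoints"] = [s.to_dict() for s in self.axis_endpoints]
        return doc

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def helix_selector(self, name: str, atom: str = "CA") -> Selector:
        sub, lo, hi = self.helices[name]
        return Selector(subunit=sub, first=lo, last=hi, atom=atom)


def resolve_selection(s: Structure, selector: Selector, tmap: TopologyMap,
                      required: bool = True) -> np.ndarray:
    """Resolve a selector to atom indices in file order.

    Deterministic: the same selector on the same structure always returns
    the identical index list. An empty result raises
    :class:`SelectionError` when ``required`` (the default).
    """
    try:
        sub = tmap.subunits[selector.subunit]
    except KeyError:
        raise SelectionError(f"unknown subunit {selector.subunit!r}") from None
    m = sub.mask(s)
    if selector.is_single:
        m = m & (s.resids == selector.resid) & (s.names == selector.atom)
    else:
        m = m & (s.resids >= selector.first) & (s.resids <= selector.last)
        if selector.atom is not None:
            m = m & (s.names == selector.atom)
    idx = np.flatnonzero(m)
    if required and idx.size == 0:
        raise SelectionError(f"selector {selector} matched no atoms")
    if selector.is_single and idx.size > 1:
        raise SelectionError(f"single-atom selector {selector} matched {idx.size} atoms")
    return idx


# ---------------------------------------------------------------------------
# PDB I/O (biotite backend)
# ---------------------------------------------------------------------------

def _structure_from_atom_array(arr: bst.AtomArray, provenance: str) -> Structure:
    box = None
    if arr.box is not None:
        lengths = np.linalg.norm(np.asarray(arr.box), axis=-1) / ANG_PER_NM
        if np.all(lengths > 0):
            box = lengths
    serial = (arr.get_annotation("atom_id") if "atom_id" in arr.get_annotation_categories()
              else np.arange(1, arr.array_length() + 1))
    return Structure(
        serials=serial,
        names=arr.atom_name.astype(object),
        elements=arr.element.astype(object),
        resids=arr.res_id,
        resnames=arr.res_name.astype(object),
        chains=arr.chain_id.astype(object),
        coords=np.asarray(arr.coord, dtype=float) / ANG_PER_NM,
        box=box,
        provenance=provenance,
    )


def _warn_on_altlocs(pdb: PDBFile, path) -> None:
    alt = set()
    for line in pdb.lines:
        if line.startswith(("ATOM", "HETATM")) and len(line) > 16 and line[16] not in (" ", "A"):
            alt.add(line[16])
    if alt:
        warnings.warn(f"{path}: alternate locations {sorted(alt)} discarded "
                      "(keeping altloc 'A'/blank)", stacklevel=3)


def read_structure(path: str | os.PathLike, format: str = "pdb") -> Structure:
    """Read a coordinate file; multi-model files return the first model."""
    if format.lower() != "pdb":
        raise ValueError(f"unsupported structure format {format!r}")
    try:
        pdb = PDBFile.read(str(path))
    except OSError:
        raise
    except Exception as exc:  # malformed records
        raise FormatError(f"{path}: not parseable as PDB: {exc}") from exc
    _warn_on_altlocs(pdb, path)
    try:
        arr = pdb.get_structure(model=1, altloc="first", extra_fields=["atom_id"])
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if arr.array_length() == 0:
        raise FormatError(f"{path}: no atoms")
    return _structure_from_atom_array(arr, provenance=f"{path} (pdb)")


def read_trajectory(path: str | os.PathLike, topology: Structure | None = None,
                    format: str | None = None) -> Trajectory:
    """Read a trajectory: multi-model PDB natively, XTC/DCD via mdtraj.

    Frame times are synthesized as the frame index (ns) when the format
    stores none; multi-model PDB stores none.
    """
    path = str(path)
    if format is None:
        ext = Path(path).suffix.lower().lstrip(".")
        format = {"pdb": "multi-model-pdb"}.get(ext, ext)
    if format == "multi-model-pdb":
        pdb = PDBFile.read(path)
        _warn_on_altlocs(pdb, path)
        stack = pdb.get_structure(altloc="first", extra_fields=["atom_id"])
        if stack.array_length() == 0:
            raise FormatError(f"{path}: no atoms")
        top = _structure_from_atom_array(stack[0], provenance=f"{path} (multi-model-pdb)")
        coords = np.asarray(stack.coord, dtype=float) / ANG_PER_NM
        if coords.ndim == 2:  # single model
            coords = coords[None]
    elif format in ("xtc", "dcd"):
        if topology is None:
            raise TopologyError(f"{format} trajectories need an explicit topology Structure")
        import mdtraj  # optional backend

        with mdtraj.open(path) as fh:
            data = fh.read()
        xyz = data[0] if isinstance(data, tuple) else data
        coords = np.asarray(xyz, dtype=float)
        if format == "dcd":
            coords = coords / ANG_PER_NM  # mdtraj raw DCD reader yields Angstrom
        top = topology
    else:
        raise ValueError(f"unsupported trajectory format {format!r}")
    if topology is not None:
        if coords.shape[1] != topology.n_atoms:
            raise TopologyError(
                f"{path}: {coords.shape[1]} atoms per frame, topology has {topology.n_atoms}")
        top = topology
    return Trajectory(top, coords)


def _atom_array_from_structure(s: Structure) -> bst.AtomArray:
    n = s.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(s.coords, dtype=np.float32) * ANG_PER_NM
    arr.chain_id = s.chains.astype("U4")
    arr.res_id = s.resids
    arr.res_name = s.resnames.astype("U5")
    arr.atom_name = s.names.astype("U6")
    arr.element = s.elements.astype("U2")
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("atom_id", s.serials)
    if s.box is not None:
        arr.box = np.diag(s.box * ANG_PER_NM)
    return arr


def write_structure(s: Structure, path: str | os.PathLike) -> None:
    pdb = PDBFile()
    pdb.set_structure(_atom_array_from_structure(s))
    pdb.write(str(path))


def write_trajectory(t: Trajectory, path: str | os.PathLike) -> None:
    """Write a trajectory as multi-model PDB (MODEL/ENDMDL)."""
    if t.n_frames == 0:
        raise TopologyError("refusing to write a 0-frame trajectory")
    base = _atom_array_from_structure(t.topology)
    stack = bst.AtomArrayStack(t.n_frames, t.n_atoms)
    for cat in base.get_annotation_categories():
        stack.set_annotation(cat, base.get_annotation(cat))
    stack.coord = np.asarray(t.coords, dtype=np.float32) * ANG_PER_NM
    if t.topology.box is not None:
        stack.box = np.repeat(np.diag(t.topology.box * ANG_PER_NM)[None], t.n_frames, axis=0)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Remote structures
# ---------------------------------------------------------------------------

def fetch_pdb(pdb_id: str, cache_dir: str | os.PathLike | None = None) -> Path:
    """Locate (or download) a PDB entry, returning the local file path.

    Search order: ``cache_dir`` if given, then ``./data``, then
    ``~/.cache/gsecens``. If absent, attempts an RCSB download into the
    cache; raises ``OSError`` when the file is unavailable and the machine
    is offline.
    """
    pdb_id = pdb_id.lower()
    fname = f"{pdb_id}.pdb"
    candidates = []
    if cache_dir is not None:
        candidates.append(Path(cache_dir) / fname)
    candidates.append(Path("data") / fname)
    default_cache = Path.home() / ".cache" / "gsecens"
    candidates.append(default_cache / fname)
    for c in candidates:
        if c.is_file():
            return c
    target = Path(cache_dir) / fname if cache_dir is not None else default_cache / fname
    target.parent.mkdir(parents=True, exist_ok=True)
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    import urllib.request

    try:
        with urllib.request.urlopen(url, timeout=30) as resp:
            data = resp.read()
    except Exception as exc:
        raise OSError(
            f"PDB entry {pdb_id.upper()} not found locally ({', '.join(map(str, candidates))}) "
            f"and download from {url} failed: {exc}") from exc
    target.write_bytes(data)
    return target
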