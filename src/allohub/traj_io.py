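"""Trajectory, topology and alignment input/output.

Coordinates are stored in nanometres throughout the package; PDB files
(which use angstroms) are converted on read and write.  Times are in
nanoseconds; masses in daltons.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.info as struc_info
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Trajectory",
    "CalphaChain",
    "FormatError",
    "read_pdb_multimodel",
    "write_pdb_multimodel",
    "read_table_traj",
    "write_table_traj",
    "select_calpha",
    "write_sa_fasta",
    "read_sa_fasta",
]

ANGSTROM_PER_NM = 10.0

#: topology columns required by every constructor
TOPOLOGY_COLUMNS = ("chain_id", "res_id", "res_name", "atom_name", "mass")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class Trajectory:
    """A Cartesian coordinate trajectory plus per-atom topology.

    Attributes
    ----------
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Positions in nm.
    times : ndarray, shape (n_frames,)
        Frame times in ns, strictly increasing.
    topology : pandas.DataFrame
        One row per atom with columns ``chain_id``, ``res_id`` (1-based),
        ``res_name``, ``atom_name`` and ``mass`` (Da).
    """

    coords: np.ndarray
    times: np.ndarray
    topology: pd.DataFrame

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords must have shape (frames, atoms, 3), got {self.coords.shape}"
            )
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (self.coords.shape[0],):
            raise ValueError("times must have one entry per frame")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        missing = [c for c in TOPOLOGY_COLUMNS if c not in self.topology.columns]
        if missing:
            raise ValueError(f"topology is missing columns {missing}")
        if len(self.topology) != self.coords.shape[1]:
            raise ValueError(
                f"topology has {len(self.topology)} atoms but coordinates "
                f"have {self.coords.shape[1]}"
            )
        if not np.all(self.topology["mass"].to_numpy() > 0):
            raise ValueError("all atomic masses must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class CalphaChain:
    """Ordered Cα selection for one chain."""

    chain_id: str
    atom_indices: np.ndarray  # indices into Trajectory.topology rows
    res_ids: np.ndarray  # 1-based residue indices, strictly increasing

    def __post_init__(self) -> None:
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        if self.res_ids.size > 1 and not np.all(np.diff(self.res_ids) > 0):
            raise ValueError(
                f"residue indices not strictly increasing in chain {self.chain_id!r}"
            )

    def __len__(self) -> int:
        return len(self.atom_indices)


def _element_mass(element: str) -> float:
    """Standard atomic weight for an element symbol (Da)."""
    element = element.strip().capitalize()
    if not element:
        raise FormatError("atom with empty element symbol; cannot assign mass")
    try:
        mass = struc_info.mass(element, is_residue=False)
    except KeyError:
        mass = None
    if mass is None or mass <= 0:
        raise FormatError(f"unknown element {element!r}; cannot assign mass")
    return float(mass)


def _model_atom_counts(path: str) -> list[int]:
    """Per-MODEL ATOM/HETATM record counts (single implicit model if no MODEL)."""
    counts: list[int] = []
    current = 0
    seen_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                if seen_model:
                    counts.append(current)
                seen_model = True
                current = 0
            elif rec in ("ATOM", "HETATM"):
                current += 1
    counts.append(current)
    return counts


def read_pdb_multimodel(path: str) -> Trajectory:
    """Read a (possibly multi-model) PDB file as a trajectory.

    Each MODEL becomes one frame; a single-structure file yields one frame.
    Frame times are assigned 0, 1, 2, ... (frame units) since PDB carries no
    time information.  Masses come from the element symbol.
    """
    counts = _model_atom_counts(path)
    if sum(counts) == 0:
        raise FormatError(f"{path}: no ATOM/HETATM records found")
    for i, c in enumerate(counts[1:], start=2):
        if c != counts[0]:
            raise FormatError(
                f"{path}: model {i} has {c} atoms, expected {counts[0]} "
                f"(model 1)"
            )

    pdb = PDBFile.read(path)
    stack = pdb.get_structure(model=None)  # AtomArrayStack, Å
    if isinstance(stack, struc.AtomArray):  # pragma: no cover - defensive
        stack = struc.stack([stack])

    coords = np.asarray(stack.coord, dtype=float) / ANGSTROM_PER_NM
    elements = stack.element
    masses = np.array([_element_mass(e) for e in elements])
    topology = pd.DataFrame(
        {
            "chain_id": stack.chain_id,
            "res_id": stack.res_id.astype(int),
            "res_name": stack.res_name,
            "atom_name": stack.atom_name,
            "element": elements,
            "mass": masses,
        }
    )
    times = np.arange(coords.shape[0], dtype=float)
    return Trajectory(coords=coords, times=times, topology=topology)


def write_pdb_multimodel(traj: Trajectory, path: str) -> None:
    """Write a trajectory as a multi-model PDB (coordinates nm -> Å)."""
    n_atoms = traj.n_atoms
    atoms = struc.AtomArray(n_atoms)
    atoms.chain_id = traj.topology["chain_id"].to_numpy(dtype="U4")
    atoms.res_id = traj.topology["res_id"].to_numpy()
    atoms.res_name = traj.topology["res_name"].to_numpy(dtype="U5")
    atoms.atom_name = traj.topology["atom_name"].to_numpy(dtype="U6")
    if "element" in traj.topology.columns:
        atoms.element = traj.topology["element"].to_numpy(dtype="U2")
    else:
        atoms.element = np.array(
            [n.strip()[:1] for n in traj.topology["atom_name"]], dtype="U2"
        )
    stack = struc.stack([atoms] * traj.n_frames)
    stack.coord = traj.coords * ANGSTROM_PER_NM
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)


def read_topology_table(path: str) -> pd.DataFrame:
    """Read a per-atom topology sidecar (CSV or whitespace-delimited).

    Required columns: chain_id, res_id, res_name, atom_name and either
    mass or element (mass wins when both are present).
    """
    topo = _read_delimited(path)
    topo.columns = [str(c).strip().lower() for c in topo.columns]
    if "mass" not in topo.columns:
        if "element" not in topo.columns:
            raise FormatError(
                f"{path}: topology needs a 'mass' or 'element' column"
            )
        topo["mass"] = [_element_mass(e) for e in topo["element"]]
    missing = [c for c in TOPOLOGY_COLUMNS if c not in topo.columns]
    if missing:
        raise FormatError(f"{path}: topology missing columns {missing}")
    topo["res_id"] = topo["res_id"].astype(int)
    return topo


def _read_delimited(path: str) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
    sep = "," if "," in first else r"\s+"
    return pd.read_csv(path, sep=sep, comment="#")


def read_table_traj(path: str, topology_path: str) -> Trajectory:
    """Read a plain-text frames x (3*atoms) coordinate table (nm) + topology."""
    arr = np.loadtxt(path, delimiter="," if _is_csv(path) else None, comments="#")
    arr = np.atleast_2d(arr)
    if arr.shape[1] % 3 != 0:
        raise FormatError(
            f"{path}: {arr.shape[1]} columns is not divisible by 3"
        )
    n_frames, n_atoms = arr.shape[0], arr.shape[1] // 3
    topo = read_topology_table(topology_path)
    if len(topo) != n_atoms:
        raise FormatError(
            f"coordinate table implies {n_atoms} atoms but topology "
            f"{topology_path} lists {len(topo)}"
        )
    coords = arr.reshape(n_frames, n_atoms, 3)
    return Trajectory(
        coords=coords, times=np.arange(n_frames, dtype=float), topology=topo
    )


def _is_csv(path: str) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "," in line
    return False


def write_table_traj(traj: Trajectory, path: str, topology_path: str) -> None:
    """Write the coordinate table and topology sidecar (inverse of read_table_traj)."""
    flat = traj.coords.reshape(traj.n_frames, -1)
    np.savetxt(path, flat, fmt="%.17g")
    traj.topology.to_csv(topology_path, index=False)


def select_calpha(traj: Trajectory) -> list[CalphaChain]:
    """Select Cα atoms per chain, in residue order.

    Chains with fewer than 4 residues cannot host a 4-residue fragment;
    they are excluded with a warning.
    """
    topo = traj.topology
    is_ca = topo["atom_name"].astype(str).str.strip() == "CA"
    if not is_ca.any():
        raise ValueError("trajectory contains no Cα (atom name 'CA') atoms")
    chains: list[CalphaChain] = []
    for chain_id, sub in topo[is_ca].groupby("chain_id", sort=True):
        sub = sub.sort_values("res_id")
        if len(sub) < 4:
            warnings.warn(
                f"chain {chain_id!r} has only {len(sub)} residues (<4); "
                "excluded from fragment encoding",
                stacklevel=2,
            )
            continue
        chains.append(
            CalphaChain(
                chain_id=str(chain_id),
                atom_indices=sub.index.to_numpy(),
                res_ids=sub["res_id"].to_numpy(),
            )
        )
    return chains


# ---------------------------------------------------------------------------
# Structural-alphabet alignment FASTA
# ---------------------------------------------------------------------------

def write_sa_fasta(alignment, path: str) -> None:
    """Write an encoded alignment as FASTA, one record per frame.

    Column metadata (chain id and first residue of each fragment) and the
    source id go to a ``<path>.meta.json`` sidecar so that
    :func:`read_sa_fasta` round-trips losslessly.
    """
    if alignment.n_frames == 0 or alignment.n_columns == 0:
        raise ValueError("refusing to write an empty alignment")
    with open(path, "w") as fh:
        for f in range(alignment.n_frames):
            t = alignment.times[f] if alignment.times is not None else f
            fh.write(f">frame_{f} time={t:g}\n")
            fh.write("".join(alignment.letters[f]) + "\n")
    meta = {
        "source": alignment.source,
        "columns": [[str(c), int(r)] for c, r in alignment.columns],
    }
    with open(path + ".meta.json", "w") as fh:
        json.dump(meta, fh)


def read_sa_fasta(path: str):
    """Read a stacked structural-alphabet alignment written by write_sa_fasta."""
    from .alphabet import SAAlignment  # local import to avoid a cycle

    headers: list[str] = []
    rows: list[str] = []
    with open(path) as fh:
        seq: list[str] = []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if seq:
                    rows.append("".join(seq))
                    seq = []
                headers.append(line[1:])
            else:
                seq.append(line)
        if seq:
            rows.append("".join(seq))
    if not rows:
        raise FormatError(f"{path}: no FASTA records found")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise FormatError(f"{path}: records have differing lengths {sorted(lengths)}")
    letters = np.array([list(r) for r in rows], dtype="U1")
    times = []
    for i, h in enumerate(headers):
        t = i
        for tok in h.split():
            if tok.startswith("time="):
                t = float(tok[5:])
        times.append(t)
    try:
        with open(path + ".meta.json") as fh:
            meta = json.load(fh)
        columns = [(c, int(r)) for c, r in meta["columns"]]
        source = meta.get("source")
    except FileNotFoundError:
        columns = [("A", i + 1) for i in range(letters.shape[1])]
        source = path
    return SAAlignment(
        letters=letters, columns=columns, times=np.asarray(times, float), source=source
    )
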