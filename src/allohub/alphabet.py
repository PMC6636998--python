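"""Structural-alphabet coarse-graining of Cα chains.

A chain of N residues is described by its N−3 overlapping 4-Cα fragments
(stride 1).  Each fragment is assigned the letter of the prototype fragment
with minimal Kabsch RMSD, making the encoding invariant to rigid-body
motion of the frame.  The prototype library is pluggable; the package
bundles a 25-letter synthetic library (see ``data/sa25_synthetic.json``)
built by :func:`allohub.synthetic.make_synthetic_library` as a stand-in
for published Cα fragment alphabets such as M32K25, whose prototype
coordinates are defined in the prior literature.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .traj_io import FormatError, Trajectory, select_calpha

__all__ = [
    "FragmentLibrary",
    "SAAlignment",
    "kabsch_superpose",
    "kabsch_rmsd",
    "encode_chain",
    "encode_trajectory",
    "load_library",
    "default_library",
    "build_library_from_fragments",
]

FRAGMENT_LENGTH = 4


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def _check_fragment(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (FRAGMENT_LENGTH, 3):
        raise ValueError(f"{name} must be a 4x3 coordinate array, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return x


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[float, np.ndarray]:
    """Optimal rigid superposition of one 4-point fragment onto another.

    Returns ``(rmsd, rotation)`` where ``rotation`` is the proper rotation
    (det = +1) that maps the centred mobile fragment onto the centred
    reference, and ``rmsd`` is the minimum RMSD over all rigid
    transformations (nm).
    """
    mob = _check_fragment(mobile, "mobile")
    ref = _check_fragment(reference, "reference")
    refc = ref - ref.mean(axis=0)
    if np.allclose(refc, 0.0):
        raise ValueError("degenerate reference fragment: all points identical")
    mobc = mob - mob.mean(axis=0)

    h = mobc.T @ refc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    ssd = float(np.sum(mobc**2) + np.sum(refc**2) - 2.0 * (s[0] + s[1] + d * s[2]))
    rmsd = float(np.sqrt(max(ssd, 0.0) / FRAGMENT_LENGTH))
    return rmsd, rot


def kabsch_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD of ``mobile`` onto ``reference`` (rotation discarded)."""
    return kabsch_superpose(mobile, reference)[0]


def _rmsd_to_prototypes(frag: np.ndarray, protos_c: np.ndarray, protos_ss: np.ndarray) -> np.ndarray:
    """RMSD of one centred fragment against a stack of centred prototypes.

    ``protos_c``: (L, 4, 3) centred prototypes; ``protos_ss``: (L,) their
    squared norms.  Vectorised over letters for speed.
    """
    fragc = frag - frag.mean(axis=0)
    ss_frag = np.sum(fragc**2)
    h = np.einsum("ki,lkj->lij", fragc, protos_c)  # (L, 3, 3)
    u, s, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("lij,ljk->lik", vt.transpose(0, 2, 1), u.transpose(0, 2, 1)))
    traces = s[:, 0] + s[:, 1] + np.sign(det) * s[:, 2]
    ssd = ss_frag + protos_ss - 2.0 * traces
    return np.sqrt(np.maximum(ssd, 0.0) / FRAGMENT_LENGTH)


# ---------------------------------------------------------------------------
# Fragment library
# ---------------------------------------------------------------------------

@dataclass
class FragmentLibrary:
    """An ordered set of prototype 4-Cα fragment geometries."""

    letters: list[str]
    prototypes: np.ndarray  # (n_letters, 4, 3) nm
    name: str = "unnamed"

    def __post_init__(self) -> None:
        self.prototypes = np.asarray(self.prototypes, dtype=float)
        if len(self.letters) < 2:
            raise FormatError("a fragment library needs at least 2 letters")
        if len(set(self.letters)) != len(self.letters):
            raise FormatError("duplicate letters in fragment library")
        if self.prototypes.shape != (len(self.letters), FRAGMENT_LENGTH, 3):
            raise FormatError(
                f"prototypes must have shape ({len(self.letters)}, 4, 3), "
                f"got {self.prototypes.shape}"
            )
        # cached centred prototypes for fast encoding
        self._centred = self.prototypes - self.prototypes.mean(axis=1, keepdims=True)
        self._sumsq = np.sum(self._centred**2, axis=(1, 2))

    @property
    def n_letters(self) -> int:
        return len(self.letters)

    def assign(self, fragment: np.ndarray) -> tuple[str, float]:
        """Letter and RMSD of the best-matching prototype (ties -> lowest index)."""
        rmsds = _rmsd_to_prototypes(np.asarray(fragment, float), self._centred, self._sumsq)
        best = int(np.argmin(rmsds))  # argmin takes the first minimum: tie-break
        return self.letters[best], float(rmsds[best])

    def index(self, letter: str) -> int:
        return self.letters.index(letter)


def load_library(path: str) -> FragmentLibrary:
    """Load a fragment library from JSON or CSV.

    JSON layout: ``{"name": ..., "letters": [...], "prototypes": {letter:
    [[x,y,z] x4]}}``.  CSV layout: one row per letter with columns
    ``letter, x1, y1, z1, ..., x4, y4, z4``.
    """
    if str(path).endswith(".json"):
        with open(path) as fh:
            data = json.load(fh)
        letters = list(data["letters"])
        protos = []
        for letter in letters:
            pts = np.asarray(data["prototypes"][letter], dtype=float)
            if pts.shape != (FRAGMENT_LENGTH, 3):
                raise FormatError(
                    f"prototype for letter {letter!r} has shape {pts.shape}, "
                    "expected (4, 3)"
                )
            protos.append(pts)
        return FragmentLibrary(
            letters=letters, prototypes=np.array(protos), name=data.get("name", str(path))
        )
    df = pd.read_csv(path)
    if df.shape[1] != 1 + FRAGMENT_LENGTH * 3:
        raise FormatError(
            f"{path}: expected 13 columns (letter + 12 coordinates), got {df.shape[1]}"
        )
    letters = [str(x) for x in df.iloc[:, 0]]
    protos = df.iloc[:, 1:].to_numpy(dtype=float).reshape(-1, FRAGMENT_LENGTH, 3)
    return FragmentLibrary(letters=letters, prototypes=protos, name=str(path))


def default_library() -> FragmentLibrary:
    """The bundled 25-letter synthetic fragment alphabet."""
    ref = resources.files("allohub.data").joinpath("sa25_synthetic.json")
    with resources.as_file(ref) as path:
        return load_library(str(path))


def build_library_from_fragments(
    fragments: np.ndarray, k: int, seed: int = 0, max_iter: int = 50
) -> FragmentLibrary:
    """Build a k-letter library by k-medoid clustering of fragments.

    The dissimilarity is pairwise Kabsch RMSD.  Initialisation is greedy
    max–min (farthest-point) seeding from the medoid of the whole set, so
    the result is deterministic for a given input order; ``seed`` only
    enters if ``k`` exceeds the number of distinct geometries.
    """
    fragments = np.asarray(fragments, dtype=float)
    m = fragments.shape[0]
    if fragments.ndim != 3 or fragments.shape[1:] != (FRAGMENT_LENGTH, 3):
        raise ValueError("fragments must have shape (m, 4, 3)")
    if not 2 <= k <= m:
        raise ValueError(f"k must be in [2, {m}]")

    centred = fragments - fragments.mean(axis=1, keepdims=True)
    sumsq = np.sum(centred**2, axis=(1, 2))
    dist = np.zeros((m, m))
    for i in range(m):
        dist[i] = _rmsd_to_prototypes(fragments[i], centred, sumsq)
    dist = 0.5 * (dist + dist.T)  # symmetrise round-off

    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        d_to_near = dist[:, medoids].min(axis=1)
        medoids.append(int(np.argmax(d_to_near)))

    for _ in range(max_iter):
        assign = np.argmin(dist[:, medoids], axis=1)
        new_medoids = []
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if members.size == 0:
                new_medoids.append(medoids[c])
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids.append(int(members[np.argmin(within)]))
        if new_medoids == medoids:
            break
        medoids = new_medoids

    letters = list(string.ascii_uppercase[:k]) if k <= 26 else [
        f"L{i}" for i in range(k)
    ]
    return FragmentLibrary(
        letters=letters, prototypes=fragments[medoids], name=f"kmedoid{k}"
    )


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

@dataclass
class SAAlignment:
    """Stacked alignment of structural-alphabet strings.

    One row per frame; one column per 4-residue fragment position
    (``columns[p] = (chain_id, first_res_id)``, fragment covering residues
    first..first+3).
    """

    letters: np.ndarray  # (n_frames, n_columns), dtype U1
    columns: list[tuple[str, int]]
    times: np.ndarray | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        self.letters = np.asarray(self.letters, dtype="U1")
        if self.letters.ndim != 2:
            raise ValueError("letters must be a frames x columns matrix")
        if len(self.columns) != self.letters.shape[1]:
            raise ValueError("one column descriptor per alignment column required")
        if self.times is None:
            self.times = np.arange(self.letters.shape[0], dtype=float)

    @property
    def n_frames(self) -> int:
        return self.letters.shape[0]

    @property
    def n_columns(self) -> int:
        return self.letters.shape[1]

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for c, _ in self.columns:
            if c not in seen:
                seen.append(c)
        return seen

    def chain_column_indices(self, chain_id: str) -> np.ndarray:
        """Alignment column indices belonging to one chain."""
        idx = [i for i, (c, _) in enumerate(self.columns) if c == chain_id]
        if not idx:
            raise KeyError(f"no columns for chain {chain_id!r}")
        return np.asarray(idx, dtype=int)

    def column_labels(self) -> list[str]:
        return [f"{c}:{r}" for c, r in self.columns]

    def to_strings(self) -> list[str]:
        return ["".join(row) for row in self.letters]


def encode_chain(chain_coords: np.ndarray, library: FragmentLibrary) -> str:
    """Encode one frame of one chain (N x 3 Cα coordinates) into N−3 letters."""
    coords = np.asarray(chain_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("chain coordinates must be an N x 3 array")
    n = coords.shape[0]
    if n < FRAGMENT_LENGTH:
        raise ValueError(f"chain of {n} residues cannot host a 4-residue fragment")
    out = []
    for i in range(n - FRAGMENT_LENGTH + 1):
        frag = coords[i : i + FRAGMENT_LENGTH]
        if not np.all(np.isfinite(frag)):
            raise ValueError(f"non-finite coordinates at fragment position {i}")
        letter, _ = library.assign(frag)
        out.append(letter)
    return "".join(out)


def encode_trajectory(traj: Trajectory, library: FragmentLibrary) -> SAAlignment:
    """Encode every frame of every encodable chain into a stacked alignment.

    Columns concatenate the per-chain encodings in chain order; the column
    map records (chain id, first residue) so per-chain sub-alignments can
    be recovered.
    """
    chains = select_calpha(traj)
    if not chains:
        raise ValueError("no chain with >= 4 residues to encode")
    columns: list[tuple[str, int]] = []
    for ch in chains:
        for j in range(len(ch) - FRAGMENT_LENGTH + 1):
            columns.append((ch.chain_id, int(ch.res_ids[j])))

    n_frames = traj.n_frames
    letters = np.empty((n_frames, len(columns)), dtype="U1")
    for f in range(n_frames):
        col = 0
        for ch in chains:
            coords = traj.coords[f, ch.atom_indices]
            try:
                s = encode_chain(coords, library)
            except ValueError as exc:
                raise ValueError(
                    f"frame {f}, chain {ch.chain_id!r}: {exc}"
                ) from exc
            letters[f, col : col + len(s)] = list(s)
            col += len(s)
    return SAAlignment(
        letters=letters, columns=columns, times=traj.times.copy(), source=None
    )
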