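"""Finite-size-corrected normalized mutual information between fragment columns.

For two alignment columns C_i, C_j observed over N frames the coupling is

    nMI(C_i; C_j) = clamp_[0,1]( (I(C_i;C_j) - eps(C_i,C_j)) / H(C_i,C_j) )

with the plug-in mutual information I and joint entropy H (natural log,
nats) and the finite-size error

    eps = (B*_ij - B*_i - B*_j + 1) / (2N)

where B* counts joint/marginal states with non-zero probability.  Columns
with zero joint entropy (both constant) have nMI = 0 by convention.

Pairs of sequence-overlapping fragments (|first_res_i - first_res_j| <= 3
within one chain) share residues and are trivially correlated; they are
masked out of the matrix by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import SAAlignment

__all__ = [
    "ColumnPairStats",
    "MIMatrix",
    "column_mi",
    "block_mi_matrix",
    "positional_entropy",
    "fragment_total_mi",
]

OVERLAP_SPAN = 3  # fragments closer than this share residues


@dataclass
class ColumnPairStats:
    """Information-theoretic statistics for one column pair."""

    I: float  # mutual information (nats)
    H: float  # joint entropy (nats)
    eps: float  # finite-size error (nats)
    raw_nmi: float  # (I - eps)/H before clamping
    nmi: float  # clamped to [0, 1]
    N: int
    Bij: int
    Bi: int
    Bj: int


def _codes(column: np.ndarray) -> np.ndarray:
    _, inv = np.unique(np.asarray(column), return_inverse=True)
    return inv


def _pair_stats_from_codes(ci: np.ndarray, cj: np.ndarray) -> ColumnPairStats:
    n = ci.shape[0]
    ki = int(ci.max()) + 1
    kj = int(cj.max()) + 1
    joint = np.bincount(ci * kj + cj, minlength=ki * kj).astype(float)
    joint = joint.reshape(ki, kj)
    pij = joint / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)

    nz = pij > 0
    pij_nz = pij[nz]
    h = float(-np.sum(pij_nz * np.log(pij_nz)))
    outer = np.outer(pi, pj)[nz]
    i_val = float(np.sum(pij_nz * np.log(pij_nz / outer)))

    bij = int(np.count_nonzero(nz))
    bi = int(np.count_nonzero(pi))
    bj = int(np.count_nonzero(pj))
    eps = (bij - bi - bj + 1) / (2.0 * n)

    if h > 0.0:
        raw = (i_val - eps) / h
    else:
        raw = 0.0
    nmi = float(min(max(raw, 0.0), 1.0))
    return ColumnPairStats(
        I=i_val, H=h, eps=eps, raw_nmi=float(raw), nmi=nmi, N=n, Bij=bij, Bi=bi, Bj=bj
    )


def column_mi(ci: np.ndarray, cj: np.ndarray) -> ColumnPairStats:
    """Corrected normalized mutual information between two letter columns."""
    ci = np.asarray(ci)
    cj = np.asarray(cj)
    if ci.shape != cj.shape or ci.ndim != 1:
        raise ValueError(
            f"columns must be 1-D and of equal length, got {ci.shape} vs {cj.shape}"
        )
    if ci.shape[0] < 2:
        raise ValueError("need at least 2 observations per column")
    return _pair_stats_from_codes(_codes(ci), _codes(cj))


@dataclass
class MIMatrix:
    """Symmetric fragment-pair matrix of corrected normalized MI.

    ``mask`` is True for pairs that enter the analysis; overlapping-fragment
    pairs and the diagonal are False and carry the value 0.
    """

    values: np.ndarray
    labels: list[str]  # "chain:first_res" per fragment column
    columns: list[tuple[str, int]]
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = self.values.shape[0]
        if self.values.shape != (p, p):
            raise ValueError("values must be square")
        if len(self.labels) != p:
            raise ValueError("one label per fragment required")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("MI matrix must be symmetric")

    @property
    def n_fragments(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path)


def overlap_mask(columns: list[tuple[str, int]]) -> np.ndarray:
    """Analysis mask: True for non-overlapping, off-diagonal fragment pairs."""
    p = len(columns)
    mask = np.ones((p, p), dtype=bool)
    np.fill_diagonal(mask, False)
    for a in range(p):
        ca, ra = columns[a]
        for b in range(a + 1, p):
            cb, rb = columns[b]
            if ca == cb and abs(ra - rb) <= OVERLAP_SPAN:
                mask[a, b] = mask[b, a] = False
    return mask


def block_mi_matrix(
    alignment: SAAlignment,
    frame_range: range | tuple[int, int] | None = None,
    chain_id: str | None = None,
    mask_overlapping: bool = True,
    provenance: dict | None = None,
) -> MIMatrix:
    """All-pairs corrected nMI over a chain's columns within a frame range.

    ``frame_range`` may be a ``range`` or a half-open ``(start, stop)``
    tuple; ``None`` means all frames.  ``chain_id=None`` uses all columns
    (inter-chain couplings included).
    """
    if frame_range is None:
        rows = np.arange(alignment.n_frames)
    elif isinstance(frame_range, range):
        rows = np.asarray(frame_range, dtype=int)
    else:
        rows = np.arange(int(frame_range[0]), int(frame_range[1]))
    if rows.size == 0:
        raise ValueError("empty frame range")
    if rows.min() < 0 or rows.max() >= alignment.n_frames:
        raise ValueError("frame range outside alignment")

    if chain_id is None:
        col_idx = np.arange(alignment.n_columns)
    else:
        col_idx = alignment.chain_column_indices(chain_id)
    columns = [alignment.columns[i] for i in col_idx]
    labels = [f"{c}:{r}" for c, r in columns]

    sub = alignment.letters[np.ix_(rows, col_idx)]
    codes = [np.unique(sub[:, p], return_inverse=True)[1] for p in range(sub.shape[1])]

    p = len(col_idx)
    mask = overlap_mask(columns) if mask_overlapping else ~np.eye(p, dtype=bool)
    values = np.zeros((p, p))
    for a in range(p):
        for b in range(a + 1, p):
            if not mask[a, b]:
                continue
            stats = _pair_stats_from_codes(codes[a], codes[b])
            values[a, b] = values[b, a] = stats.nmi

    prov = dict(provenance or {})
    prov.setdefault("frame_start", int(rows[0]))
    prov.setdefault("frame_stop", int(rows[-1]) + 1)
    if chain_id is not None:
        prov.setdefault("chain_id", chain_id)
    return MIMatrix(
        values=values, labels=labels, columns=columns, mask=mask, provenance=prov
    )


def positional_entropy(
    alignment: SAAlignment, frame_range: range | tuple[int, int] | None = None
) -> np.ndarray:
    """Per-column Shannon entropy (nats) of the letter frequencies."""
    if frame_range is None:
        rows = np.arange(alignment.n_frames)
    elif isinstance(frame_range, range):
        rows = np.asarray(frame_range, dtype=int)
    else:
        rows = np.arange(int(frame_range[0]), int(frame_range[1]))
    if rows.size == 0:
        raise ValueError("empty frame range")
    sub = alignment.letters[rows]
    out = np.zeros(sub.shape[1])
    for p in range(sub.shape[1]):
        _, counts = np.unique(sub[:, p], return_counts=True)
        freq = counts / counts.sum()
        out[p] = -np.sum(freq * np.log(freq))
    return out


def fragment_total_mi(matrix: MIMatrix, fragment: int | str) -> float:
    """Total coupling of one fragment: sum of its unmasked nMI entries."""
    if isinstance(fragment, str):
        try:
            idx = matrix.labels.index(fragment)
        except ValueError:
            raise KeyError(f"unknown fragment {fragment!r}") from None
    else:
        idx = int(fragment)
        if not 0 <= idx < matrix.n_fragments:
            raise KeyError(f"fragment index {idx} out of range")
    return float(matrix.values[idx, matrix.mask[idx]].sum())
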