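"""Conformational substate extraction from block MI matrices.

The similarity between two symmetric coupling matrices A and B is the
covariance overlap

    d(A,B) = sqrt( tr A + tr B - 2 tr(A^1/2 B^1/2) )
    Omega(A,B) = 1 - d(A,B) / sqrt(tr A + tr B)

computed via eigendecomposition.  Omega is 1 for identical matrices and 0
for orthogonal ones.  MI matrices are symmetric but not guaranteed
positive semidefinite; negative eigenvalues are clipped to zero before the
square roots and the clipped magnitude is recorded (a warning is raised
when it exceeds 1% of the trace).

A trajectory is segmented into substates by greedy left-to-right run
building over its time-ordered block matrices: a block joins the current
run iff its overlap with the running mean matrix stays above a threshold.
Substates across replicas/states are then compared by complete-linkage
hierarchical clustering with distance 1 - Omega.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .alphabet import SAAlignment
from .mi import MIMatrix

__all__ = [
    "OverlapResult",
    "Substate",
    "SubstateSet",
    "split_blocks",
    "covariance_overlap",
    "segment_substates",
    "cluster_substates",
]


def split_blocks(alignment: SAAlignment | int, n_blocks: int) -> list[range]:
    """Split frames into contiguous, length-balanced, non-overlapping blocks.

    A remainder of r frames is distributed one frame to each of the first
    r blocks.  Accepts an alignment or a plain frame count.
    """
    n_frames = alignment if isinstance(alignment, int) else alignment.n_frames
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if n_blocks > n_frames:
        raise ValueError(f"cannot split {n_frames} frames into {n_blocks} blocks")
    base, rem = divmod(n_frames, n_blocks)
    ranges: list[range] = []
    start = 0
    for b in range(n_blocks):
        size = base + (1 if b < rem else 0)
        ranges.append(range(start, start + size))
        start += size
    return ranges


@dataclass
class OverlapResult:
    """Covariance overlap between two symmetric matrices."""

    omega: float
    d: float
    eigvals_a: np.ndarray
    eigvals_b: np.ndarray
    eigvecs_a: np.ndarray
    eigvecs_b: np.ndarray
    psd_adjustment: float  # total magnitude of clipped negative eigenvalues


def _as_array(m: MIMatrix | np.ndarray) -> np.ndarray:
    if isinstance(m, MIMatrix):
        return m.values
    return np.asarray(m, dtype=float)


def covariance_overlap(
    a: MIMatrix | np.ndarray,
    b: MIMatrix | np.ndarray,
    warn_clip_frac: float | None = 0.01,
) -> OverlapResult:
    """Covariance overlap Omega(A, B) in [0, 1] via eigendecomposition."""
    am = _as_array(a)
    bm = _as_array(b)
    if am.shape != bm.shape or am.ndim != 2 or am.shape[0] != am.shape[1]:
        raise ValueError(f"matrices must be square and same shape: {am.shape} vs {bm.shape}")
    if not (np.allclose(am, am.T) and np.allclose(bm, bm.T)):
        raise ValueError("matrices must be symmetric")

    identical = np.array_equal(am, bm)
    la, va = np.linalg.eigh(am)
    lb, vb = np.linalg.eigh(bm)
    clip = float(-la[la < 0].sum() - lb[lb < 0].sum())
    la = np.clip(la, 0.0, None)
    lb = np.clip(lb, 0.0, None)
    tra = float(la.sum())
    trb = float(lb.sum())
    if warn_clip_frac is not None and clip > warn_clip_frac * max(
        tra + trb, np.finfo(float).tiny
    ):
        warnings.warn(
            f"clipped negative eigenvalue mass {clip:.3g} exceeds "
            f"{warn_clip_frac:.0%} of the total trace {tra + trb:.3g}",
            stacklevel=2,
        )

    if identical or tra + trb == 0.0:
        # equal matrices (or two null matrices) overlap perfectly; the
        # short-circuit avoids sqrt-amplified round-off in d
        return OverlapResult(1.0, 0.0, la, lb, va, vb, clip)

    # tr(A^1/2 B^1/2) = sum_ij sqrt(la_i) sqrt(lb_j) (v_i . w_j)^2
    m = va.T @ vb
    cross = float(np.sqrt(la) @ (m**2) @ np.sqrt(lb))
    d2 = tra + trb - 2.0 * cross
    d = float(np.sqrt(max(d2, 0.0)))
    omega = float(min(max(1.0 - d / np.sqrt(tra + trb), 0.0), 1.0))
    if d == 0.0:
        omega = 1.0
    return OverlapResult(omega, d, la, lb, va, vb, clip)


@dataclass
class Substate:
    """A contiguous run of trajectory blocks with similar coupling matrices."""

    member_blocks: list[int]
    representative: np.ndarray  # mean of member matrices
    probability: float


@dataclass
class SubstateSet:
    """Substate decomposition of one trajectory's block sequence."""

    substates: list[Substate]
    omega_threshold: float
    min_run: int
    labels: list[str] | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_substates(self) -> int:
        return len(self.substates)

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([s.probability for s in self.substates])

    def boundaries(self) -> list[int]:
        """First block index of each substate after the first."""
        return [s.member_blocks[0] for s in self.substates[1:]]


def _runs_to_substates(runs: list[list[int]], matrices: list[np.ndarray]) -> list[Substate]:
    total = sum(len(r) for r in runs)
    out = []
    for r in runs:
        rep = np.mean([matrices[i] for i in r], axis=0)
        out.append(Substate(member_blocks=list(r), representative=rep, probability=len(r) / total))
    return out


def segment_substates(
    matrices: list[MIMatrix | np.ndarray],
    omega_threshold: float = 0.85,
    min_run: int = 2,
    labels: list[str] | None = None,
    provenance: dict | None = None,
) -> SubstateSet:
    """Segment a time-ordered block-matrix sequence into substates.

    Block t+1 joins the current run iff Omega(mean of run, M_{t+1}) >=
    ``omega_threshold``.  Runs shorter than ``min_run`` are merged into the
    neighbouring run with the higher overlap (left neighbour on ties).
    """
    if not matrices:
        raise ValueError("need at least one block matrix")
    if not 0.0 < omega_threshold <= 1.0:
        raise ValueError("omega_threshold must be in (0, 1]")
    arrays = [_as_array(m) for m in matrices]

    runs: list[list[int]] = [[0]]
    rep = arrays[0].copy()
    for t in range(1, len(arrays)):
        if covariance_overlap(rep, arrays[t], warn_clip_frac=None).omega >= omega_threshold:
            runs[-1].append(t)
        else:
            runs.append([t])
        rep = np.mean([arrays[i] for i in runs[-1]], axis=0)

    # merge short runs into the more-similar contiguous neighbour
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for idx, run in enumerate(runs):
            if len(run) >= min_run:
                continue
            rep_run = np.mean([arrays[i] for i in run], axis=0)
            omega_left = omega_right = -1.0
            if idx > 0:
                rep_left = np.mean([arrays[i] for i in runs[idx - 1]], axis=0)
                omega_left = covariance_overlap(rep_run, rep_left, warn_clip_frac=None).omega
            if idx < len(runs) - 1:
                rep_right = np.mean([arrays[i] for i in runs[idx + 1]], axis=0)
                omega_right = covariance_overlap(rep_run, rep_right, warn_clip_frac=None).omega
            if omega_left >= omega_right:
                runs[idx - 1] = runs[idx - 1] + run
            else:
                runs[idx + 1] = run + runs[idx + 1]
            del runs[idx]
            changed = True
            break

    first = matrices[0]
    if labels is None and isinstance(first, MIMatrix):
        labels = first.labels
    return SubstateSet(
        substates=_runs_to_substates(runs, arrays),
        omega_threshold=omega_threshold,
        min_run=min_run,
        labels=labels,
        provenance=dict(provenance or {}),
    )


def cluster_substates(
    matrices: list[MIMatrix | np.ndarray],
    cut_height: float | None = None,
    n_clusters: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Complete-linkage clustering of substate matrices with distance 1 - Omega.

    Returns ``(linkage_matrix, flat_labels, leaf_order)``.  Flat labels are
    cut at ``cut_height`` (distance criterion) or into ``n_clusters``
    groups; with neither given, every matrix keeps its own label.
    """
    arrays = [_as_array(m) for m in matrices]
    n = len(arrays)
    if n < 2:
        raise ValueError("need at least two matrices to cluster")
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = 1.0 - covariance_overlap(arrays[i], arrays[j], warn_clip_frac=None).omega
    z = linkage(squareform(dist, checks=False), method="complete")
    if cut_height is not None:
        flat = fcluster(z, t=cut_height, criterion="distance")
    elif n_clusters is not None:
        flat = fcluster(z, t=n_clusters, criterion="maxclust")
    else:
        flat = np.arange(1, n + 1)
    return z, flat, leaves_list(z)
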