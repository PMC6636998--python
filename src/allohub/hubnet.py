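"""Ensemble difference networks and allosteric hub-fragment calling.

Per liganded state the substate coupling matrices from all replicas are
combined into a probability-weighted ensemble-average network.  Between
two states (conventionally "apo" and "holo") a difference network of
per-pair log2 fold-changes is computed, pair-wise significance is assessed
with a two-sided Wilcoxon rank-sum test over the per-substate samples, and
multiplicity is controlled by Benjamini–Hochberg FDR.  Hub fragments are
the fragments incident to at least one significant pair, ranked by their
largest absolute log2 fold-change.

The module also houses two small companions: MSA-guided substitution
suggestion for hub residues, and the allosteric coupling coefficient
Q = K_ia / K_ia/x (Q > 1: the effector increases substrate affinity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .substates import SubstateSet

__all__ = [
    "EnsembleNetwork",
    "HubTable",
    "ensemble_average",
    "difference_network",
    "call_hubs",
    "suggest_substitutions",
    "coupling_Q",
]


@dataclass
class EnsembleNetwork:
    """Probability-weighted average coupling network for one liganded state."""

    state: str
    matrix: np.ndarray
    weights: np.ndarray  # per contributing substate, sums to 1
    stack: list[np.ndarray]  # individual substate matrices, for statistics
    labels: list[str]
    mask: np.ndarray

    @property
    def n_fragments(self) -> int:
        return self.matrix.shape[0]


def ensemble_average(
    substate_sets: list[SubstateSet], state: str = "", mask: np.ndarray | None = None
) -> EnsembleNetwork:
    """Average substate matrices across replicas, weighted by occupancy.

    Each replica contributes total weight 1/n_replicas, split over its
    substates by their occupancy probabilities.
    """
    if not substate_sets:
        raise ValueError("need at least one substate set")
    n_rep = len(substate_sets)
    stack: list[np.ndarray] = []
    weights: list[float] = []
    labels: list[str] | None = None
    for ss in substate_sets:
        if ss.labels is not None:
            if labels is None:
                labels = list(ss.labels)
            elif list(ss.labels) != labels:
                raise ValueError("substate sets disagree on fragment labels")
        for sub in ss.substates:
            stack.append(np.asarray(sub.representative, dtype=float))
            weights.append(sub.probability / n_rep)
    dims = {m.shape for m in stack}
    if len(dims) != 1:
        raise ValueError(f"substate matrices have mismatched dimensions: {dims}")
    w = np.asarray(weights)
    w = w / w.sum()
    matrix = np.tensordot(w, np.stack(stack), axes=1)
    p = matrix.shape[0]
    if labels is None:
        labels = [str(i) for i in range(p)]
    if mask is None:
        mask = ~np.eye(p, dtype=bool)
    return EnsembleNetwork(
        state=state, matrix=matrix, weights=w, stack=stack, labels=labels, mask=mask
    )


def difference_network(
    apo: EnsembleNetwork, holo: EnsembleNetwork, pseudocount: float = 1e-3
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-pair log2 fold-change table holo vs apo, plus the signed difference matrix.

    log2fc(i,j) = log2((nMI_holo + c) / (nMI_apo + c)); positive values are
    couplings predicted to strengthen in the holo state.
    """
    if apo.labels != holo.labels:
        raise ValueError("ensemble networks are on different fragment spaces")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    mask = apo.mask & holo.mask
    iu, ju = np.where(np.triu(mask))
    a = apo.matrix[iu, ju]
    h = holo.matrix[iu, ju]
    with np.errstate(divide="ignore"):
        log2fc = np.log2(h + pseudocount) - np.log2(a + pseudocount)
    table = pd.DataFrame(
        {
            "frag_i": [apo.labels[i] for i in iu],
            "frag_j": [apo.labels[j] for j in ju],
            "i": iu,
            "j": ju,
            "nmi_apo": a,
            "nmi_holo": h,
            "log2fc": log2fc,
        }
    )
    diff = holo.matrix - apo.matrix
    return table, diff


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value; exact when tie-free."""
    if np.ptp(np.concatenate([x, y])) == 0.0:
        return 1.0  # all observations identical: no evidence of a shift
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "asymptotic" if ties else "exact"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


@dataclass
class HubTable:
    """Significant fragment pairs and the hub ranking derived from them."""

    pairs: pd.DataFrame  # per pair: nmi_apo, nmi_holo, log2fc, p, q, significant
    hubs: pd.DataFrame  # per hub fragment: score, rank
    lfc_min: float
    q_max: float | None
    p_max: float | None

    def top(self, k: int) -> pd.DataFrame:
        return self.hubs.head(k)


def call_hubs(
    diff_table: pd.DataFrame,
    apo: EnsembleNetwork,
    holo: EnsembleNetwork,
    lfc_min: float = 2.0,
    q_max: float | None = 5e-4,
    p_max: float | None = None,
) -> HubTable:
    """Identify allosteric hub fragments between two liganded states.

    Per pair a two-sided Wilcoxon rank-sum test compares the per-substate
    nMI samples of the two states; Benjamini–Hochberg FDR is applied
    across all tested pairs.  A pair is significant when |log2fc| >=
    ``lfc_min`` and q <= ``q_max`` (or, when ``p_max`` is given instead,
    raw p <= ``p_max``).  Hubs are fragments incident to >= 1 significant
    pair, ranked by their largest |log2fc| among significant pairs
    (ties broken toward the lower fragment index).
    """
    if len(apo.stack) < 2 or len(holo.stack) < 2:
        raise ValueError(
            "need >= 2 substate samples per state for the rank-sum test; "
            "provide more replicas or a finer substate segmentation"
        )
    if q_max is None and p_max is None:
        raise ValueError("one of q_max or p_max must be set")

    apo_stack = np.stack(apo.stack)
    holo_stack = np.stack(holo.stack)
    pvals = np.empty(len(diff_table))
    for row_idx, (i, j) in enumerate(zip(diff_table["i"], diff_table["j"])):
        pvals[row_idx] = _ranksum_p(apo_stack[:, i, j], holo_stack[:, i, j])
    qvals = multipletests(pvals, method="fdr_bh")[1]

    pairs = diff_table.copy()
    pairs["p"] = pvals
    pairs["q"] = qvals
    sig = np.abs(pairs["log2fc"]) >= lfc_min
    if p_max is not None:
        sig &= pairs["p"] <= p_max
    else:
        sig &= pairs["q"] <= q_max
    pairs["significant"] = sig

    scores: dict[int, float] = {}
    for _, row in pairs[pairs["significant"]].iterrows():
        for frag in (int(row["i"]), int(row["j"])):
            scores[frag] = max(scores.get(frag, 0.0), abs(float(row["log2fc"])))
    hub_rows = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    hubs = pd.DataFrame(
        {
            "fragment": [apo.labels[i] for i, _ in hub_rows],
            "index": [i for i, _ in hub_rows],
            "score": [s for _, s in hub_rows],
            "rank": np.arange(1, len(hub_rows) + 1),
        }
    )
    return HubTable(pairs=pairs, hubs=hubs, lfc_min=lfc_min, q_max=q_max, p_max=p_max)


# ---------------------------------------------------------------------------
# MSA-guided substitution suggestion
# ---------------------------------------------------------------------------

def suggest_substitutions(
    msa,
    target_id: str,
    positions: list[int],
    min_freq: float = 0.05,
) -> dict[int, dict[str, float]]:
    """Residues tolerated at hub positions, from their frequency in an MSA.

    ``msa`` is a path to a FASTA alignment or a Biopython
    ``MultipleSeqAlignment``; ``positions`` are 1-based positions in the
    *ungapped* target sequence.  Per position, returns residues (excluding
    the wild type and gaps) whose column frequency is >= ``min_freq``.
    """
    from Bio import AlignIO

    if isinstance(msa, str):
        msa = AlignIO.read(msa, "fasta")
    target_row = None
    for rec in msa:
        if rec.id == target_id:
            target_row = str(rec.seq)
            break
    if target_row is None:
        raise KeyError(f"sequence {target_id!r} not found in alignment")

    # map ungapped target position (1-based) -> alignment column
    col_of_pos: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(target_row):
        if ch != "-":
            pos += 1
            col_of_pos[pos] = col

    n_seq = len(msa)
    out: dict[int, dict[str, float]] = {}
    for p in positions:
        if p not in col_of_pos:
            raise ValueError(
                f"position {p} outside the ungapped target (length {pos})"
            )
        col = col_of_pos[p]
        wild = target_row[col].upper()
        column = [str(rec.seq[col]).upper() for rec in msa]
        non_gap = [c for c in column if c != "-"]
        if not non_gap:
            warnings.warn(f"position {p} maps to an all-gap column", stacklevel=2)
            out[p] = {}
            continue
        tolerated: dict[str, float] = {}
        for aa in sorted(set(column)):
            if aa in ("-", wild):
                continue
            freq = column.count(aa) / n_seq
            if freq >= min_freq:
                tolerated[aa] = freq
        out[p] = tolerated
    return out


def coupling_Q(k_ia: float, k_ia_x: float) -> dict[str, float]:
    """Allosteric coupling coefficient Q = K_ia / K_ia/x.

    ``k_ia``: substrate dissociation/affinity constant without the
    effector; ``k_ia_x``: the same constant in the effector's presence
    (identical units).  Q > 1 (log10 Q > 0) indicates positive coupling
    (activation); Q < 1 indicates negative coupling (inhibition).
    """
    if k_ia <= 0 or k_ia_x <= 0:
        raise ValueError("affinity constants must be positive")
    q = k_ia / k_ia_x
    return {"Q": float(q), "log10Q": float(np.log10(q))}
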