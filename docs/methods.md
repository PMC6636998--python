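# Methods notes

This note records the statistical model behind the package, the defaults
and their rationale, what the synthetic generators do and do not emulate,
and the numerical choices a maintainer would want to know about.

## Model and assumptions

The central object is the *stacked structural-alphabet alignment*: each
trajectory frame is reduced, per chain, to a string over a finite set of
prototype 4-Cα fragment geometries (letters). The method assumes that

- allosterically relevant backbone dynamics are visible as *correlated
  letter switching* between fragment columns, even when the overall fold
  does not change;
- a trajectory visits a small number of *conformational substates*, within
  which the coupling pattern is stationary, so a block-wise analysis with
  substate segmentation is more faithful than one global average;
- replicate simulations and (for oligomers) protomer chains are
  exchangeable samples of the same underlying network, so per-substate
  matrices can be pooled for rank-based testing.

Fragment-pair coupling is the corrected normalized mutual information
(natural log throughout, so entropies and MI are in nats; only the ratio
(I − ε)/H enters downstream, so the log base cancels):

    nMI = clamp_[0,1]( (I − ε) / H ),   ε = (B*_ij − B*_i − B*_j + 1) / 2N.

ε is the leading-order plug-in bias of I for a finite sample of N frames;
it can be negative, and the corrected ratio can leave [0, 1] (e.g. it is
(ln 2 + 0.0025)/ln 2 ≈ 1.0036 for identical two-letter columns at
N = 200), hence the clamp — nMI is used as a similarity weight and must
stay a bounded similarity. Columns with zero joint entropy carry nMI = 0
by convention.

Pairs of fragments that overlap in sequence (|first residue difference|
≤ 3 within a chain) share up to three residues and are trivially
correlated; they are masked from every analysis by default
(`mask_overlapping=False` restores them). Whether to mask such pairs is a
genuine design choice; masking avoids self-correlation dominating the
hub ranking.

## Covariance overlap and substates

Matrix similarity uses the covariance overlap

    d(A,B)² = tr A + tr B − 2 tr(A^½ B^½),   Ω = 1 − d/√(tr A + tr B),

evaluated through eigendecompositions: tr(A^½B^½) = Σ_ij √λ_i^A √λ_j^B
(v_i^A · v_j^B)². The formula presupposes PSD matrices, but an nMI matrix
with a zero diagonal is indefinite — its spectrum is (nearly) symmetric
about zero, so about half the eigen-mass is always negative. Negative
eigenvalues are clipped to zero before the square roots; the clipped
magnitude is recorded on every result (`psd_adjustment`). A warning on
heavy clipping is raised only for direct calls, not inside the
segmentation/clustering loops where it is structural rather than
diagnostic. Two special cases are pinned exactly: equal inputs give Ω = 1
(short-circuited, because d ≈ √round-off would otherwise bite), and two
all-zero matrices are defined as identical (Ω = 1).

Segmentation is greedy and deterministic: walk the time-ordered block
matrices left to right; block t+1 joins the current run iff Ω between the
running mean matrix and M_{t+1} is at least `omega_threshold`; runs
shorter than `min_run` are merged into the contiguous neighbour with the
higher overlap (left wins ties). The substate representative is the
arithmetic mean of its member matrices (reproduces the single-block
identity), and its probability is the member-block fraction. Defaults
`omega_threshold = 0.85`, `min_run = 2` — the segmentation criterion is
"a high degree of similarity", which is inherently a tunable; both are
exposed everywhere. Complete-linkage clustering of substates uses
distance 1 − Ω via `scipy.cluster.hierarchy`.

## Block scheme, ensembles and hub statistics

Trajectories are split into `n_blocks = 20` equal, contiguous,
non-overlapping blocks (remainder frames go one each to the first
blocks), mirroring the 20 × 20 ns block scheme the analysis was designed
around. Ensemble averaging weights each substate by
occupancy/n_replicas. The difference network is
log₂((nMI_holo + c)/(nMI_apo + c)) with pseudocount c = 10⁻³, because
corrected nMI is exactly 0 for many pairs and the ratio is otherwise
undefined; c = 0 restores exact antisymmetry and is available.

Per-pair significance: two-sided Wilcoxon rank-sum (Mann–Whitney) over
the per-substate nMI samples of the two states — exact enumeration when
the pooled sample is tie-free, normal approximation with tie correction
otherwise; all-identical samples get p = 1. Multiplicity is controlled by
Benjamini–Hochberg FDR across all unmasked pairs. Two filters are
supported because both appear in practice: the default |log₂FC| ≥ 2 with
q ≤ 5×10⁻⁴, and a raw-p alternative (`p_max`, typically 0.01). Note the
q-based default needs many substate samples: with only 5 samples per
state the smallest attainable rank-sum p is 1/126 ≈ 0.008, so after a BH
correction across hundreds of pairs *nothing* can reach q ≤ 5×10⁻⁴ — the
synthetic hub-recovery studies therefore use the raw-p filter at 0.01,
which is attainable at 5-vs-5 and matches the exact-enumeration floor.
Hub score is the largest |log₂FC| among a fragment's significant pairs;
ranking ties break toward the lower fragment index.

## Pathways

Fragment nodes are joined when (a) the minimum inter-Cα distance between
the two 4-residue fragments in a reference frame is ≤ `cutoff`
(default 0.75 nm — just beyond two Cα–Cα contact shells, keeping paths
physically contiguous), and (b) nMI ≥ `min_nmi` (default 0.01, the
finite-size noise floor). Edge cost is −ln nMI, so multiplicative
coupling along a path becomes additive cost and Dijkstra finds the most
strongly coupled physically connected route. A virtual super-source with
zero-cost links to all source fragments makes one pass cover a whole
pocket; equal-cost routes resolve to the lexicographically smallest node
sequence. Unreachable sinks are reported explicitly. The edge rule,
weight transform and cutoff are all exposed parameters — the method is
defined by "Dijkstra over the correlation values", not by one specific
gating.

## Schlitter entropy

S′ = (k_B/2) ln det(1 + k_B T e² ħ⁻² M σ), with σ the positional
covariance (SI units; nm → m, Da → kg) and mass weighting applied
symmetrically (√(m_i m_j)), computed through the eigenvalues of
M^½ σ M^½; negative eigenvalues (round-off) are clipped, contributing
ln 1 = 0. S′ is reported per molecule (J/K and units of k_B) and per
mole. The covariance uses the 1/n normalisation so duplicating frames
changes nothing. Rigid-body motion is removed by an iterated
least-squares superposition onto the mean structure (default on; disable
for toy single-particle systems, where superposition would absorb all
motion). The standard determinant form of the bound is used; degenerate
scalar readings of the formula are not dimensionally meaningful for a
matrix σ.

Structural-alphabet encoding itself needs no prior superposition — the
Kabsch fit inside the letter assignment makes it rigid-motion invariant
per fragment — so none is performed before encoding.

## Synthetic generators: what they emulate, and what not

`simulate_alignment` draws latent binary (or k-ary) conformer states per
fragment and frame; a coupled pair (i, j, ρ) shares its state with
probability (1 + ρ)/2 (a binary symmetric channel), giving the planted
coupling a closed-form MI: I = ln 2 − H_b(p), H = ln 2 + H_b(p). Regime
schedules switch the active coupling set over frame intervals, emulating
substate transitions. `simulate_trajectory` realises the letters
geometrically: planted fragments occupy non-overlapping 4-residue slots
on a widely spaced linear scaffold (0.38 nm Cα spacing within a
fragment, 2 nm between slots), so at zero noise re-encoding recovers the
planted letters exactly; optional Gaussian coordinate noise is
Monte-Carlo checked against a 99% letter-recovery floor.

Chosen study conditions (fixed, not tuned per run):

- regime-switch studies: 20 blocks × 400 frames, two regimes of four
  ρ = 1 couplings each, switch at block 10 — this construction yields
  adjacent within-regime overlaps ≥ 0.95 and across-regime overlaps
  < 0.5, the separation regime the segmentation is specified for;
- hub-recovery studies: 5 replicas × 2400 frames per state, one planted
  pair with ρ = 0.5 (nMI ≈ 0.10) vs ρ = 0.99 (nMI ≈ 0.91), an ≈ 8.4-fold
  difference (log₂FC ≈ 3.1) with within-state CV ≤ 0.1.

What the generators do *not* emulate: real fragment-letter
autocorrelation in time (frames are i.i.d. given the regime), three-way
couplings, letter distributions with more than a few conformers per
fragment, folded-geometry contact networks, or the slow conformational
drift of real MD. Passing the recovery studies therefore shows the
estimator/segmentation/testing machinery is correct under its own model,
not that any particular protein's hubs would be found with a given
trajectory length.

The bundled 25-letter alphabet (`data/sa25_synthetic.json`) is
*synthetic*: deterministic output of
`make_synthetic_library(25, seed=20250901)`, chains of four points at
0.38 nm spacing with randomized bend/twist, mutually ≥ 0.05 nm Kabsch
RMSD apart. It is a stand-in with the same interface and cardinality as
published Cα fragment alphabets (e.g. M32K25), whose prototype
coordinates are defined in the prior literature and are not redistributed
here; any such library can be supplied as JSON/CSV.

## Numerical choices and degenerate inputs

- Kabsch RMSD via 3×3 SVD with a determinant sign correction (proper
  rotations only); letter ties break to the lowest library index. A
  degenerate (all-points-identical) reference is an error.
- Near-zero RMSDs carry √-amplified cancellation noise (~10⁻⁸ nm); exact
  zeros are not promised.
- 0·ln 0 ≡ 0 throughout the information measures.
- k-medoid library building uses greedy farthest-point seeding from the
  global medoid, so it is deterministic for a fixed input order.
- Substate probabilities always sum to 1 and member blocks partition the
  block sequence; both are enforced by construction.
- Pipeline outputs are pure functions of (inputs, config); a provenance
  JSON records versions, parameters and input SHA-256 digests.

## Known limitations

- The rank-sum test treats substate matrices as independent samples;
  substates from one replica share initial conditions, so the effective
  sample size is optimistic for short simulations.
- Hub localisation is at fragment (4-residue) resolution, and fragments
  adjacent to a strongly coupled one inherit part of its signal (they
  share 3 residues); expect hubs to come in short runs of neighbours.
- With few substate samples the FDR-based default filter is
  unattainable (see above); the raw-p filter is the practical choice for
  small designs and is reported as such.
- The trajectory generator's linear scaffold cannot produce realistic
  tertiary contacts, so pathway studies on synthetic data use abstract
  graphs rather than generated structures.
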