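# Methods

This note documents the model, the parameters that matter, the
numerical choices, what the synthetic data generator does and does not
emulate, and the package's known limitations.

## Detection model

The package treats single-cell detection as seeded graph clustering.
For each candidate seed it extracts an m×m patch of the (temporally
downsampled) movie, builds a similarity graph over the patch's pixels,
and solves

    (λ-HNC)   min_S  cut(S, S̄) − λ · W_in(S),
              positive seeds ⊆ S,  negative seeds ⊆ S̄,

where `cut(S, S̄)` is the total weight of edges leaving S and
`W_in(S)` the total weight of edges inside S. Small λ favors clusters
that are well separated from the rest of the patch; large λ favors
large, internally coherent clusters.

**Reduction to a parametric minimum cut.** With weighted degrees
`d_i = Σ_j w_ij`, the identity `W_in(S) = (Σ_{i∈S} d_i − cut(S, S̄))/2`
turns the objective into `(1 + λ/2)·cut − (λ/2)·Σ_{i∈S} d_i`, i.e. up
to a positive factor `cut(S, S̄) − μ Σ_{i∈S} d_i` with
`μ = λ/(λ+2) ∈ [0, 1)`. That problem is an s–t minimum cut on an
auxiliary network: arcs `s→i` of capacity `μ·d_i` for every non-seed
node, effectively-infinite arcs pinning positive seeds to `s` and
negative seeds to `t`, and each graph edge as an opposite arc pair of
capacity `w_ij`. Source-side capacities grow monotonically with μ, so
the optimal clusters are nested in μ (hence in λ) and at most `|V|`
distinct clusters exist.

**All breakpoints, no λ grid.** The solver bisects recursively on μ:
solve at the endpoints of an interval; if the two optima differ, solve
at the μ where their objective lines `cut(S) − μ·Σ_{i∈S} d_i` cross.
If the probe returns no strictly better new cluster the crossing is a
breakpoint; otherwise both halves are recursed. This needs O(ℓ) cut
computations for ℓ breakpoints and returns the *exact* breakpoint
family — downstream postprocessing never sees a sampled λ grid. A
fully parametric flow implementation would be an allowed optimization
behind the same contract.

**Max-flow engine.** Cuts are computed by a Dinic max-flow with float
capacities, JIT-compiled with numba. Float capacities avoid the
integer rounding that a fixed-point engine would force on the Gaussian
weights. Residual capacities below 1e−12 are treated as saturated.
The minimal source side (nodes reachable from s in the final residual
network) is returned; it is the unique smallest optimal cluster, which
makes tie-breaking at a fixed λ deterministic ("smallest cluster
wins") and is consistent with the nested-family convention. At an
exact breakpoint both adjacent clusters are optimal; `cluster_at`
resolves the tie to the smaller one.

**Verification.** The solver is checked against exhaustive enumeration
(`brute_force_hnc`) on hundreds of random seeded graphs with ≤ 12
nodes at 20 λ values each (objective agreement to 1e−9), against an
independent max-flow implementation (networkx) for the λ=0 minimum-cut
limit, and against the structural invariants: strict nestedness,
ℓ ≤ |V|, monotone optimal objective, and invariance of the cluster
family under rescaling all weights.

## Similarity: correlation of correlations

Pearson correlation finds pixels of the same cell (they share the
cell's calcium signal) but declares background pixels mutually
dissimilar, although "uncorrelated with everything" is itself a strong
shared signature. The (sim)² measure therefore represents each pixel
by its *correlation image* — the vector of its correlations to a
reference set of pixels — and sets `w_ij = exp(−α‖R_i − R_j‖²)`. Both
within-cell pairs and background-background pairs then receive high
weights, while background-cell pairs do not, which is precisely the
structure the cut needs.

Implementation notes:

- Traces are standardized once per patch (`(x − mean)/(sd·√(T−1))`),
  so correlations are plain dot products. Zero-variance traces map to
  the zero vector: their correlation with anything, themselves
  included, is defined as 0 ("no evidence of co-activity").
- The reference set is resampled independently per patch, i.i.d. with
  replacement, `⌈γ|V|⌉` draws. Sampling noise in R is O(1/√T) per
  entry.
- Sparse computation projects the feature matrix to p dimensions with
  scikit-learn's randomized-solver PCA (any method reproducing the top
  principal subspace is acceptable — the contract is the block
  partition, not the exact projector), min–max rescales each projected
  dimension to [0, 1) (points at the max land in the last block;
  constant dimensions collapse to block 0), and keeps pixel pairs
  whose κ-section grid blocks coincide or are adjacent (Chebyshev
  distance ≤ 1).

## Parameters

| name | default | meaning / guidance |
| --- | --- | --- |
| `temporal_downsample` | 10 | frames averaged into one before all stages; noise reduction |
| `patch_size` m | 31 px | window per seed; must fully contain any cell centered in it |
| `neg_radius` ρ | 10 px | negative-seed circle; must be < m/2, large enough to enclose a cell |
| `superpixel_size` k | 3 px | positive-seed square; 1–5 depending on cell size |
| `n_grid` | 5 px | seed-selection block side; 1 = full enumeration |
| `p_seed` | 0.40 | fraction of blocks processed, best scores first |
| `n_neg` | 10 | negatives on the circle; little effect once the circle encloses the cell |
| `gamma` γ | 0.32 | reference-set sampling rate; ≥ 0.25 loses essentially nothing |
| `alpha` α | 1.0 | Gaussian similarity scale |
| `sparse_p` p | 3 | PCA dimensions for sparse computation |
| `kappa` κ | 25 | grid sections per dimension; larger = sparser graph |
| `n_min`/`n_max`/`n_avg` | 40/200/80 px | size window and preferred size; set from the dataset's cell sizes |
| `overlap_max` | 0.5 | duplicate-suppression overlap threshold |

Named profiles ship the published per-dataset presets (m, ρ, k and the
size window vary with cell size across the benchmark datasets).

## Pipeline design choices

- **Coordinates** are 0-based (row, col), rows increasing downward,
  shared by every module. Movies are promoted to floating point on
  load.
- **Downsampling** drops trailing remainder frames so every output
  frame averages exactly `factor` inputs.
- **Border patches** are translated inward rather than zero-padded
  (padding would fabricate data and corrupt correlations); the seed is
  then off-center. If the negative-seed circle consequently leaves the
  patch, the pipeline keeps the surviving arc of circle points
  (requiring at least 4) — the frame edge already bounds the cluster
  on the missing side. Without this, cells lying within ρ of the
  frame edge are systematically unreachable.
- **Seed scoring** averages each pixel's correlation with its existing
  8-neighbors (3 or 5 at borders), one argmax per grid block, ties to
  the smallest (row, col).
- **Duplicate suppression.** A seed whose center lies inside an
  accepted footprint is skipped. A new footprint is discarded when it
  shares more than `overlap_max` of the smaller footprint's pixels
  with any single accepted footprint, *or* more than `overlap_max` of
  its own pixels with the union of accepted footprints. The union
  clause matters because spurious clusters are often fragmented and
  straddle several accepted cells while staying below every pairwise
  threshold.
- **Footprints are raw pixel sets** — no hole filling, no
  morphological smoothing, no connectivity enforcement; the
  postprocessor is purely size-based.
- **Reproducibility.** Every patch derives an independent RNG stream
  from `(master_seed, seed-row, seed-col)`; reference-set sampling and
  the PCA solver both draw from it. Identical inputs and master seed
  give identical output.
- **Per-seed failures** (e.g. a corner seed retaining fewer than 4
  negatives) are logged and skipped; a run never aborts on one seed.

## Synthetic data

The generator emulates what the detector actually consumes: temporal
correlation structure. Cells are disk footprints whose pixels share
one trace — a Poisson spike train (default 0.02 events/frame)
convolved with an exponential calcium kernel `exp(−t/τ)`, τ = 20
frames, i.e. GCaMP-like ~2.5 s transients at a ~8 Hz frame rate —
superimposed on a static smooth polynomial background plus i.i.d.
Gaussian pixel noise. The stationary signal variance is
`amplitude²·rate/(1 − e^{−2/τ})`, so the expected within-cell pixel
correlation is `sv/(sv + noise_sd²)` and 0 for background pairs;
`noise_sd=None` resolves to SNR 1 (signal variance = noise variance).
The generator's defaults are the package's reference study condition:
128×128, 2000 raw frames (200 after 10× averaging), 15 disjoint disk
cells of radius 4–6 px, SNR 1.

What it deliberately does **not** emulate: overlapping cells and
signal demixing, time-varying (one-photon-like) background, neuropil
contamination, motion artifacts, photon (Poisson) noise, or
non-stationary firing. Passing the end-to-end test therefore shows
that the pipeline recovers disjoint, active cells from realistic
correlation structure at matched signal and noise variance — not that
it handles overlapping or inactive cells (the model does not claim
either).

## Evaluation

Matching is greedy by ascending center-of-mass distance with an
inclusive 5-pixel threshold, each cell matched at most once, distance
ties broken by (reference index, detected index); this realizes
"closest cell, matched once" deterministically. Precision, recall and
F1 follow, with 0/0 defined as 0. The active/inactive classifier
(mean footprint trace, ΔF/F against the trace median as baseline,
active iff > median + 3.5 sample SD at ≥ 3 time steps of the
10×-averaged movie) is a deliberately approximate heuristic and is
labelled as such in its docstring; it uses the simplest ΔF/F baseline
(trace median) rather than a running percentile.

## Problem sizes used in tests

The acceptance-style checks run at sizes chosen so that the full suite
completes in a couple of minutes on one CPU: 200 random graphs with at
most 12 nodes for the solver-oracle comparison (exhaustive enumeration
is exponential), 10 reference-set samplings of a 31×31, 1000-frame
patch for the similarity mechanism, and one 128×128, 2000-frame movie
for the end-to-end run (about 40 s, the single most expensive step).
The end-to-end run uses the shipped "04.00" preset, whose size window
(50–190 px, preferred 90) brackets the generator's cell areas of
~64–133 px, following the method's own rule of adapting the size
window to the dataset's cell sizes.

## Known limitations

- Clusters are not required to be spatially connected; fragmented
  false positives can occur among low-score background seeds and are
  only partially suppressed by the size window and overlap rules.
- Cells without temporal activity are invisible to the method by
  construction.
- The λ=0 cluster of a patch whose seeds lie in disconnected graph
  components is legal (cut 0) but rarely informative.
- The breakpoint search assumes exact arithmetic on objective lines;
  with float weights, breakpoints closer together than ~1e−11 may be
  merged. The acceptance checks bound the practical effect (objective
  agreement to 1e−9).
- Movies must fit in memory; there is no chunked or streaming reader.
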