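# Methods

## The model

`edrnet` studies interareal cortical networks as spatially embedded,
directed, weighted graphs.  The organizing assumption is the
*exponential distance rule* (EDR): the probability that an axonal
projection has length *d* decays as

    p(d) = λ e^(−λd),

with a single decay-rate parameter λ (mm⁻¹).  Given a symmetric matrix
*D* of barycenter-to-barycenter interareal distances, the EDR induces a
family of random connectomes via a maximum-entropy sampling algorithm:

1. draw a length *d* from p(d) restricted to (0, d_max];
2. choose uniformly at random an unordered area pair whose distance
   falls in the same bin as *d* (bin width Δ; draws landing in a bin
   that contains no pairs are rejected and redrawn, which leaves the
   conditional length law intact);
3. insert one unit of weight between them in a uniformly random
   direction;
4. repeat until the number of distinct ordered connected pairs reaches
   the target M, so the realized binary density matches the data
   exactly.

Accumulated multiplicities form the edge weights; because the unimodal
distance distribution q(d) is filtered through an exponential, the
weights come out log-normal-like, spanning several orders of magnitude
at realistic densities.  The *constant distance rule* (CDR) null drops
the distance dependence entirely: pairs are chosen uniformly among all
pairs.  `λ = 0` encodes the CDR exactly.  Note that running the binned
algorithm with a literal tiny positive λ does *not* converge to the
CDR — the bin-based lookup weights bins by p(bin) rather than by pair
count — so the CDR is implemented as its own uniform-pair branch rather
than as a small-λ limit.

Brains of different sizes are compared on a common *adimensional
template*: all distances are divided by the species' mean interareal
distance ⟨d⟩, and the decay rate becomes γ = λ⟨d⟩.  The two regimes
shipped as presets correspond to a small smooth cortex
(⟨d⟩ = 4.54 mm, λ = 0.78 mm⁻¹, ρ = 0.68, γ = 3.54) and a larger folded
one (⟨d⟩ = 26.35 mm, λ = 0.19 mm⁻¹, ρ = 0.66, γ = 5.0).

## Parameters that matter

- **λ (mm⁻¹)** — the only model parameter.  Defaults follow the regimes
  above.  1/λ is the mean axon length.
- **Δ, sampler bin width (mm)** — pair-lookup granularity; defaults
  0.4 mm at mouse scale and 5 mm at macaque scale.  Results are
  insensitive to Δ as long as several pairs populate most bins.
- **M or ρ** — stopping target; the realized binary density always
  equals it exactly.
- **Histogram bin widths** — 0.5 mm for metric distance and length
  histograms, 0.2 for adimensional ones.  Bins are left-closed
  right-open `[kΔ, (k+1)Δ)` with the top edge closed; nothing pins down
  the edge convention, so one was fixed.
- **Matching grid and ensemble** — λ fitting uses a grid search with
  ensemble averages (default 1000 realizations per grid point; analyses
  and tests use 200 with correspondingly wider expectations).  A grid
  argmin is used instead of a continuous optimizer because the objective
  is a noisy ensemble average; the grid is transparent and reproducible.

## Statistics

**Decay-rate estimation.**  `fit_decay` bins a length sample and fits
the log counts against bin centers, either by ordinary least squares
("log-linear") or by a Poisson GLM with log link.  For exponential data,
binned counts are exactly proportional to e^(−λ·center), so both are
unbiased at the bin level; on 2×10⁶ draws they agree to the third
decimal.  A trailing bin that the sample only partially reaches (because
of the length cutoff) is censored and dropped — keeping it biases λ
upward by ~5% at mouse scale.  Confidence intervals use the normal
approximation on the slope.  Local gray-matter decays are fitted with a restricted
`fit_range` (≤ 0.9 mm).

**Motif census.**  Every unordered node triple is classified into one of
the 16 directed 3-node isomorphism classes.  Classes are numbered 1–16
in the classic triad-census order (`003, 012, 102, 021D, 021U, 021C,
111D, 111U, 030T, 030C, 201, 120D, 120U, 120C, 210, 300`); this anchors
class 3 to the lone bidirectional link and class 10 to the oriented
3-cycle, the two classes with a fixed published identity.  The census is
a vectorized 64-pattern table lookup; the table is labeled at import by
running a triad census on each single-pattern graph, and the suite
cross-checks the counts against both networkx and an independent
canonical-form enumeration.  Null profiles use degree-preserving
double-edge swaps (self-loops and duplicate edges rejected, default
10·M attempts) and report per-class log residuals ln(m_data/⟨m_null⟩)
with 2.5/97.5-percentile intervals; classes with zero null mean are
flagged rather than computed.

**Cliques and core.**  A clique requires links in *both* directions
between every member pair (on a 12-node set with a single missing
directed link, the best cliques have 11 nodes — the directed convention
is forced by that published example).  The census counts *all* cliques
per size, not only maximal ones; both are exposed.  The core is the
union of all maximum cliques; ties are all included.  Block densities
are reported at full precision and rounded to whole percent.  The
Erdős–Rényi chance likelihood of a core block uses the closed binomial
formula C(N,n_c)·C(n_c(n_c−1),M_cc)·p^M_cc·(1−p)^rest evaluated in log
space.  Evaluating it with the published inputs (N=33, n_c=12,
M_cc=131, p=0.681) gives ≈ 6.8×10⁻¹², not the printed 2.07×10⁻¹²; the
convention behind the printed figure is ambiguous, so the formula is
implemented as printed and the discrepancy is documented rather than
resolved.  Nothing downstream depends on it beyond "vanishingly small".

**Similarity.**  The in-link similarity of areas (x, y) counts the
sources from which both or neither receive a projection, normalized by
N, minus the agreement expected from the two in-degrees alone.  All N
areas count as potential sources, including x and y themselves (absent
self-connections contribute "neither" agreements); the inclusive
convention is forced by the published bound n ≤ N.  The index is
symmetric, zero in expectation on Erdős–Rényi graphs, and decays with
distance under the EDR; steeper γ tilts the profile more strongly.
Ensemble clouds pool 300 EDR realizations by default and are smoothed
with a Gaussian KDE (Silverman bandwidth; any rule giving a comparably
smooth cloud would do).

**Wiring.**  Total wire length Λ = Σ A_ij D_ij.  The null permutes rows
and columns of A together, which reassigns areas to positions while
fixing the topology; E[Λ_null] = M·⟨d⟩.  Annealed placement uses
position swaps with Metropolis acceptance and geometric cooling
(defaults T₀ = Λ/100, factor 0.999, 10⁵ steps; the schedule is a design
choice and is fully configurable).  One caveat discovered empirically: at N = 33 and ρ ≈ 0.68,
*chance-level* optimization over the 33! placements reduces Λ by ~8–10%
even for distance-blind CDR graphs, so "percent reduction" is not by
itself evidence of spatial structure.  The discriminating statistic is
the position of Λ_data in the permutation null: EDR layouts sit below
the 5th percentile, CDR layouts are typical draws.

**Variance comparison.**  The two-sided permutation test on the
variance ratio var(x)/var(y) counts permuted ratios ≤ min(r, 1/r) or
≥ max(r, 1/r), includes the observed ratio in the permutation
distribution (minimum attainable p = 1/(n_perm+1)), and is calibrated:
null p-values are uniform.

## Synthetic species

The real distance matrices and tracer connectomes behind the published
analyses are not machine-readable, so all analyses and tests run on
synthetic species with known ground truth.  `make_species` lays area
barycenters on a jittered grid over a 2-D sheet, rescales coordinates to
an exact target ⟨d⟩, realizes one EDR connectome, and draws an
axon-length sample from the realized connection lengths with
multiplicity — the same pathway a tracer-derived neuron-count histogram
measures.  The presets mask the grid to the inscribed ellipse of the
sheet: a full rectangle cannot reach the empirical d_max/⟨d⟩ ≈ 2.2 (its
corner pairs force ≥ ~2.55), while the rounded sheet lands at 2.1–2.45
depending on the jitter draw.  The rectangle remains available via
`shape="rectangle"`.

What the fixtures do *not* emulate: cortical folding (which sharpens
q(d) — the presets differ in γ but not strongly in q-shape), geodesic
white-matter path lengths (distances are Euclidean on the sheet),
area-specific or anisotropic decay rates, and measurement asymmetries of
anterograde vs retrograde tracing.  Passing tests therefore certify the
statistical machinery and the model's internal behavior, not claims
about any particular real cortex.

## Problem sizes

Analyses and the test suite run at the published scale where that is
cheap (N = 33 areas, ρ ≈ 0.66–0.68, 2×10⁶ length draws, 1000-draw
permutation nulls) and at reduced ensemble sizes where the published
choice is expensive (matching ensembles of 200 instead of ≥10³;
annealing runs of 2×10⁴–10⁵ steps).  Reduced-ensemble expectations are
correspondingly widened, following the tolerance laid out with each
check.

## Known limitations

- λ_P from parameter matching inherits the sampling noise of the single
  target realization; at N = 33 its seed-to-seed spread is about one
  0.05 grid step (occasionally two for the clique measure, whose counts
  are heavy-tailed).
- The annealer is a plain Metropolis scheme; it recovers planted optima
  on small instances but carries no optimality guarantee.
- The weighted wire cost Σ W_ij D_ij is exposed but not validated
  against any external result.
- Edge weights are insertion multiplicities (integers); FLN views are
  per-target normalizations of those, not modeled neuron counts.
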