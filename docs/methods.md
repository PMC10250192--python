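# Methods

This note documents the models and algorithms implemented in `lepimacro`,
the defaults and numerical choices, what the synthetic-data generators do
and do not emulate, and known limitations.

## Data model

All stages share a `DatedTree`: a rooted, strictly bifurcating, ultrametric
phylogeny with branch lengths in millions of years (Ma) and node ages in Ma
before present. Ultrametricity is checked to a relative tolerance of 1e-6 on
root-to-tip path sums; non-ultrametric input is accepted only with an
explicit override (likelihoods still run, but time-sliced summaries are
unreliable and the parser warns). Polytomies are rejected by default and can
be resolved arbitrarily with zero-length branches in seeded order, because
every likelihood here assumes bifurcation. Tables are UTF-8 CSV with a
header row; species keys are matched case-sensitively after whitespace
trimming. Every stochastic operation takes an explicit seeded
`numpy.random.Generator`; the same seed gives bit-identical output.

## Host-module detection

The butterfly × host-family record matrix `A` (non-negative weights; row
sums `r`, column sums `c`, total `F`) is partitioned by maximizing Barber's
weighted bipartite modularity

    Q = (1/F) * sum_ij (A_ij - r_i c_j / F) * delta(g_i, g_j).

Search: label-propagation ascent in the LPAwb+ spirit — alternating
row/column sweeps move each node to the label maximizing its own Q
contribution (ties to the lowest label id, so runs are deterministic given
the seed) — iterated with greedy pairwise module merging until neither step
improves Q by more than 1e-10 (at most 10,000 sweeps). The best of
`n_restarts` (default 20) initializations is returned: one restart seeds
unique labels on rows, one on columns (the canonical start when that side is
smaller), the rest use random labelings of random coarseness. Returned
module ids are canonical: ordered by total module weight, ties broken by the
lexicographically smallest member label. Record counts are used as weights
by default; a presence/absence collapse is available. Butterflies whose only
"hosts" are non-plant foods participate as ordinary column groups unless
excluded via configuration.

On matrices small enough for exhaustive search the ascent attains the global
maximum; at the default study scale (200 species, 13 planted modules, 5%
noise) the planted partition is recovered with adjusted Rand index >= 0.9 in
~96% of replicates. The remaining failures are identifiability failures of
the noisy instance, not search failures: the Q-maximal partition genuinely
merges a module pair glued by heavy noise edges (verified by comparing the
search optimum against an ascent started from the truth).

## Diet breadth and host relatedness

A species is a specialist if its deduplicated host-family set has size
k = 1 and a generalist if k >= 2. Host-repertoire spread on a dated
plant-family tree is summarized by six metrics: richness k, mean pairwise
patristic distance (MPD), mean nearest-taxon distance (MNTD), phylogenetic
diversity (PD, the spanning-subtree branch length, optionally including the
root path), the maximum pairwise distance, and the variance of pairwise
distances. Distance metrics are undefined (NaN) for k = 1; families missing
from the plant tree are dropped and reported.

The relatedness test is one-tailed per species: observed MPD against a null
of k families drawn uniformly **without replacement** from the host pool
(default pool: all families observed in the dataset — restricting the null
to plausible hosts), N = 999 draws by default, with the +1 correction
p = (#{null <= observed} + 1)/(N + 1), so p is never 0 and is exact under
exchangeability. MPD was chosen as the test statistic because it is the
standard relatedness summary; the other metrics are emitted for inspection.
No multiple-testing correction is applied across species — the reported
summary is the raw fraction of generalists with p <= alpha (default 0.05).
Under random diets the test rejects at the nominal rate (checked over 1,000
synthetic generalists); under clade-clustered diets its power at the default
study scale is ~0.9.

## Mk models and stochastic character mapping

Discrete characters evolve by a k-state continuous-time Markov chain with
generator Q (1/Ma): ER (one symmetric rate) or ARD (all k(k-1) rates free).
Likelihoods use Felsenstein pruning with per-branch transition matrices
P(t) = exp(Qt), computed by eigendecomposition with an `expm` fallback when
the eigenvector matrix is ill-conditioned, and per-node rescaling against
underflow. Missing tips (no host data) get all-ones partials, preserving
tree shape without adding state information. The root prior defaults to the
stationary distribution of the fitted Q (flat for ER) and is configurable.
ML rates are optimized on the log scale in [1e-9, 1e3]/Ma (bounded scalar
optimization for ER; multistart L-BFGS-B for ARD). A character observed in
fewer than two states yields a boundary fit with a warning. For the 13-state
host-module character ER is the default (ARD's 156 rates are
over-parameterized); ARD remains available.

Stochastic maps follow the SIMMAP recipe: conditional likelihoods up, root
state from its posterior, each node conditional on its parent, then each
branch path conditional on its endpoints by **uniformization**: the chain is
rewritten with jump rate L = max_s(-Q_ss) and jump matrix R = I + Q/L; the
conditioned jump count is sampled from its exact series (truncated when the
remaining Poisson tail is below 1e-10), intermediate states from the
conditioned jump chain, jump times as uniform order statistics, and virtual
(self) jumps removed. Degenerate cases (zero rate, zero-length branches)
require equal endpoints and return a single segment. Map-averaged node
frequencies converge to the exact marginals (computed independently by an
outside/inside pass) and per-branch segment durations sum to branch lengths
by construction; both are asserted in the tests. `n_maps` defaults to 1,000.

## DEC biogeography

Ranges are non-empty subsets of 2–14 bioregions, enumerated in deterministic
order (by size, then lexicographically), optionally constrained by a maximum
range size and by connectivity under an adjacency matrix — the practical
route to tractable state counts, since unconstrained spaces grow as 2^n - 1.
The anagenetic generator adds area j to range R at rate
d * sum_{i in R} adj[i, j] and removes each occupied area at rate e, the
last removal entering an absorbing null (globally extinct) range;
transitions whose target is excluded from the state space are disallowed.
Cladogenesis at nodes: DEC allows identity (single-area), subset sympatry
and single-area vicariance; DIVALIKE allows any vicariant split (both
daughters may be multi-area) and no subset sympatry; events in a range's set
are equally weighted and renormalized after filtering against the state
space. Founder (+J) jump dispersal is deliberately excluded. The root prior
is flat over allowed ranges. Time-stratified models attach one adjacency
matrix per slice; branches crossing slice boundaries multiply per-segment
transition matrices in time order.

The state vector carries the null range explicitly. A tip whose range value
is `None` is an **observed** extinct-in-place lineage (the forward
simulator's null flag); `"?"` marks genuinely missing data. This matters for
parameter recovery: if extinct lineages are pruned or treated as missing,
the ML of e collapses to 0 regardless of the truth — single-area daughters
come "for free" from DEC cladogenesis while the absorbing null makes the
extant-tip likelihood strictly decreasing in e (we verified this across tree
scales, including truth e = 0.1 recovering ~0.003). Feeding the complete
generator output to the likelihood makes (d, e) jointly identifiable —
median relative errors of ~1% (d) and ~4% (e) at the test conditions — and
the construction reduces exactly to the standard DEC likelihood when every
tip is extant. Empirical datasets, which contain no observed extinct tips,
therefore inherit the usual DEC caveat that e is weakly identified.

ML of (d, e) is multistart L-BFGS-B on log rates in [1e-8, 1e2]/Ma.
Ancestral ranges are exact marginals from an outside pass through the
cladogenetic event tables. Biogeographic stochastic mapping samples node
ranges and cladogenetic events from their joint posterior, then
endpoint-conditioned anagenetic paths per branch by the same uniformization
machinery. Every expansion R -> R + {j} is logged at its time (Ma before
present) and attributed as dispersal into j from each source i in R with
weight adj[i, j] / sum_i' adj[i', j] (the attribution rule is configurable in
spirit: stored events keep full detail). Relative mean rates are mean
per-simulation counts; the divide-by-100 display convention used in figure
annotations is an output option and never applied to stored values.
Time-sliced rates bin events into half-open [t, t + 5) Ma bins (an event at
exactly 5 Ma falls in the older bin's interval [5, 10)); named-period
matrices average the member bins whose midpoints fall inside the period.

## Sampling-fraction arithmetic

True richness per state is estimated as
`total_richness x family_proportion x state_proportion`, rounded half-up
only at the final reported step (3358.57 -> 3,359; rounding earlier would
compound). Genus-based module richness splits each genus' total equally over
the **distinct** modules of its sampled congeners (24 species over 3 modules
-> 8 each); allocations stay fractional until module totals are reported.
Fraction files divide sampled counts by estimated totals; a sampled count
exceeding its estimate is clipped to fraction 1 with a warning. Per-family
state estimates always sum back to the family total within 1 of rounding.

## Synthetic-data generators

The generators define the study conditions the tests run under:

- **Trees**: forward Gillespie birth–death from two crown lineages,
  conditioned on n extant tips by stopping the clock when the event after
  reaching n would occur (so pure-birth crown ages have mean
  sum_{k=2..n} 1/(lambda k)); clade death triggers rejection and
  re-simulation (capped at 10,000 attempts). With extinction this is
  first-passage stopping, not uniform sampling over histories — adequate for
  generating test conditions, and documented here for that reason. Defaults
  (200 tips, lambda = 0.06, mu = 0.01 /Ma) give crown ages near 100 Ma.
- **Host matrices**: 13 planted modules of 3 host families; balanced home-
  module assignment (block sizes differ by at most one, the standard
  planted-partition benchmark design, keeping the planted structure
  identifiable); 32.3% generalists; generalist repertoire k = 1 +
  zero-truncated-Poisson(1.2), capped at module size; each extra family
  within-module with probability 1 - noise (noise default 0.05, one decision
  per repertoire slot, sampled without replacement); weights
  Poisson(3) + 1 record counts. Real host databases are sparser, heavier-
  tailed and phylogenetically autocorrelated; passing recovery tests here
  show the algorithms work when the planted signal exists, not that any
  empirical matrix has 13 modules.
- **Plant trees**: a backbone over modules (crown 120 Ma) carrying one young
  clade per module (crown 15 Ma), so within-module families are mutually
  closely related — the structure the relatedness test has power against.
- **Traits**: forward CTMC simulation along branches with retained internal
  truth; default 2 states at 0.005/Ma (low saturation over ~100 Ma).
- **Ranges**: Gillespie DEC dynamics along branches (d = 0.05, e = 0.01 /Ma
  over 7 realm-like areas by default), uniform cladogenetic events at nodes,
  null absorbing with extinct-in-place tips flagged.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run entirely on synthetic data:
oracle comparisons on 2–4-tip fixtures with 2–3 areas; sampler checks at
10,000 maps/simulations on those fixtures; parameter recovery over 20
replicates of 300-tip (DEC, 4 areas) and 500-tip (Mk) trees; null-test
calibration over 1,000 random generalists (999 null draws each); module
recovery over 50 replicates at 200 species. The acceptance script mirrors
these at the same or slightly smaller sizes (its BSM stage uses one 100-tip
tree with 1,000 simulations, the mapping count used for the dispersal-rate
summaries).

## Known limitations

- No +J founder-event cladogenesis; no Bayesian sampling of Q or (d, e).
- e in DEC is weakly identified from extant-only data (see above).
- The label-propagation search is a heuristic; global optimality is only
  guaranteed where exhaustive enumeration is feasible (and verified there).
- The bipartite-network and diet stages treat species as independent; no
  phylogenetic signal is modeled in module membership itself.
- Duplicate tip labels are rejected rather than resolved; deduplication of
  conspecific specimens is left to the user.
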