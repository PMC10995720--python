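# Methods

`dolloml` compares two ways of reconstructing ancestral gene content on a
rooted phylogeny from a binary presence/absence matrix of orthogroups (or
protein domains), and ships a synthetic-data generator that reproduces the
error structure of similarity-based orthology inference against a known
truth. This note records the models, the conventions the package fixes
where the underlying tools leave them open, and what the synthetic
experiments do and do not demonstrate.

## Dollo parsimony

A character may be gained exactly once and lost arbitrarily often; the
reconstruction minimizes losses under that constraint, with **absence as
the ancestral state**. Both choices follow the conventions of the classic
Dollo implementations (a fixed input tree, states reported at all nodes,
zero treated as ancestral). Under them the optimum is closed-form: the gain
sits at the most recent common ancestor (MRCA) of the carrier tips, and a
node is present iff it descends from (or is) the MRCA and its own subtree
still contains a carrier. A character found on both sides of the root is
gained "at" the root, which keeps gain/loss bookkeeping well defined there.
The optimum is unique under this convention; the test suite asserts both
optimality and uniqueness against exhaustive enumeration of all single-gain
assignments on trees of up to 12 internal nodes. Branch lengths are never
read.

Because Dollo places every orthogroup at the MRCA of its members, an
orthology pipeline that splits one family into several groups whose member
species straddle a deep node will make Dollo count that family several
times at that node — the inflation mechanism the comparison is designed to
expose.

## Two-state CTMC and marginal reconstruction

The likelihood engine models each character as a stationary, time-reversible
two-state Markov chain, homogeneous across branches:

* `kappa` = pi1/pi0 parameterizes the stationary frequencies
  (pi0 = 1/(1+kappa), pi1 = kappa/(1+kappa)); the root prior is the
  stationary distribution.
* The rate matrix is normalized by s = 1/(2 pi0 pi1) so that branch lengths
  are expected state changes at relative rate 1. The binary chain then has
  closed-form transition probabilities
  P01(tau) = pi1 (1 - e^(-s tau)), P10(tau) = pi0 (1 - e^(-s tau)) with
  tau = r t. Different normalizations amount to a constant rescaling of
  branch lengths and are absorbed whenever lengths are refit.
* Among-character rate variation is discrete-gamma: `n_categories` (default
  4) equal-probability categories, each represented by the analytic mean of
  gamma(alpha, rate alpha) over its quantile segment, renormalized to mean
  exactly 1.

Likelihoods use Felsenstein pruning over unique site patterns with
per-(node, pattern) rescaling (log-scale accumulators), so matrices with
tens of thousands of columns on 57-tip trees are handled without underflow.
Marginal posteriors use the standard up-down (outside) recursion; rate
categories are mixed by their posterior weights. Tip posteriors equal the
observed states (the observation model is error-free). The engine is
checked against exhaustive enumeration over all internal-state assignments
and categories (relative tolerance 1e-10) on trees of up to 10 internal
nodes.

**Fitting.** Any subset of {kappa, alpha, branch lengths} is maximized by
coordinate-wise bounded scalar optimization (Brent): log kappa in [-7, 7],
log alpha in [-3, 5], branch lengths in [1e-9, 100], deterministic
initialization (kappa = 1, alpha = 1, input lengths), sweeps repeated until
the log-likelihood gains less than 1e-6 (at most 50 sweeps). Branch sweeps
run in pre-order with partial vectors updated in place, so each 1-D
maximization sees the current values of all other branches and is accepted
only if it improves the objective — the trajectory is monotone. An
all-constant matrix leaves the likelihood flat in branch lengths; the fit
warns and keeps the input lengths. Parameter-recovery tests generate 5,000
characters on the 57-tip tree at the empirical Pfam fit (kappa = 0.20,
alpha = 0.46) and require both estimates back within 20% relative error;
observed errors are a few percent.

## Count and gain/loss statistics

Per-node counts are sums over characters: 0/1 states for Dollo, marginal
posterior presence probabilities for ML ("expected counts"). Gains and
losses are tallied per edge against the parent. For ML two modes exist:

* `expected-difference` (default): a character contributes
  max(p_child - p_parent, 0) to gains and the mirror image to losses. This
  preserves the balance identity count(child) = count(parent) + gains -
  losses exactly (to 1e-9), which the Dollo tallies satisfy by construction.
* `event-count`: each character contributes a full 1 to whichever side its
  probability moved, ties contributing nothing — the semantics a
  threshold-style post-processing script would produce.

Post-processing scripts in the wild describe this tallying loosely enough
to mean either mode; `expected-difference` is the default here because it
keeps counts and flows consistent and degrades gracefully for near-equal
probabilities. The root has no parent edge: Dollo books root-origin
characters as gains at the root itself; ML books nothing there.

Overestimation summaries compare per-node counts against a known truth,
report the maximum overestimate per node across replicates, flag nodes
exceeding a threshold (default 105 genes in at least one replicate), and
aggregate by node depth, measured as the number of internal nodes strictly
between a node and the root (root and its children at depth 0). Pooled
gain/loss quartiles are reported so a "major event" cut (e.g. the third
quartile) can be applied to any run.

## Synthetic data generator

Each replicate simulates `n_families` (default 5,000) families present in
every tip of a guide tree with **no gains and no losses** — the true count
at every node is exactly `n_families` — then re-derives orthogroups from
the sequences the way a similarity clusterer would, with full provenance
records.

* **Sequence evolution.** Aligned sequences (default length 200, no indels)
  evolve by a 20-state Poisson process: per-site rates are continuous
  gamma(`alpha_sites`) draws shared across the tree; each edge accumulates
  Poisson(t x `rate_scalar` x site rate) substitutions, each replacing the
  letter uniformly among the other 19. The endpoint given the substitution
  count is sampled from its exact distribution rather than by iterating
  replacements (validated against one-at-a-time application). The process
  is chosen over an empirical amino-acid matrix because expected identity
  has the closed form p_same(tau) = 1/20 + (19/20) e^(-(20/19) tau), making
  the generator testable by quadrature; a hook accepts a user-supplied
  symmetric exchangeability matrix. Per-replicate nuisance parameters span
  the ranges such simulation experiments use: `rate_scalar` uniform in
  [0.2, 10] and `alpha_sites` uniform in [0.4, 1.6] (only the ranges are
  part of the experimental design, so the draws are uniform).
* **Clustering.** Within each family, sequences are single-linkage
  clustered at pairwise identity >= theta (default 0.25). Components of
  size >= 2 become orthogroups; isolated sequences become singletons,
  excluded from every orthogroup and hence scored absent — exactly how
  similarity-based orthology tools lose divergent members. An optional
  per-(family, species) duplication hook (default probability 0.05, extra
  divergence 0.05) produces the same-species co-clustering distortion;
  presence is still scored once per species.
* **Guide tree.** The default 57-tip tree is built as two nested
  radiations: a deep burst (balanced topology, internal edges ~0.002)
  into 28 subclades with long stems (log-normal around 0.30), each
  followed by a recent burst (terminal branches log-normal around 0.05
  with heavy jitter, sigma 0.6). This emulates clades like the metazoan
  phyla — deep splits in quick succession, long independent stems — and it
  is what makes the clustering errors realistic: within-subclade
  identities stay high long after all between-subclade identities have
  decayed to a common near-threshold band, so fast replicates keep
  subclades intact while connecting them essentially at random.
  Occasional long terminal branches produce singletons.
* **Calibration.** theta = 0.25 is calibrated jointly with the tree scale
  so that slow replicates (`rate_scalar` <= 0.5) come back almost fully
  intact: generate_dataset enforces that at least 99% of families form one
  complete cluster there and raises a configuration error otherwise. At
  fast rates the same threshold sits inside the saturation band, which
  produces the three distortions of interest: family splitting (orthogroup
  counts grow monotonically with the rate scalar), singletons, and
  orthogroups whose tip sets straddle deep nodes — including, at rate
  scalar ~8, families fragmenting into more than one root-spanning group,
  which is precisely what makes Dollo's root count exceed the truth.
* **Determinism.** One master seed; per-family streams are derived by
  counter-based seed sequences (master, replicate, family), so any single
  family is reproducible in isolation.

A sequence-free generator (`fragment_phenomenological`) cuts tree edges
independently with probability `p_split` and turns the resulting tip blocks
into orthogroups/singletons; it reproduces the split/singleton structure
cheaply for tests that do not study the divergence mechanism itself.

**What the generator does not emulate.** Cross-family clustering (and with
it false merges between unrelated families), insertions/deletions and
alignment error, empirical amino-acid exchangeabilities, gene gain/loss or
transfer during simulation, and real orthology pipelines' score
normalization. Consequently the Dollo root inflation reproduced here is
driven by within-family fragmentation into deep-node-straddling groups in
the near-threshold regime; on real data, nonorthologous similarity between
families adds a further inflation route that is out of scope here. Passing
tests therefore demonstrate the engines' statistical behavior under
controlled orthology error, not the full error budget of an empirical
pipeline.

## Problem sizes and runtime choices

The study-scale checks use the simulated experiment's dimensions — 57 tips,
5,000 families per replicate, three replicates at rate scalars
{0.5, 2, 8} with alpha_sites = 0.8 — which run in minutes on one core
thanks to pattern compression (a fast replicate yields ~28,000 orthogroups
but only ~2,600 unique presence patterns). Exhaustive-oracle suites use
1,000 random Dollo instances (<= 12 internal nodes) and 500 random
likelihood instances (<= 10 internal nodes). Property tests on parsing,
conversion and tallying use small random trees and matrices.

## Degenerate inputs and edge conventions

Characters absent from every tip reconstruct as all-absent with no origin
(they cannot arise from orthogroup tables, where every group has at least
one member). Newick edges without lengths default to 1.0 with a warning
(Dollo ignores lengths; ML requires them). Polytomies are resolved
randomly, seeded, by repeatedly joining two random children under a new
node with branch length 1e-6 — small enough that ML transition matrices on
the new edges stay effectively the identity, while Dollo is unaffected.
Single-node trees are accepted (the likelihood base case). PHYLIP discrete
output pads/truncates names to exactly 10 characters and refuses ambiguous
truncations. No ascertainment-bias correction is applied for invariant
columns, matching the default behavior of the reference ML toolchain.

## Known limitations

Joint (max-path) ancestral reconstruction, non-stationary or
branch-heterogeneous models, and >2-state characters are out of scope. The
coordinate-wise optimizer is robust for this 2-state model but slower than
gradient-based alternatives; branch-length fits on matrices with ~30,000
columns dominate runtime. The root inflation produced by the generator is
a stochastic, near-threshold phenomenon: its size (a few percent of the
true count at the root) is smaller than what cross-family false orthology
can produce on real data.
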