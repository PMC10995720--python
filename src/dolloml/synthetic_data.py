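"""Synthetic data with the error structure of similarity-based orthology
inference, against a known gene-content truth.

Each replicate starts from ``n_families`` gene families present in every
tip of a guide tree, with **no gains and no losses**: the true ancestral
count at every node is exactly ``n_families``. Protein sequences evolve
independently for each family along the guide tree under a 20-state Poisson
substitution process, with branch lengths multiplied by a per-replicate
rate scalar (drawn in [0.2, 10]) and among-site rate variation drawn from a
gamma distribution whose shape is drawn per replicate in [0.4, 1.6]. A
similarity clusterer (single linkage at a pairwise-identity threshold) then
partitions each family's sequences into orthogroups, reproducing the three
distortions of real orthology inference: families split into several
orthogroups, sequences left as singletons (excluded from every orthogroup),
and multiple genes of one species co-clustered (via an optional per-species
gene-duplication hook). Every simulated gene is tracked, so downstream
reconstructions can be compared against the exact truth.

The 20-state Poisson process (uniform replacement among the 19 other
letters) is used instead of an empirical amino-acid matrix because expected
pairwise identity then has the closed form

    p_same(tau) = 1/20 + (19/20) * exp(-(20/19) * tau),

which makes the whole generator testable against quadrature; an optional
hook accepts a user-supplied symmetric exchangeability matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .phylo_io import OrthogroupTable, RootedTree

N_LETTERS = 20

#: Per-replicate parameter ranges of the simulated experiment.
RATE_SCALAR_RANGE = (0.2, 10.0)
ALPHA_SITES_RANGE = (0.4, 1.6)

#: Default single-linkage pairwise-identity threshold. Calibrated on the
#: default 57-tip guide tree so that (i) replicates at rate scalar <= 0.5
#: are almost always partitioned into complete single-cluster families and
#: (ii) at fast rates the between-subclade identities sit in the
#: near-threshold band where clustering errors — splits, singletons and
#: deep-node-straddling groups — actually occur, as they do for real
#: similarity-based orthology inference on saturated sequences.
IDENTITY_THRESHOLD = 0.25

#: Extra branch length separating a duplicated gene from its source tip
#: sequence (the same-species co-clustering hook).
PARALOG_DIVERGENCE = 0.05


class CalibrationError(ValueError):
    """Raised when a slow-rate replicate fails the completeness contract."""


# ---------------------------------------------------------------------------
# Guide tree
# ---------------------------------------------------------------------------

def _balanced_topology(rng: np.random.Generator, n_leaves: int
                       ) -> tuple[list[int], list[list[int]]]:
    """Balanced random bifurcating topology (leaf sets halved recursively,
    with a random shuffle so the shape varies with the seed).

    Returns (parent, children) with node 0 as root; leaves are the nodes
    with no children.
    """
    parent = [-1]
    children: list[list[int]] = [[]]
    order = rng.permutation(n_leaves)

    def build(node: int, leaves: np.ndarray) -> None:
        if len(leaves) == 1:
            return
        half = len(leaves) // 2
        for part in (leaves[:half], leaves[half:]):
            child = len(parent)
            parent.append(node)
            children.append([])
            children[node].append(child)
            build(child, part)

    build(0, order)
    return parent, children


def guide_tree(n_tips: int = 57, seed: int = 2024,
               n_subclades: int = 28,
               stem: float = 0.30, crown: float = 0.05,
               internal_scale: float = 0.002,
               stem_jitter: float = 0.05,
               crown_jitter: float = 0.6) -> RootedTree:
    """Random bifurcating guide tree shaped like nested rapid radiations.

    The tree has two bursts of diversification: a deep, nearly simultaneous
    radiation (balanced topology, tiny internal edges of mean
    ``internal_scale``) splitting the root into ``n_subclades`` subclades
    whose stems are long (log-normal around ``stem``), and a recent
    radiation inside each subclade (tiny internals, terminal branches
    log-normal around ``crown``). This is the branch-length profile of
    groups such as the metazoan phyla: deep splits in quick succession,
    long independent stems, then recent diversification.

    For orthology-error simulation the consequence is that sequences within
    a subclade stay mutually similar long after all between-subclade
    identities have decayed to a common, near-threshold level — and because
    the deep internodes are negligible, every pair of subclades is at
    essentially the same distance, whichever side of the root each sits on.
    In fast replicates the similarity graph therefore keeps subclades
    intact but connects them essentially at random, producing orthogroups
    that straddle deep nodes in several disjoint pieces — the signature
    distortion of similarity-based orthology inference on saturated
    sequences. Deterministic given ``seed``; tips are named ``sp01..spNN``.
    """
    if n_tips < 2:
        raise ValueError("need at least two tips")
    n_subclades = min(n_subclades, n_tips)
    rng = np.random.default_rng(seed)
    sizes = np.full(n_subclades, n_tips // n_subclades)
    sizes[:n_tips - sizes.sum()] += 1

    # deep radiation over subclade stems
    parent, children = _balanced_topology(rng, n_subclades)
    blen = [float("nan")] * len(parent)
    labels: list[str | None] = [None] * len(parent)
    stems = [v for v in range(len(parent)) if not children[v]]
    for v in range(len(parent)):
        if parent[v] != -1:
            blen[v] = float(rng.exponential(internal_scale))

    tip_no = 0
    for stem_node, size in zip(stems, sizes):
        blen[stem_node] = float(stem * rng.lognormal(0.0, stem_jitter))
        sub_parent, sub_children = _balanced_topology(rng, int(size))
        offset = len(parent)
        for sv in range(len(sub_parent)):
            if sub_parent[sv] == -1:      # subclade root merges into stem
                continue
            parent.append(offset + sub_parent[sv] - 1
                          if sub_parent[sv] != 0 else stem_node)
            children.append([])
            blen.append(float("nan"))
            labels.append(None)
        # remap: subclade node sv>0 -> offset+sv-1; sv==0 -> stem_node
        def node_id(sv: int) -> int:
            return stem_node if sv == 0 else offset + sv - 1
        for sv in range(len(sub_parent)):
            for c in sub_children[sv]:
                children[node_id(sv)].append(node_id(c))
        for sv in range(1, len(sub_parent)):
            v = node_id(sv)
            if sub_children[sv]:
                blen[v] = float(rng.exponential(internal_scale))
            else:
                tip_no += 1
                labels[v] = f"sp{tip_no:02d}"
                blen[v] = float(crown * rng.lognormal(0.0, crown_jitter))
        if not sub_children[0]:           # single-tip subclade
            tip_no += 1
            labels[stem_node] = f"sp{tip_no:02d}"

    from .phylo_io import _canonicalize  # reuse the post-order renumbering
    root = parent.index(-1)
    return _canonicalize(np.asarray(parent), children, blen, labels, root)


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------

def _poisson_endpoint_same_prob(n_subs: np.ndarray) -> np.ndarray:
    """P(final letter == initial letter | n substitutions) for the uniform
    20-state jump chain: 1/20 + (19/20) * (-1/19)**n."""
    return 1.0 / N_LETTERS + (N_LETTERS - 1.0) / N_LETTERS * \
        (-1.0 / (N_LETTERS - 1.0)) ** n_subs


def _evolve_along_edge(seq: np.ndarray, tau: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Evolve a sequence over per-site expected substitution counts ``tau``.

    Substitution counts are Poisson; the endpoint letter given the count is
    sampled from its exact distribution (equal to applying that many uniform
    replacements one by one) rather than by iterating replacements.
    """
    n_subs = rng.poisson(tau)
    p_same = _poisson_endpoint_same_prob(n_subs)
    stay = rng.random(seq.shape) < p_same
    jumps = (seq + 1 + rng.integers(0, N_LETTERS - 1, size=seq.shape)) \
        % N_LETTERS
    return np.where(stay, seq, jumps).astype(np.uint8)


def _evolve_along_edge_explicit(seq: np.ndarray, n_subs: np.ndarray,
                                rng: np.random.Generator) -> np.ndarray:
    """Reference implementation: apply each substitution one at a time.
    Used only to validate the closed-form endpoint sampling."""
    out = seq.astype(np.int64).copy()
    remaining = n_subs.copy()
    while (remaining > 0).any():
        hit = remaining > 0
        out[hit] = (out[hit] + 1
                    + rng.integers(0, N_LETTERS - 1, size=int(hit.sum()))) \
            % N_LETTERS
        remaining[hit] -= 1
    return out.astype(np.uint8)


def expected_identity(distance: float, alpha_sites: float | None = None,
                      n_quad: int = 400) -> float:
    """Expected pairwise identity at total path length ``distance``.

    With a fixed site rate the identity is p_same(distance); with gamma
    among-site rates the closed form is averaged over the rate distribution
    by quantile quadrature.
    """
    def p_same(tau):
        return 1.0 / N_LETTERS + (N_LETTERS - 1.0) / N_LETTERS * \
            np.exp(-N_LETTERS / (N_LETTERS - 1.0) * tau)

    if alpha_sites is None:
        return float(p_same(distance))
    from scipy import stats
    q = (np.arange(n_quad) + 0.5) / n_quad
    rates = stats.gamma.ppf(q, a=alpha_sites, scale=1.0 / alpha_sites)
    return float(np.mean(p_same(rates * distance)))


def simulate_family(tree: RootedTree, rate_scalar: float, alpha_sites: float,
                    seq_length: int, seed: int | np.random.SeedSequence,
                    exchange_matrix: np.ndarray | None = None) -> np.ndarray:
    """Simulate one family's aligned tip sequences (no indels).

    Returns a ``(n_tips, seq_length)`` uint8 array of letters in 0..19, rows
    ordered like ``tree.tip_ids``. The root sequence is uniform over the
    alphabet; each site carries a continuous gamma(alpha_sites) rate shared
    across the whole tree, and each edge of length ``t`` accumulates
    Poisson(t * rate_scalar * site_rate) substitutions.
    """
    rng = np.random.default_rng(seed)
    site_rates = rng.gamma(alpha_sites, 1.0 / alpha_sites, size=seq_length)
    seqs: dict[int, np.ndarray] = {}
    seqs[tree.root] = rng.integers(0, N_LETTERS, size=seq_length,
                                   dtype=np.uint8)
    eig = None
    if exchange_matrix is not None:
        eig = _prepare_exchange(exchange_matrix)
    for v in tree.preorder():
        if v == tree.root:
            continue
        tau = float(tree.branch_length[v]) * rate_scalar * site_rates
        parent_seq = seqs[int(tree.parent[v])]
        if eig is None:
            seqs[v] = _evolve_along_edge(parent_seq, tau, rng)
        else:
            seqs[v] = _evolve_exchange(parent_seq, tau, eig, rng)
    return np.stack([seqs[v] for v in tree.tip_ids])


def _prepare_exchange(q: np.ndarray):
    """Eigendecomposition of a symmetric 20x20 rate matrix, normalized to
    one expected substitution per unit tau."""
    q = np.asarray(q, dtype=float)
    if q.shape != (N_LETTERS, N_LETTERS) or not np.allclose(q, q.T):
        raise ValueError("exchange matrix must be symmetric 20x20")
    q = q.copy()
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -np.mean(np.diag(q))
    q /= rate
    vals, vecs = np.linalg.eigh(q)
    return vals, vecs


def _evolve_exchange(seq, tau, eig, rng):
    vals, vecs = eig
    # P(tau_site) row for the parent letter of each site
    expd = np.exp(vals[None, :] * tau[:, None])           # (L, 20)
    amp = vecs[seq, :]                                    # (L, 20)
    probs = np.einsum("lk,lk,jk->lj", amp, expd, vecs)
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(len(seq))
    return (probs.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(np.uint8)


#: Alphabet used when dumping simulated sequences to FASTA (the 20
#: proteinogenic amino acids, in the order of the integer codes).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def write_family_fasta(seqs: np.ndarray, names: list[str], path) -> None:
    """Dump one family's simulated sequences (integer-coded rows) as FASTA."""
    if seqs.shape[0] != len(names):
        raise ValueError("one name per sequence row required")
    letters = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    with open(path, "w") as fh:
        for name, row in zip(names, seqs):
            fh.write(f">{name}\n")
            fh.write(letters[row].tobytes().decode() + "\n")


# ---------------------------------------------------------------------------
# Similarity clustering
# ---------------------------------------------------------------------------

def pairwise_identity(seqs: np.ndarray) -> np.ndarray:
    """Fraction of identical positions for every pair of aligned rows."""
    eq = seqs[:, None, :] == seqs[None, :, :]
    return eq.mean(axis=2)


def cluster_family(seqs: np.ndarray, threshold: float = IDENTITY_THRESHOLD
                   ) -> tuple[list[list[int]], list[int]]:
    """Single-linkage clustering of aligned sequences at an identity cutoff.

    Sequences are nodes of a graph with an edge wherever pairwise identity
    reaches ``threshold``; connected components of size >= 2 become
    clusters (orthogroups) and isolated sequences become singletons, which
    similarity-based orthology tools exclude from every orthogroup.
    Returns (clusters, singletons) as lists of row indices; every row
    appears exactly once.
    """
    n = seqs.shape[0]
    ident = pairwise_identity(seqs)
    adj = coo_matrix(np.triu(ident >= threshold, k=1))
    n_comp, labels = connected_components(adj, directed=False)
    clusters: list[list[int]] = []
    singletons: list[int] = []
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp).tolist()
        if len(members) >= 2:
            clusters.append(members)
        else:
            singletons.extend(members)
    return clusters, singletons


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions for one batch of synthetic replicates.

    ``rate_scalar`` / ``alpha_sites`` may be fixed; when ``None`` they are
    drawn per replicate, uniformly over the experiment's ranges
    ([0.2, 10] and [0.4, 1.6]). ``paralog_fraction`` is the per-(family,
    species) probability of carrying a recent gene duplicate, the hook that
    produces same-species co-clustering. ``seed`` is mandatory.
    """

    tree: RootedTree
    seed: int
    n_families: int = 5000
    seq_length: int = 200
    rate_scalar: float | None = None
    alpha_sites: float | None = None
    identity_threshold: float = IDENTITY_THRESHOLD
    paralog_fraction: float = 0.05
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name, val, lo, hi in (
                ("rate_scalar", self.rate_scalar, *RATE_SCALAR_RANGE),
                ("alpha_sites", self.alpha_sites, *ALPHA_SITES_RANGE)):
            if val is not None and not lo <= val <= hi:
                raise ValueError(f"{name}={val} outside [{lo}, {hi}]")
        if not 0.0 < self.identity_threshold < 1.0:
            raise ValueError("identity_threshold must lie in (0, 1)")


@dataclass
class TruthRecord:
    """Ground truth of one replicate: which orthogroups and singletons every
    true family produced, plus the replicate-level nuisance parameters.
    The true count at every node of the tree is ``n_families``."""

    n_families: int
    rate_scalar: float | None
    alpha_sites: float | None
    seed: int
    families: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"n_families": self.n_families,
                       "rate_scalar": self.rate_scalar,
                       "alpha_sites": self.alpha_sites,
                       "seed": self.seed,
                       "families": self.families}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _family_seed(seed: int, replicate: int, family: int
                 ) -> np.random.SeedSequence:
    """Counter-based stream splitting: any single family is reproducible in
    isolation from (master seed, replicate index, family index)."""
    return np.random.SeedSequence([seed, replicate, family])


def generate_dataset(config: SimulationConfig, replicate: int = 0
                     ) -> tuple[OrthogroupTable, TruthRecord]:
    """Generate one replicate: simulate every family, cluster it, and book
    the provenance of every produced orthogroup and singleton.

    Slow replicates (rate scalar <= 0.5) are required to be almost fully
    recovered — at least 99% of families must come back as exactly one
    complete cluster — otherwise the identity threshold is miscalibrated
    for the tree and a :class:`CalibrationError` is raised.
    """
    tree = config.tree
    rep_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, replicate, 2 ** 20]))
    rate_scalar = config.rate_scalar if config.rate_scalar is not None \
        else float(rep_rng.uniform(*RATE_SCALAR_RANGE))
    alpha_sites = config.alpha_sites if config.alpha_sites is not None \
        else float(rep_rng.uniform(*ALPHA_SITES_RANGE))

    tip_labels = [tree.labels[v] for v in tree.tip_ids]
    n_tips = len(tip_labels)
    groups: dict[str, dict[str, list[str]]] = {}
    singles: list[tuple[str, str]] = []
    families: dict[str, dict[str, list[str]]] = {}
    n_complete = 0

    for fam in range(config.n_families):
        fam_ss = _family_seed(config.seed, replicate, fam)
        seqs = simulate_family(tree, rate_scalar, alpha_sites,
                               config.seq_length, fam_ss)
        species = list(tip_labels)
        genes = [f"F{fam:05d}_{sp}" for sp in species]
        if config.paralog_fraction > 0:
            dup_rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, replicate, fam, 7]))
            dup_mask = dup_rng.random(n_tips) < config.paralog_fraction
            for i in np.flatnonzero(dup_mask):
                tau = np.full(config.seq_length,
                              PARALOG_DIVERGENCE * rate_scalar)
                dup_seq = _evolve_along_edge(seqs[i], tau, dup_rng)
                seqs = np.vstack([seqs, dup_seq[None, :]])
                species.append(species[i])
                genes.append(f"F{fam:05d}_{species[i]}_d2")

        clusters, singletons = cluster_family(seqs,
                                              config.identity_threshold)
        fam_id = f"F{fam:05d}"
        fam_ogs: list[str] = []
        fam_singles: list[str] = []
        for ci, members in enumerate(clusters):
            og_id = f"OG_{fam_id}_{ci}"
            per_sp: dict[str, list[str]] = {}
            for m in members:
                per_sp.setdefault(species[m], []).append(genes[m])
            groups[og_id] = per_sp
            fam_ogs.append(og_id)
        for m in singletons:
            singles.append((species[m], genes[m]))
            fam_singles.append(genes[m])
        families[fam_id] = {"orthogroups": fam_ogs,
                            "singletons": fam_singles}
        if (len(clusters) == 1 and not singletons
                and set(species[m] for m in clusters[0]) == set(tip_labels)):
            n_complete += 1

    if rate_scalar <= 0.5 and config.n_families > 0:
        frac = n_complete / config.n_families
        if frac < 0.99:
            raise CalibrationError(
                f"only {frac:.1%} of families were recovered as one complete "
                f"cluster at rate scalar {rate_scalar:.2f}; the identity "
                f"threshold {config.identity_threshold} is miscalibrated for "
                "this tree — lower it (or shorten the tree)")

    table = OrthogroupTable(groups, singles)
    truth = TruthRecord(n_families=config.n_families,
                        rate_scalar=rate_scalar, alpha_sites=alpha_sites,
                        seed=config.seed, families=families)
    return table, truth


def generate_replicates(config: SimulationConfig):
    """Yield ``config.n_replicates`` replicates as (table, truth) pairs."""
    for rep in range(config.n_replicates):
        yield generate_dataset(config, replicate=rep)


# ---------------------------------------------------------------------------
# Phenomenological fragmentation (fast, sequence-free)
# ---------------------------------------------------------------------------

def fragment_phenomenological(tree: RootedTree, n_families: int,
                              p_split: float, seed: int
                              ) -> tuple[OrthogroupTable, TruthRecord]:
    """Sequence-free fragmentation: cut each tree edge independently with
    probability ``p_split`` and turn the resulting tip blocks into
    orthogroups (blocks of size >= 2) or singletons (size 1). Reproduces the
    split/singleton structure without simulating sequences; useful where
    the divergence mechanism itself is not under study.
    """
    if not 0.0 <= p_split <= 1.0:
        raise ValueError(f"p_split must lie in [0, 1], got {p_split}")
    rng = np.random.default_rng(seed)
    edges = tree.edges()
    tip_labels = [tree.labels[v] for v in tree.tip_ids]
    groups: dict[str, dict[str, list[str]]] = {}
    singles: list[tuple[str, str]] = []
    families: dict[str, dict[str, list[str]]] = {}
    for fam in range(n_families):
        keep = rng.random(len(edges)) >= p_split
        labels = np.arange(tree.n_nodes)
        for (u, v), k in zip(edges, keep):
            if k:
                ru, rv = labels[u], labels[v]
                labels[labels == rv] = ru
        fam_id = f"F{fam:05d}"
        blocks: dict[int, list[int]] = {}
        for tip in tree.tip_ids:
            blocks.setdefault(int(labels[tip]), []).append(tip)
        fam_ogs: list[str] = []
        fam_singles: list[str] = []
        ci = 0
        for members in blocks.values():
            if len(members) >= 2:
                og_id = f"OG_{fam_id}_{ci}"
                ci += 1
                groups[og_id] = {
                    tree.labels[m]: [f"{fam_id}_{tree.labels[m]}"]
                    for m in members}
                fam_ogs.append(og_id)
            else:
                m = members[0]
                singles.append((tree.labels[m], f"{fam_id}_{tree.labels[m]}"))
                fam_singles.append(f"{fam_id}_{tree.labels[m]}")
        families[fam_id] = {"orthogroups": fam_ogs,
                            "singletons": fam_singles}
    truth = TruthRecord(n_families=n_families, rate_scalar=None,
                        alpha_sites=None, seed=seed, families=families)
    return OrthogroupTable(groups, singles), truth
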