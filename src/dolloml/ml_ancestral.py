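"""Maximum-likelihood marginal ancestral reconstruction of binary characters.

The model is a stationary, time-reversible two-state continuous-time Markov
chain, homogeneous over the tree, with among-character rate variation
modelled by a discretized gamma distribution:

* stationary frequencies are parameterized by ``kappa`` = pi1/pi0, the
  presence/absence frequency ratio (pi0 = 1/(1+kappa), pi1 = kappa/(1+kappa));
* the rate matrix is normalized so that one unit of branch length equals one
  expected state change at relative rate 1, giving the closed-form
  transition probabilities

      P01(tau) = pi1 * (1 - exp(-s * tau)),   s = 1 / (2 * pi0 * pi1),
      P10(tau) = pi0 * (1 - exp(-s * tau)),   tau = r * t;

* ``alpha`` is the gamma shape; rates are discretized into ``n_categories``
  equal-probability categories, each represented by its segment mean.

Likelihoods are computed by Felsenstein pruning over compressed site
patterns, marginal posteriors by the standard up-down (outside) recursion
mixing rate categories by their posterior weights, and free parameters
(kappa, alpha, branch lengths) are fitted by monotone coordinate-wise
bounded scalar maximization of the log-likelihood.

:func:`likelihood_oracle` recomputes likelihood and marginals by exhaustive
enumeration on small trees; it exists solely as an independent check of the
pruning implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from .phylo_io import PresenceMatrix, RootedTree, tip_state_array

logger = logging.getLogger("dolloml")

ORACLE_MAX_INTERNAL = 10

#: optimizer bounds (natural-log scale for kappa/alpha; linear for lengths)
LOG_KAPPA_BOUNDS = (-7.0, 7.0)
LOG_ALPHA_BOUNDS = (-3.0, 5.0)
BRANCH_BOUNDS = (1e-9, 100.0)
FIT_TOL = 1e-6
MAX_SWEEPS = 50


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def stationary_freqs(kappa: float) -> tuple[float, float]:
    """Stationary (pi0, pi1) of the two-state chain with pi1/pi0 = kappa."""
    if not kappa > 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    return 1.0 / (1.0 + kappa), kappa / (1.0 + kappa)


def discretize_gamma(alpha: float, k: int) -> np.ndarray:
    """Mean-one discrete-gamma rates: ``k`` equal-probability categories,
    each represented by the mean of the gamma(alpha, rate alpha) density
    over its quantile segment (computed in closed form via the partial
    expectation of the gamma distribution)."""
    if not alpha > 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if k < 1:
        raise ValueError(f"need at least one category, got {k}")
    if k == 1:
        return np.ones(1)
    probs = np.arange(1, k) / k
    cuts = stats.gamma.ppf(probs, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate(([0.0], cuts, [np.inf]))
    # partial expectation of gamma(a, scale) over [0,x] is mean*F_{a+1}(x)
    upper_cdf = stats.gamma.cdf(bounds[1:], a=alpha + 1.0, scale=1.0 / alpha)
    lower_cdf = stats.gamma.cdf(bounds[:-1], a=alpha + 1.0, scale=1.0 / alpha)
    rates = k * (upper_cdf - lower_cdf)
    return rates / rates.mean()


@dataclass
class BinaryCTMCModel:
    """Two-state CTMC with discrete-gamma among-character rate variation."""

    kappa: float
    alpha: float
    n_categories: int = 4
    rates: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.pi0, self.pi1 = stationary_freqs(self.kappa)
        self.rates = discretize_gamma(self.alpha, self.n_categories)

    @property
    def pi(self) -> np.ndarray:
        return np.array([self.pi0, self.pi1])

    @property
    def scale(self) -> float:
        """Rate-matrix normalization 1/(2*pi0*pi1): one expected change per
        unit branch length at relative rate 1."""
        return 1.0 / (2.0 * self.pi0 * self.pi1)


def transition_probs(model: BinaryCTMCModel, t: float,
                     r: float = 1.0) -> np.ndarray:
    """2x2 transition matrix over a branch of length ``t`` at rate ``r``."""
    if t < 0:
        raise ValueError(f"branch length must be non-negative, got {t}")
    decay = np.exp(-model.scale * r * t)
    p01 = model.pi1 * (1.0 - decay)
    p10 = model.pi0 * (1.0 - decay)
    return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


def _edge_mats(model: BinaryCTMCModel, t: float) -> np.ndarray:
    """(k, 2, 2) transition matrices, one per rate category."""
    decay = np.exp(-model.scale * model.rates * t)  # (k,)
    p01 = model.pi1 * (1.0 - decay)
    p10 = model.pi0 * (1.0 - decay)
    out = np.empty((len(model.rates), 2, 2))
    out[:, 0, 0] = 1.0 - p01
    out[:, 0, 1] = p01
    out[:, 1, 0] = p10
    out[:, 1, 1] = 1.0 - p10
    return out


# ---------------------------------------------------------------------------
# Pattern compression and pruning
# ---------------------------------------------------------------------------

def _compress(tip_states: np.ndarray, tip_ids: list[int]
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique site patterns over the tip rows.

    Returns (patterns (n_tips, P), weights (P,), inverse (C,)) with
    column j of the input equal to pattern ``inverse[j]``.
    """
    cols = tip_states[tip_ids]  # (n_tips, C)
    patterns, inverse, counts = np.unique(
        cols, axis=1, return_inverse=True, return_counts=True)
    return patterns, counts.astype(float), inverse


class _PruningEngine:
    """Shared state for pruning, up-down marginals and branch optimization.

    Down arrays ``D[v][p, k, x]`` hold the probability of the tip data below
    node v given state x at v under category k, rescaled per (node, pattern)
    with the log of the scaling factor accumulated in ``dscale[v][p]``.
    """

    def __init__(self, tree: RootedTree, patterns: np.ndarray,
                 weights: np.ndarray, model: BinaryCTMCModel):
        self.tree = tree
        self.patterns = patterns
        self.weights = weights
        self.n_pat = patterns.shape[1]
        self.set_model(model)
        self.blen = tree.branch_length.copy()
        self._tip_row = {v: i for i, v in enumerate(tree.tip_ids)}

    def set_model(self, model: BinaryCTMCModel) -> None:
        self.model = model
        self.k = model.n_categories

    def _tip_down(self, v: int) -> np.ndarray:
        obs = self.patterns[self._tip_row[v]]  # (P,)
        d = np.zeros((self.n_pat, self.k, 2))
        d[np.arange(self.n_pat), :, obs] = 1.0
        return d

    def edge_mats(self, v: int, t: float | None = None) -> np.ndarray:
        if t is None:
            t = self.blen[v]
        return _edge_mats(self.model, float(t))

    def down_pass(self) -> None:
        """Fill D, dscale, and the per-edge messages M (child -> parent)."""
        tree = self.tree
        n = tree.n_nodes
        self.D: list[np.ndarray | None] = [None] * n
        self.M: list[np.ndarray | None] = [None] * n
        self.dscale = np.zeros((n, self.n_pat))
        for v in tree.postorder():
            if tree.is_tip(v):
                d = self._tip_down(v)
            else:
                d = np.ones((self.n_pat, self.k, 2))
                for c in tree.children[v]:
                    d = d * self.M[c]
                    self.dscale[v] += self.dscale[c]
            m = d.max(axis=(1, 2))
            np.maximum(m, 1e-300, out=m)
            d = d / m[:, None, None]
            with np.errstate(divide="ignore"):
                self.dscale[v] += np.log(m)
            self.D[v] = d
            if v != tree.root:
                self.M[v] = np.einsum("kxy,pky->pkx",
                                      self.edge_mats(v), d)

    def site_log_likelihoods(self) -> np.ndarray:
        """Per-pattern log-likelihood (category-mixed, root prior applied)."""
        root = self.tree.root
        lik = np.einsum("pkx,x->p", self.D[root], self.model.pi) / self.k
        with np.errstate(divide="ignore"):
            return np.log(lik) + self.dscale[root]

    def log_likelihood(self) -> float:
        return float(self.site_log_likelihoods() @ self.weights)

    def up_pass(self) -> None:
        """Fill U[v][p,k,x] = scaled P(data outside subtree(v), state x at v)
        and its log-scale ``uscale``; requires a current down pass."""
        tree = self.tree
        n = tree.n_nodes
        self.U: list[np.ndarray | None] = [None] * n
        self.uscale = np.zeros((n, self.n_pat))
        root = tree.root
        u0 = np.broadcast_to(self.model.pi, (self.n_pat, self.k, 2)).copy()
        self.U[root] = u0
        for v in tree.preorder():
            if tree.is_tip(v):
                continue
            for c in tree.children[v]:
                f = self.U[v].copy()
                fscale = self.uscale[v].copy()
                for w in tree.children[v]:
                    if w != c:
                        f = f * self.M[w]
                        fscale += self.dscale[w]
                u = np.einsum("pkz,kzx->pkx", f, self.edge_mats(c))
                m = u.max(axis=(1, 2))
                np.maximum(m, 1e-300, out=m)
                u = u / m[:, None, None]
                with np.errstate(divide="ignore"):
                    fscale += np.log(m)
                self.U[c] = u
                self.uscale[c] = fscale

    def pattern_posteriors(self) -> np.ndarray:
        """(n_nodes, P) posterior probability of presence per pattern."""
        n = self.tree.n_nodes
        out = np.empty((n, self.n_pat))
        for v in range(n):
            joint = self.U[v] * self.D[v]  # (P, k, 2); scales cancel in ratio
            tot = joint.sum(axis=(1, 2))
            with np.errstate(invalid="ignore", divide="ignore"):
                out[v] = np.where(tot > 0, joint[:, :, 1].sum(axis=1) / tot,
                                  0.0)
        return np.clip(out, 0.0, 1.0)

    # -- branch-length optimization ----------------------------------------

    def _branch_objective(self, f: np.ndarray, dv: np.ndarray,
                          t: float) -> float:
        mats = _edge_mats(self.model, t)
        lik = np.einsum("pkz,kzx,pkx->p", f, mats, dv) / self.k
        with np.errstate(divide="ignore"):
            return float(np.log(np.maximum(lik, 1e-300)) @ self.weights)

    def optimize_branches(self) -> None:
        """One monotone pre-order sweep of per-branch Brent maximization.

        For each edge (v -> c) the likelihood as a function of the single
        branch length factorizes as sum_z F(z) * sum_x P_t(z,x) * D_c(x),
        where F combines the up message at v with the sibling messages; the
        scale terms are constant in t and dropped. Requires fresh down and
        up passes; messages and up arrays are updated in place so every
        1-D maximization sees the latest values of all other branches.
        """
        tree = self.tree
        for v in tree.preorder():
            if tree.is_tip(v):
                continue
            for c in tree.children[v]:
                f = self.U[v].copy()
                fscale = self.uscale[v].copy()
                for w in tree.children[v]:
                    if w != c:
                        f = f * self.M[w]
                        fscale += self.dscale[w]
                dv = self.D[c]
                cur = self._branch_objective(f, dv, float(self.blen[c]))
                res = minimize_scalar(
                    lambda lt: -self._branch_objective(f, dv, np.exp(lt)),
                    bounds=np.log(BRANCH_BOUNDS), method="bounded",
                    options={"xatol": 1e-8})
                if -res.fun > cur:
                    self.blen[c] = float(np.exp(res.x))
                # refresh the message and the child's up array
                self.M[c] = np.einsum("kxy,pky->pkx",
                                      self.edge_mats(c), self.D[c])
                u = np.einsum("pkz,kzx->pkx", f, self.edge_mats(c))
                m = u.max(axis=(1, 2))
                np.maximum(m, 1e-300, out=m)
                self.U[c] = u / m[:, None, None]
                with np.errstate(divide="ignore"):
                    self.uscale[c] = fscale + np.log(m)


def _make_engine(tree: RootedTree, matrix: PresenceMatrix,
                 model: BinaryCTMCModel
                 ) -> tuple[_PruningEngine, np.ndarray]:
    if np.isnan(tree.branch_length[np.arange(tree.n_nodes) != tree.root]).any():
        raise ValueError("likelihood computation requires branch lengths "
                         "on every non-root edge")
    tips = tip_state_array(tree, matrix)
    patterns, weights, inverse = _compress(tips, tree.tip_ids)
    return _PruningEngine(tree, patterns, weights, model), inverse


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def log_likelihood(tree: RootedTree, matrix: PresenceMatrix,
                   model: BinaryCTMCModel) -> float:
    """Total log-likelihood of the matrix by Felsenstein pruning, averaging
    the gamma categories with equal prior weight and applying the
    stationary root prior."""
    if matrix.n_characters == 0:
        return 0.0
    engine, _ = _make_engine(tree, matrix, model)
    engine.down_pass()
    return engine.log_likelihood()


@dataclass
class PosteriorMatrix:
    """Marginal posterior probability of presence, per node per character."""

    probs: np.ndarray  # (n_nodes, n_characters)
    characters: list[str]

    @property
    def n_nodes(self) -> int:
        return self.probs.shape[0]


def marginal_posteriors(tree: RootedTree, matrix: PresenceMatrix,
                        model: BinaryCTMCModel) -> PosteriorMatrix:
    """Per-node marginal posterior of presence for every character,
    computed by the up-down algorithm with categories mixed by their
    posterior weights. Tip posteriors equal the observed states."""
    engine, inverse = _make_engine(tree, matrix, model)
    engine.down_pass()
    engine.up_pass()
    pat_post = engine.pattern_posteriors()
    return PosteriorMatrix(pat_post[:, inverse], list(matrix.characters))


def likelihood_oracle(tree: RootedTree,
                      character: dict[str, int] | np.ndarray,
                      model: BinaryCTMCModel
                      ) -> tuple[float, np.ndarray]:
    """Exhaustive-likelihood check: sums over every internal-state
    assignment and every rate category; marginals by conditioning.
    Returns (likelihood, per-node P(presence)). Small trees only."""
    from itertools import product

    internal = tree.internal_ids
    if len(internal) > ORACLE_MAX_INTERNAL:
        raise ValueError(
            f"tree has {len(internal)} internal nodes; oracle enumerates "
            f"at most {ORACLE_MAX_INTERNAL}")
    tip_of = tree.tip_index()
    assign = np.zeros(tree.n_nodes, dtype=int)
    if isinstance(character, dict):
        for lab, s in character.items():
            assign[tip_of[lab]] = s
    else:
        for i, v in enumerate(tree.tip_ids):
            assign[v] = np.asarray(character)[i]

    mats = {v: [transition_probs(model, float(tree.branch_length[v]), r)
                for r in model.rates] for v in range(tree.n_nodes)
            if v != tree.root}
    total = 0.0
    present_mass = np.zeros(tree.n_nodes)
    k = model.n_categories
    for combo in product((0, 1), repeat=len(internal)):
        for v, s in zip(internal, combo):
            assign[v] = s
        for ki in range(k):
            w = model.pi[assign[tree.root]] / k
            for u, v in tree.edges():
                w *= mats[v][ki][assign[u], assign[v]]
            total += w
            present_mass += w * assign
    return total, present_mass / total


@dataclass
class FitResult:
    model: BinaryCTMCModel
    tree: RootedTree
    log_likelihood: float
    n_sweeps: int


def fit_model(tree: RootedTree, matrix: PresenceMatrix,
              free: tuple[str, ...] = ("kappa", "alpha"),
              init: BinaryCTMCModel | None = None,
              n_categories: int = 4,
              tol: float = FIT_TOL,
              max_sweeps: int = MAX_SWEEPS) -> FitResult:
    """Maximize the log-likelihood over any subset of {kappa, alpha,
    branch_lengths} by coordinate-wise bounded scalar optimization.

    Initialization is deterministic (kappa = 1, alpha = 1, input branch
    lengths) unless ``init`` is given. Sweeps of coordinate updates repeat
    until the log-likelihood improves by less than ``tol``. The final
    log-likelihood never falls below the initial one.
    """
    bad = set(free) - {"kappa", "alpha", "branch_lengths"}
    if bad:
        raise ValueError(f"unknown free parameters: {sorted(bad)}")
    model = init if init is not None else BinaryCTMCModel(
        kappa=1.0, alpha=1.0, n_categories=n_categories)
    free = tuple(free)
    variable = ((matrix.data.min(axis=0) != matrix.data.max(axis=0)).any()
                if matrix.n_characters else False)
    if "branch_lengths" in free and not variable:
        logger.warning("matrix has no variable character; the likelihood is "
                       "flat in branch lengths, keeping input lengths")
        free = tuple(p for p in free if p != "branch_lengths")

    engine, _ = _make_engine(tree, matrix, model)
    engine.down_pass()
    cur = engine.log_likelihood()

    def eval_model(m: BinaryCTMCModel) -> float:
        engine.set_model(m)
        engine.down_pass()
        return engine.log_likelihood()

    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        before = cur
        if "kappa" in free:
            res = minimize_scalar(
                lambda lk: -eval_model(replace(model, kappa=float(np.exp(lk)))),
                bounds=LOG_KAPPA_BOUNDS, method="bounded",
                options={"xatol": 1e-7})
            cand = replace(model, kappa=float(np.exp(res.x)))
            if -res.fun > cur:
                model, cur = cand, -res.fun
        if "alpha" in free:
            res = minimize_scalar(
                lambda la: -eval_model(replace(model, alpha=float(np.exp(la)))),
                bounds=LOG_ALPHA_BOUNDS, method="bounded",
                options={"xatol": 1e-7})
            cand = replace(model, alpha=float(np.exp(res.x)))
            if -res.fun > cur:
                model, cur = cand, -res.fun
        engine.set_model(model)
        engine.down_pass()
        if "branch_lengths" in free:
            engine.up_pass()
            engine.optimize_branches()
            engine.down_pass()
        cur = engine.log_likelihood()
        if cur - before < tol:
            break

    fitted_tree = tree.copy()
    fitted_tree.branch_length = engine.blen.copy()
    return FitResult(model=model, tree=fitted_tree, log_likelihood=cur,
                     n_sweeps=sweeps)


# ---------------------------------------------------------------------------
# Simulation under the model (for parameter-recovery checks)
# ---------------------------------------------------------------------------

def simulate_binary_characters(tree: RootedTree, model: BinaryCTMCModel,
                               n_characters: int, seed: int,
                               rate_mode: str = "discrete") -> PresenceMatrix:
    """Simulate ``n_characters`` independent binary characters down the tree.

    Root states are drawn from the stationary distribution; each character
    carries a rate drawn either from the model's discrete categories
    (``rate_mode="discrete"``, matching the fitted model class exactly) or
    from the continuous gamma(alpha, rate alpha) distribution.
    """
    rng = np.random.default_rng(seed)
    if rate_mode == "discrete":
        rates = rng.choice(model.rates, size=n_characters)
    elif rate_mode == "continuous":
        rates = rng.gamma(model.alpha, 1.0 / model.alpha, size=n_characters)
    else:
        raise ValueError(f"unknown rate_mode {rate_mode!r}")
    states = np.zeros((tree.n_nodes, n_characters), dtype=np.uint8)
    states[tree.root] = rng.random(n_characters) < model.pi1
    for v in tree.preorder():
        if v == tree.root:
            continue
        t = float(tree.branch_length[v])
        decay = np.exp(-model.scale * rates * t)
        p01 = model.pi1 * (1.0 - decay)
        p11 = 1.0 - model.pi0 * (1.0 - decay)
        parent_state = states[int(tree.parent[v])]
        p_present = np.where(parent_state == 1, p11, p01)
        states[v] = rng.random(n_characters) < p_present
    tips = states[tree.tip_ids]
    chars = [f"char{j}" for j in range(n_characters)]
    return PresenceMatrix(list(tree.tip_labels), chars, tips)
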