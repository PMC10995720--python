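"""Trees, binary presence/absence matrices, and orthogroup tables.

This module holds the lightweight containers the reconstruction engines
operate on, plus readers/writers for the on-disk formats used around them:

* Newick for rooted phylogenies (parsing delegated to :mod:`dendropy`),
* the PHYLIP "discrete characters" dialect (sequential records, names padded
  to exactly 10 characters) that PHYLIP Dollop consumes,
* plain TSV for matrices and OrthoFinder-style orthogroup tables.

Node ids of a :class:`RootedTree` are assigned in deterministic post-order,
so the same Newick string always yields the same numbering and downstream
outputs are reproducible across runs.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("dolloml")

#: Branch length given to edges created by random polytomy resolution.
#: Small enough to leave ML transition matrices effectively the identity on
#: the new edges; Dollo parsimony ignores branch lengths entirely.
EPSILON_BRANCH = 1e-6

#: Branch length substituted for edges whose Newick string carries none.
DEFAULT_BRANCH = 1.0

PHYLIP_NAME_WIDTH = 10


# ---------------------------------------------------------------------------
# RootedTree
# ---------------------------------------------------------------------------

@dataclass
class RootedTree:
    """Rooted phylogeny stored as flat arrays indexed by post-order node id.

    Attributes
    ----------
    parent : (n,) int array; ``-1`` for the root.
    children : per-node list of child ids, in parse order.
    branch_length : (n,) float array of lengths of the edge *above* each
        node, in expected substitutions per site; ``nan`` for the root.
    labels : per-node label; every tip has one, internal labels optional.
    root : id of the root node (always ``n - 1`` in post-order numbering).
    """

    parent: np.ndarray
    children: list[list[int]]
    branch_length: np.ndarray
    labels: list[str | None]
    root: int

    def __post_init__(self) -> None:
        n = len(self.parent)
        if (self.parent == -1).sum() != 1:
            raise ValueError("tree must have exactly one root")
        tips = [self.labels[v] for v in range(n) if not self.children[v]]
        if any(lab is None for lab in tips):
            raise ValueError("every tip must carry a label")
        if len(set(tips)) != len(tips):
            dups = sorted({t for t in tips if tips.count(t) > 1})
            raise ValueError(f"duplicate tip labels: {dups}")
        with np.errstate(invalid="ignore"):
            if np.any(self.branch_length[np.arange(n) != self.root] < 0):
                raise ValueError("branch lengths must be non-negative")

    # -- basic queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_tip(self, v: int) -> bool:
        return not self.children[v]

    @property
    def tip_ids(self) -> list[int]:
        return [v for v in range(self.n_nodes) if not self.children[v]]

    @property
    def internal_ids(self) -> list[int]:
        return [v for v in range(self.n_nodes) if self.children[v]]

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[v] for v in self.tip_ids]  # type: ignore[misc]

    def tip_index(self) -> dict[str, int]:
        """Map tip label -> node id."""
        return {self.labels[v]: v for v in self.tip_ids}  # type: ignore[misc]

    def postorder(self) -> list[int]:
        """Node ids, children before parents (ids are already post-order)."""
        return list(range(self.n_nodes))

    def preorder(self) -> list[int]:
        return list(range(self.n_nodes - 1, -1, -1))

    def edges(self) -> list[tuple[int, int]]:
        """(parent, child) pairs for every non-root node."""
        return [(int(self.parent[v]), v)
                for v in range(self.n_nodes) if v != self.root]

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def copy(self) -> "RootedTree":
        return RootedTree(self.parent.copy(),
                          [list(c) for c in self.children],
                          self.branch_length.copy(),
                          list(self.labels), self.root)

    def subtree_tips(self) -> list[set[str]]:
        """Per node, the set of tip labels in its subtree."""
        out: list[set[str]] = [set() for _ in range(self.n_nodes)]
        for v in self.postorder():
            if self.is_tip(v):
                out[v] = {self.labels[v]}  # type: ignore[arg-type]
            else:
                for c in self.children[v]:
                    out[v] |= out[c]
        return out


def _canonicalize(parent: list[int], children: list[list[int]],
                  blen: list[float], labels: list[str | None],
                  root: int) -> RootedTree:
    """Renumber an arbitrary node labelling into post-order ids."""
    order: list[int] = []
    stack = [(root, False)]
    while stack:
        v, expanded = stack.pop()
        if expanded:
            order.append(v)
        else:
            stack.append((v, True))
            for c in reversed(children[v]):
                stack.append((c, False))
    new_id = {old: i for i, old in enumerate(order)}
    n = len(order)
    p = np.full(n, -1, dtype=np.int64)
    ch: list[list[int]] = [[] for _ in range(n)]
    bl = np.full(n, np.nan)
    lab: list[str | None] = [None] * n
    for old, new in new_id.items():
        if parent[old] != -1:
            p[new] = new_id[parent[old]]
        ch[new] = [new_id[c] for c in children[old]]
        bl[new] = blen[old]
        lab[new] = labels[old]
    return RootedTree(p, ch, bl, lab, new_id[root])


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> RootedTree:
    """Parse a (rooted) Newick string into a :class:`RootedTree`.

    Edges without an explicit length receive :data:`DEFAULT_BRANCH` (1.0)
    and a warning is logged: Dollo parsimony never reads lengths, but the
    likelihood engine requires them.
    """
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several tokenizer errors
        raise ValueError(f"Newick parse error: {exc}") from exc

    nodes = list(dtree.preorder_node_iter())
    idx = {id(nd): i for i, nd in enumerate(nodes)}
    parent = [-1] * len(nodes)
    children: list[list[int]] = [[] for _ in nodes]
    blen = [float("nan")] * len(nodes)
    labels: list[str | None] = [None] * len(nodes)
    n_missing = 0
    for nd in nodes:
        i = idx[id(nd)]
        if nd.parent_node is not None:
            parent[i] = idx[id(nd.parent_node)]
            children[parent[i]].append(i)
            if nd.edge.length is None:
                blen[i] = DEFAULT_BRANCH
                n_missing += 1
            else:
                blen[i] = float(nd.edge.length)
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label is not None:
            labels[i] = nd.label
    if n_missing:
        logger.warning("%d edge(s) had no branch length; defaulting to %g",
                       n_missing, DEFAULT_BRANCH)
    root = idx[id(dtree.seed_node)]
    return _canonicalize(parent, children, blen, labels, root)


def read_newick(path) -> RootedTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: RootedTree, path=None, *,
                 include_lengths: bool = True) -> str:
    """Serialize to Newick; returns the string and optionally writes it."""
    def render(v: int) -> str:
        if tree.is_tip(v):
            s = tree.labels[v] or ""
        else:
            s = "(" + ",".join(render(c) for c in tree.children[v]) + ")"
            if tree.labels[v]:
                s += tree.labels[v]
        if include_lengths and v != tree.root:
            s += f":{tree.branch_length[v]:.10g}"
        return s

    out = render(tree.root) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(out + "\n")
    return out


# ---------------------------------------------------------------------------
# Tree utilities
# ---------------------------------------------------------------------------

def resolve_polytomies(tree: RootedTree, seed: int) -> RootedTree:
    """Randomly resolve multifurcations into bifurcations (multi2di-style).

    While a node has more than two children, two of them are picked at
    random and joined under a fresh internal node attached by an edge of
    length :data:`EPSILON_BRANCH`. Deterministic given ``seed``; a tree that
    is already binary is returned unchanged (as a copy).
    """
    if tree.is_binary():
        return tree.copy()
    rng = np.random.default_rng(seed)
    parent = list(tree.parent)
    children = [list(c) for c in tree.children]
    blen = list(tree.branch_length)
    labels = list(tree.labels)
    for v in list(range(tree.n_nodes)):
        while len(children[v]) > 2:
            i, j = sorted(rng.choice(len(children[v]), size=2, replace=False))
            a, b = children[v][i], children[v][j]
            new = len(parent)
            parent.append(v)
            children.append([a, b])
            blen.append(EPSILON_BRANCH)
            labels.append(None)
            parent[a] = parent[b] = new
            children[v] = [c for c in children[v] if c not in (a, b)]
            children[v].append(new)
    root = int(np.flatnonzero(np.asarray(parent) == -1)[0])
    return _canonicalize(parent, children, blen, labels, root)


def node_depth(tree: RootedTree) -> dict[int, int]:
    """Number of internal nodes strictly between each node and the root.

    The root and its direct children are at depth 0; each further internal
    node on the path adds 1. This is the "proximity to the root" used to
    order nodes when summarizing where reconstruction errors concentrate.
    """
    depth: dict[int, int] = {tree.root: 0}
    for v in tree.preorder():
        if v == tree.root:
            continue
        p = int(tree.parent[v])
        depth[v] = 0 if p == tree.root else depth[p] + 1
    return depth


# ---------------------------------------------------------------------------
# PresenceMatrix
# ---------------------------------------------------------------------------

@dataclass
class PresenceMatrix:
    """Taxa x characters binary matrix.

    ``data`` is a ``uint8`` array of shape ``(len(taxa), len(characters))``
    with every cell 0 or 1.
    """

    taxa: list[str]
    characters: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.shape != (len(self.taxa), len(self.characters)):
            raise ValueError(
                f"matrix shape {self.data.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.characters)} characters")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxa names must be unique")
        if self.data.size and not np.isin(self.data, (0, 1)).all():
            raise ValueError("matrix cells must be 0 or 1")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.taxa,
                            columns=self.characters)

    def __eq__(self, other) -> bool:  # type: ignore[override]
        return (isinstance(other, PresenceMatrix)
                and self.taxa == other.taxa
                and self.characters == other.characters
                and np.array_equal(self.data, other.data))


def read_matrix_tsv(path) -> PresenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    data = df.to_numpy(dtype=np.uint8)
    return PresenceMatrix(list(df.index.astype(str)),
                          list(df.columns.astype(str)), data)


def write_matrix_tsv(matrix: PresenceMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def _phylip_name(name: str) -> str:
    return name[:PHYLIP_NAME_WIDTH].ljust(PHYLIP_NAME_WIDTH)


def write_phylip_discrete(matrix: PresenceMatrix, path) -> None:
    """Write the sequential PHYLIP discrete-characters dialect.

    Names are truncated/padded to exactly 10 characters, the convention the
    Dollop toolchain expects; truncation collisions are an error because the
    file could not be read back unambiguously.
    """
    truncated = [_phylip_name(t).rstrip() for t in matrix.taxa]
    if len(set(truncated)) != len(truncated):
        coll = sorted({t for t in truncated if truncated.count(t) > 1})
        full = [t for t in matrix.taxa if _phylip_name(t).rstrip() in coll]
        raise ValueError(
            f"taxon names collide after 10-character truncation: {full}")
    buf = io.StringIO()
    buf.write(f"{matrix.n_taxa} {matrix.n_characters}\n")
    for i, taxon in enumerate(matrix.taxa):
        row = "".join(str(int(x)) for x in matrix.data[i])
        buf.write(_phylip_name(taxon) + row + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_phylip_discrete(path) -> PresenceMatrix:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError("empty PHYLIP file")
    try:
        ntax, nchar = (int(x) for x in lines[0].split()[:2])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"bad PHYLIP header line: {lines[0]!r}") from exc
    taxa: list[str] = []
    rows: list[list[int]] = []
    li = 1
    for _ in range(ntax):
        while li < len(lines) and not lines[li].strip():
            li += 1
        if li >= len(lines):
            raise ValueError(f"expected {ntax} records, found {len(taxa)}")
        line = lines[li]
        li += 1
        name = line[:PHYLIP_NAME_WIDTH].rstrip()
        states = [c for c in line[PHYLIP_NAME_WIDTH:] if not c.isspace()]
        while len(states) < nchar and li < len(lines):
            states.extend(c for c in lines[li] if not c.isspace())
            li += 1
        if len(states) != nchar:
            raise ValueError(
                f"taxon {name!r}: expected {nchar} characters, "
                f"got {len(states)}")
        bad = sorted(set(states) - {"0", "1"})
        if bad:
            raise ValueError(f"taxon {name!r}: non-binary states {bad}")
        taxa.append(name)
        rows.append([int(c) for c in states])
    if len(taxa) != len(set(taxa)):
        dups = sorted({t for t in taxa if taxa.count(t) > 1})
        raise ValueError(f"duplicate taxon names: {dups}")
    chars = [f"c{j}" for j in range(nchar)]
    return PresenceMatrix(taxa, chars, np.array(rows, dtype=np.uint8))


# ---------------------------------------------------------------------------
# Orthogroup tables
# ---------------------------------------------------------------------------

@dataclass
class OrthogroupTable:
    """OrthoFinder-style clustering output.

    ``groups`` maps orthogroup id -> species -> list of gene ids (species
    with no member may be absent or map to an empty list). ``singletons``
    lists (species, gene) pairs excluded from every orthogroup — exactly the
    genes a similarity clusterer failed to place.
    """

    groups: dict[str, dict[str, list[str]]]
    singletons: list[tuple[str, str]] = field(default_factory=list)

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for og, per_sp in self.groups.items():
            for sp, genes in per_sp.items():
                for g in genes:
                    key = (sp, g)
                    if key in seen:
                        raise ValueError(
                            f"gene {g!r} of {sp!r} appears more than once")
                    seen.add(key)
        for sp, g in self.singletons:
            if (sp, g) in seen:
                raise ValueError(
                    f"singleton {g!r} of {sp!r} also appears in an orthogroup")
            seen.add((sp, g))

    @property
    def species(self) -> list[str]:
        out: set[str] = set()
        for per_sp in self.groups.values():
            out.update(sp for sp, genes in per_sp.items() if genes)
        out.update(sp for sp, _ in self.singletons)
        return sorted(out)


def tip_state_array(tree: RootedTree, matrix: PresenceMatrix) -> np.ndarray:
    """(n_nodes, n_chars) uint8 array with tip rows filled, internals zero.

    Raises if the matrix taxa and the tree tips differ, listing the
    symmetric difference.
    """
    tree_tips = set(tree.tip_labels)
    mat_taxa = set(matrix.taxa)
    if tree_tips != mat_taxa:
        only_tree = sorted(tree_tips - mat_taxa)
        only_mat = sorted(mat_taxa - tree_tips)
        raise ValueError(
            "matrix taxa do not match tree tips; "
            f"only in tree: {only_tree}; only in matrix: {only_mat}")
    out = np.zeros((tree.n_nodes, matrix.n_characters), dtype=np.uint8)
    row = {t: i for i, t in enumerate(matrix.taxa)}
    for v in tree.tip_ids:
        out[v] = matrix.data[row[tree.labels[v]]]
    return out


def orthogroups_to_matrix(table: OrthogroupTable,
                          species: list[str]) -> PresenceMatrix:
    """Score each orthogroup in each species as present (1) or absent (0).

    A species with several genes in one orthogroup still scores a single 1;
    singletons contribute no column and no presence.
    """
    ogs = list(table.groups)
    data = np.zeros((len(species), len(ogs)), dtype=np.uint8)
    sp_idx = {s: i for i, s in enumerate(species)}
    for j, og in enumerate(ogs):
        for sp, genes in table.groups[og].items():
            if genes:
                if sp not in sp_idx:
                    raise ValueError(
                        f"species {sp!r} in table but not in species list")
                data[sp_idx[sp], j] = 1
    return PresenceMatrix(list(species), ogs, data)


def write_orthogroups_tsv(table: OrthogroupTable, groups_path,
                          singletons_path=None,
                          species: list[str] | None = None) -> None:
    """Write orthogroups (one row per group, one column per species,
    comma-separated gene ids) plus an optional two-column singleton TSV."""
    sp = species if species is not None else table.species
    with open(groups_path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(sp) + "\n")
        for og, per_sp in table.groups.items():
            cells = [",".join(per_sp.get(s, [])) for s in sp]
            fh.write(og + "\t" + "\t".join(cells) + "\n")
    if singletons_path is not None:
        with open(singletons_path, "w") as fh:
            fh.write("species\tgene\n")
            for s, g in table.singletons:
                fh.write(f"{s}\t{g}\n")


def read_orthogroups_tsv(groups_path, singletons_path=None) -> OrthogroupTable:
    df = pd.read_csv(groups_path, sep="\t", index_col=0, dtype=str)
    groups: dict[str, dict[str, list[str]]] = {}
    for og, row in df.iterrows():
        per_sp: dict[str, list[str]] = {}
        for sp, cell in row.items():
            if isinstance(cell, str) and cell:
                per_sp[str(sp)] = cell.split(",")
        groups[str(og)] = per_sp
    singles: list[tuple[str, str]] = []
    if singletons_path is not None:
        sdf = pd.read_csv(singletons_path, sep="\t", dtype=str)
        singles = [(r.species, r.gene) for r in sdf.itertuples()]
    return OrthogroupTable(groups, singles)
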