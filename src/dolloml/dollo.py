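"""Dollo parsimony ancestral reconstruction of binary characters.

Under Dollo's criterion a character (here: an orthogroup or protein domain)
may be gained exactly once on the tree, and lost as many times as the data
require; the reconstruction minimizes the number of losses subject to that
single-gain constraint. Absence is taken as the ancestral condition, so the
gain is placed at the most recent common ancestor (MRCA) of the tips that
carry the character, and every node below the MRCA whose subtree still
contains a carrier is reconstructed as present. A character found on both
sides of the root is therefore gained "at" the root itself.

:func:`dollo_oracle` re-derives the same answer by exhaustive enumeration on
small trees and exists purely as an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .phylo_io import PresenceMatrix, RootedTree, tip_state_array

#: Largest number of internal nodes the exhaustive oracle will enumerate.
ORACLE_MAX_INTERNAL = 12


@dataclass
class DolloStates:
    """Dollo reconstruction for every character of a matrix.

    Attributes
    ----------
    states : (n_nodes, n_characters) uint8 array of presence states.
    origin : (n_characters,) int array; node id of the single gain, or -1
        for characters absent from every tip.
    characters : character labels, aligned with the matrix columns.
    """

    states: np.ndarray
    origin: np.ndarray
    characters: list[str]


def reconstruct_dollo(tree: RootedTree, matrix: PresenceMatrix) -> DolloStates:
    """Minimum-loss single-gain reconstruction of every character.

    For each character the origin is the MRCA of its carrier tips; an
    internal node is present iff it lies in the origin's subtree and its own
    subtree contains at least one carrier. Branch lengths play no role.
    """
    tip_states = tip_state_array(tree, matrix)
    n, c = tip_states.shape

    # carriers-in-subtree counts by post-order accumulation
    count1 = tip_states.astype(np.int64)
    for v in tree.postorder():
        p = int(tree.parent[v])
        if p != -1:
            count1[p] += count1[v]
    total1 = count1[tree.root]

    # post-order ids increase from descendants to ancestors, so the first
    # node whose subtree holds every carrier is the MRCA
    full = count1 == total1[None, :]
    origin = np.where(total1 > 0, np.argmax(full, axis=0), -1)

    node_ids = np.arange(n)[:, None]
    states = ((count1 >= 1) & (~full | (node_ids == origin[None, :])))
    return DolloStates(states.astype(np.uint8), origin.astype(np.int64),
                       list(matrix.characters))


def loss_count(tree: RootedTree, states: DolloStates) -> np.ndarray:
    """Per-character number of 1->0 edges in a reconstruction."""
    losses = np.zeros(len(states.characters), dtype=np.int64)
    for u, v in tree.edges():
        losses += (states.states[u] == 1) & (states.states[v] == 0)
    return losses


def dollo_oracle(tree: RootedTree,
                 character: dict[str, int] | np.ndarray
                 ) -> tuple[int, list[np.ndarray]]:
    """Exhaustive minimum-loss single-gain search for one character.

    Enumerates every assignment of {0,1} to the internal nodes, keeps those
    with at most one 0->1 transition (a present root counts as the gain),
    and returns the minimal number of 1->0 edges together with every
    assignment attaining it. Only feasible on small trees; trees with more
    than ``ORACLE_MAX_INTERNAL`` internal nodes are rejected.
    """
    internal = tree.internal_ids
    if len(internal) > ORACLE_MAX_INTERNAL:
        raise ValueError(
            f"tree has {len(internal)} internal nodes; oracle enumerates "
            f"at most {ORACLE_MAX_INTERNAL}")
    tip_of = tree.tip_index()
    full = np.zeros(tree.n_nodes, dtype=np.uint8)
    if isinstance(character, dict):
        for lab, s in character.items():
            full[tip_of[lab]] = s
    else:
        character = np.asarray(character)
        for i, v in enumerate(tree.tip_ids):
            full[v] = character[i]

    best = None
    argmin: list[np.ndarray] = []
    edges = tree.edges()
    for combo in product((0, 1), repeat=len(internal)):
        assign = full.copy()
        for v, s in zip(internal, combo):
            assign[v] = s
        gains = int(assign[tree.root] == 1)
        losses = 0
        for u, v in edges:
            if assign[u] == 0 and assign[v] == 1:
                gains += 1
            elif assign[u] == 1 and assign[v] == 0:
                losses += 1
        if gains > 1:
            continue
        if best is None or losses < best:
            best = losses
            argmin = [assign.copy()]
        elif losses == best:
            argmin.append(assign.copy())
    assert best is not None  # all-zero internals is always feasible
    return best, argmin
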