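"""Independent brute-force oracles for the Mk likelihood and marginals.

These enumerate every assignment of states to internal nodes and sum the
joint probabilities directly — exponential in the number of internal nodes
and therefore only usable on tiny trees, but entirely independent of the
pruning/two-pass implementation they are used to check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.linalg import expm


def _structure(tree):
    """(nodes postorder, parent index, branch length, leaf label) arrays."""
    nodes = list(tree.postorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    parent = [None] * len(nodes)
    blen = [0.0] * len(nodes)
    label = [n.taxon.label if n.is_leaf() else None for n in nodes]
    for n in nodes:
        for c in n.child_nodes():
            parent[index[id(c)]] = index[id(n)]
            blen[index[id(c)]] = c.edge.length or 0.0
    return nodes, parent, blen, label


def enumeration_joint(tree, tip_states, Q, prior):
    """Sum joint probabilities over all internal-state assignments.

    Returns (likelihood, per-node state accumulators) where the
    accumulators give the unnormalised marginal distribution at every node
    (tips included; observed tips are degenerate by construction). All tips
    must have observed states.
    """
    nodes, parent, blen, label = _structure(tree)
    n = len(nodes)
    k = Q.shape[0]
    P = [expm(Q * t) for t in blen]
    internal = [i for i in range(n) if label[i] is None]
    root = n - 1
    acc = np.zeros((n, k))
    total = 0.0
    fixed = {i: int(tip_states[label[i]]) for i in range(n) if label[i] is not None}
    for assignment in itertools.product(range(k), repeat=len(internal)):
        state = dict(fixed)
        state.update(zip(internal, assignment))
        p = prior[state[root]]
        for i in range(n):
            if parent[i] is not None:
                p *= P[i][state[parent[i]], state[i]]
        total += p
        for i in range(n):
            acc[i, state[i]] += p
    return total, {i: acc[i] for i in range(n)}


def enumeration_loglik(tree, tip_states, Q, prior) -> float:
    total, _ = enumeration_joint(tree, tip_states, Q, prior)
    return math.log(total) if total > 0 else float("-inf")


def enumeration_marginals(tree, tip_states, Q, prior):
    """Normalised marginal state distributions keyed by descendant leaf set."""
    nodes, _, _, _ = _structure(tree)
    total, acc = enumeration_joint(tree, tip_states, Q, prior)
    out = {}
    for i, node in enumerate(nodes):
        leafset = frozenset(l.taxon.label for l in node.leaf_iter())
        out[leafset] = acc[i] / total
    return out


def random_mk_instance(rng, max_tips=6):
    """A random small tree + tip states + Q + flat prior for oracle checks."""
    from klebkit.acsr import _q_matrix
    from klebkit.simulate import sim_tree

    n_tips = int(rng.integers(4, max_tips + 1))
    k = int(rng.integers(2, 5))
    tree = sim_tree(n_tips, seed=int(rng.integers(2**31)), depth=float(rng.uniform(0.3, 2.0)))
    scheme = rng.choice(["ER", "SYM", "ARD"])
    from klebkit.acsr import n_free_rates

    theta = rng.uniform(0.1, 2.0, size=n_free_rates(scheme, k))
    Q = _q_matrix(k, scheme, theta, 2.0, "01")
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    tip_states = {lbl: int(rng.integers(k)) for lbl in labels}
    prior = np.full(k, 1.0 / k)
    return tree, tip_states, Q, prior, k, scheme, theta
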