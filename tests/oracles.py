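"""Independent brute-force oracles used to certify the production code paths.

Everything here deliberately avoids the package's own algorithms: tree
likelihoods and posteriors are computed by enumerating all internal-state
assignments, and the competitive equilibrium by damped fixed-point
iteration.  Slow but transparently correct on small instances.
"""

from __future__ import annotations

import itertools

import numpy as np

from paleoaffinity.alignment import is_missing
from paleoaffinity.substitution import AA_INDEX


def _tree_arrays(tree, model):
    """Flatten a dendropy tree into parent pointers and transition matrices."""
    nodes = list(tree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    parents = [index[id(n.parent_node)] if n.parent_node else -1 for n in nodes]
    P = [
        model.transition_matrix(n.edge.length or 0.0) if n.parent_node else None
        for n in nodes
    ]
    return nodes, parents, P


def _leaf_state_sets(nodes, seqs, site):
    """Allowed states per node at one site: fixed for leaves, all 20 internal."""
    allowed = []
    for n in nodes:
        if n.is_leaf():
            label = n.taxon.label if n.taxon else n.label
            c = seqs[label][site]
            allowed.append(list(range(20)) if is_missing(c) else [AA_INDEX[c]])
        else:
            allowed.append(list(range(20)))
    return allowed


def enumerate_site_likelihood(tree, model, seqs, site):
    """P(site data) by summing over every assignment of internal states."""
    nodes, parents, P = _tree_arrays(tree, model)
    allowed = _leaf_state_sets(nodes, seqs, site)
    total = 0.0
    for assignment in itertools.product(*allowed):
        p = model.pi[assignment[0]]
        for i in range(1, len(nodes)):
            p *= P[i][assignment[parents[i]], assignment[i]]
        total += p
    return total


def enumerate_log_likelihood(tree, model, seqs, n_sites):
    return float(
        sum(np.log(enumerate_site_likelihood(tree, model, seqs, s)) for s in range(n_sites))
    )


def enumerate_posterior(tree, model, seqs, site, node_label):
    """P(state at node | site data) by brute-force enumeration."""
    nodes, parents, P = _tree_arrays(tree, model)
    allowed = _leaf_state_sets(nodes, seqs, site)
    target = next(
        i for i, n in enumerate(nodes)
        if (n.taxon.label if n.taxon else n.label) == node_label
    )
    mass = np.zeros(20)
    for assignment in itertools.product(*allowed):
        p = model.pi[assignment[0]]
        for i in range(1, len(nodes)):
            p *= P[i][assignment[parents[i]], assignment[i]]
        mass[assignment[target]] += p
    return mass / mass.sum()


def fixed_point_equilibrium(P_total, L_total, I_total, K_D_L, K_D_I,
                            n_iter=10000, tol=1e-14):
    """Free protein by damped fixed-point iteration on the mass balance."""
    p = P_total / 2.0
    for _ in range(n_iter):
        denom = 1.0 + L_total / (K_D_L + p) + I_total / (K_D_I + p)
        p_new = P_total / denom
        p_next = 0.5 * (p + p_new)
        if abs(p_next - p) < tol * max(p, 1e-30):
            p = p_next
            break
        p = p_next
    return p
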