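"""Marginal ancestral sequence reconstruction on a fixed rooted tree.

The likelihood is the standard pruning recursion over a reversible
amino-acid model; per-site marginal posteriors at internal nodes come from
a combined post-order/pre-order (down/up) message pass, which is exactly
equivalent to re-rooting the tree at the query node.  From the posteriors
two ancestral variants are emitted:

* the ML ancestor — at every column the residue with the highest marginal
  posterior probability;
* the AltAll ancestor — a robustness variant in which every ambiguous
  column (ML posterior < 0.90 and runner-up >= 0.10) carries the
  second-most-likely residue instead.

Gaps and unknown residues are treated as missing data (partial-likelihood
vector of ones); ancestral gap placement is not inferred.  Ties at the
argmax are broken toward the alphabetically first residue, so every
reconstruction is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .alignment import Alignment, is_missing
from .substitution import AA_INDEX, AMINO_ACIDS, SubstitutionModel

__all__ = [
    "PosteriorTable",
    "AncestralVariant",
    "load_tree",
    "tree_log_likelihood",
    "marginal_posteriors",
    "ml_sequence",
    "altall_sequence",
    "uncertainty_report",
]


@dataclass
class PosteriorTable:
    """Per-column marginal amino-acid posteriors at one tree node.

    ``probs`` has shape (n_columns, 20) over :data:`AMINO_ACIDS`; rows of
    non-missing columns sum to 1.  ``missing`` flags columns where every
    leaf below the node carries missing data.
    """

    node_id: str
    probs: np.ndarray
    missing: np.ndarray = field(default=None)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 20:
            raise ValueError("probs must have shape (n_columns, 20)")
        if self.missing is None:
            self.missing = np.zeros(self.probs.shape[0], dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-9):
            raise ValueError("posterior probabilities must lie in [0, 1]")
        ok = ~self.missing
        if ok.any() and not np.allclose(self.probs[ok].sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("non-missing posterior rows must sum to 1")

    @property
    def n_columns(self) -> int:
        return self.probs.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular view: node, 1-based column, missing flag, 20 probabilities."""
        df = pd.DataFrame(self.probs, columns=list(AMINO_ACIDS))
        df.insert(0, "node", self.node_id)
        df.insert(1, "column", np.arange(1, self.n_columns + 1))
        df.insert(2, "missing", self.missing.astype(int))
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PosteriorTable":
        df = pd.read_csv(path, sep="\t")
        node = str(df["node"].iloc[0])
        probs = df[list(AMINO_ACIDS)].to_numpy(dtype=float)
        missing = df["missing"].to_numpy(dtype=bool) if "missing" in df else None
        return cls(node_id=node, probs=probs, missing=missing)


@dataclass
class AncestralVariant:
    """An emitted ancestral sequence (ML or AltAll) with site bookkeeping.

    ``substituted_sites`` lists, for an AltAll variant, the 1-based columns
    where the second-most-likely residue replaced the ML residue, as tuples
    (column, ml_residue, alt_residue, p_ml, p_alt); it is empty for ML
    variants.  The Hamming distance to the ML sequence always equals
    ``len(substituted_sites)``.
    """

    node_id: str
    kind: str  # "ML" | "AltAll"
    sequence: str
    substituted_sites: list[tuple[int, str, str, float, float]] = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in ("ML", "AltAll"):
            raise ValueError(f"kind must be 'ML' or 'AltAll', got {self.kind!r}")

    @property
    def fasta_header(self) -> str:
        return f"{self.node_id}|{self.kind}"


# ---------------------------------------------------------------------------
# tree handling

def load_tree(path: str | Path, outgroup: str | None = None) -> dendropy.Tree:
    """Read a Newick tree; optionally root it on a named outgroup leaf."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    if outgroup is not None:
        og = None
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is not None and leaf.taxon.label == outgroup:
                og = leaf
                break
        if og is None:
            raise ValueError(f"outgroup {outgroup!r} not found among leaves")
        tree.to_outgroup_position(og, update_bipartitions=False)
    return tree


def _node_label(node: dendropy.Node) -> str | None:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label


def find_node(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for node in tree.preorder_node_iter():
        if _node_label(node) == label:
            return node
    raise KeyError(f"node {label!r} not found in tree")


def _validate_tree(alignment: Alignment, tree: dendropy.Tree) -> None:
    leaf_labels = set()
    for leaf in tree.leaf_node_iter():
        lab = _node_label(leaf)
        if lab is None:
            raise ValueError("every leaf must be labelled")
        leaf_labels.add(lab)
    if leaf_labels != set(alignment.ids):
        missing = set(alignment.ids) - leaf_labels
        extra = leaf_labels - set(alignment.ids)
        raise ValueError(
            f"leaf labels must match alignment ids (missing from tree: "
            f"{sorted(missing)}, extra in tree: {sorted(extra)})"
        )
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        t = edge.length
        if t is None or not np.isfinite(t) or t < 0:
            raise ValueError(
                f"branch lengths must be finite and >= 0, got {t} "
                f"above node {_node_label(edge.head_node)!r}"
            )


def _leaf_partial(sequence: str) -> np.ndarray:
    """(n_sites, 20) indicator partials; missing characters give all-ones."""
    n = len(sequence)
    L = np.zeros((n, 20))
    for i, c in enumerate(sequence):
        if is_missing(c):
            L[i, :] = 1.0
        else:
            L[i, AA_INDEX[c]] = 1.0
    return L


def _downward_pass(
    alignment: Alignment, tree: dendropy.Tree, model: SubstitutionModel
):
    """Post-order partial likelihoods with per-site log scaling.

    Returns (down, messages, log_scale) where ``down[node]`` is the
    (n_sites, 20) conditional likelihood of the data below the node and
    ``messages[child]`` is the child's contribution to its parent,
    sum_b P(t_child)_{a,b} down[child][:, b].
    """
    seqs = dict(alignment.records)
    n_sites = alignment.n_columns
    down: dict[dendropy.Node, np.ndarray] = {}
    messages: dict[dendropy.Node, np.ndarray] = {}
    log_scale = np.zeros(n_sites)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            down[node] = _leaf_partial(seqs[_node_label(node)])
        else:
            L = np.ones((n_sites, 20))
            for child in node.child_nodes():
                P = model.transition_matrix(child.edge.length or 0.0)
                msg = down[child] @ P.T
                messages[child] = msg
                L = L * msg
            scale = L.max(axis=1)
            scale[scale == 0] = 1.0
            L = L / scale[:, None]
            log_scale += np.log(scale)
            down[node] = L
    return down, messages, log_scale


def tree_log_likelihood(
    alignment: Alignment, tree: dendropy.Tree, model: SubstitutionModel
) -> float:
    """Log-likelihood (nats) of the alignment on the rooted tree.

    Sum over columns of log P(column | tree, model) with the model's
    stationary distribution as root prior; gaps and 'X' contribute
    all-ones partial vectors (missing data).
    """
    _validate_tree(alignment, tree)
    down, _, log_scale = _downward_pass(alignment, tree, model)
    site_lik = down[tree.seed_node] @ model.pi
    return float(np.sum(np.log(site_lik) + log_scale))


def marginal_posteriors(
    alignment: Alignment,
    tree: dendropy.Tree,
    model: SubstitutionModel,
    node: str | dendropy.Node,
) -> PosteriorTable:
    """Exact per-column marginal posteriors P(state at node | leaf data).

    Computed by the down/up message-passing recursion, equivalent to
    re-rooting the (reversible) model at the query node.  Columns whose
    descendant leaves are all missing are flagged ``missing`` (their
    posterior is then driven entirely by the rest of the tree).
    """
    _validate_tree(alignment, tree)
    target = find_node(tree, node) if isinstance(node, str) else node
    if target.is_leaf():
        raise ValueError("marginal posteriors are defined for internal nodes only")

    n_sites = alignment.n_columns
    down, messages, _ = _downward_pass(alignment, tree, model)

    # pre-order pass: up[v][:, a] propto P(data not below v, state at v = a)
    up: dict[dendropy.Node, np.ndarray] = {tree.seed_node: np.tile(model.pi, (n_sites, 1))}
    for v in tree.preorder_node_iter():
        if v.is_leaf():
            continue
        children = v.child_nodes()
        for c in children:
            agg = up[v].copy()
            for s in children:
                if s is not c:
                    agg *= messages[s]
            P = model.transition_matrix(c.edge.length or 0.0)
            u = agg @ P
            scale = u.max(axis=1)
            scale[scale == 0] = 1.0
            up[c] = u / scale[:, None]

    post = up[target] * down[target]
    norm = post.sum(axis=1)
    norm[norm == 0] = 1.0
    post = post / norm[:, None]

    # a column is flagged missing when every leaf below the node is missing
    seqs = dict(alignment.records)
    desc = [
        _node_label(leaf) for leaf in target.leaf_iter()
    ]
    missing = np.ones(n_sites, dtype=bool)
    for lab in desc:
        missing &= np.array([is_missing(c) for c in seqs[lab]])
    return PosteriorTable(node_id=str(node) if isinstance(node, str) else (_node_label(target) or "node"),
                          probs=post, missing=missing)


# ---------------------------------------------------------------------------
# variant emission

def _argmax_two(p: np.ndarray) -> tuple[int, int]:
    """Indices of the best and second-best residues, alphabetical tie-break."""
    order = sorted(range(20), key=lambda i: (-p[i], AMINO_ACIDS[i]))
    return order[0], order[1]


def ml_sequence(post: PosteriorTable) -> AncestralVariant:
    """Maximum-likelihood ancestor: the argmax residue at every column.

    Exact probability ties are broken toward the alphabetically first
    residue; missing columns are emitted as '-'.
    """
    chars = []
    for j in range(post.n_columns):
        if post.missing[j]:
            chars.append("-")
            continue
        best, _ = _argmax_two(post.probs[j])
        chars.append(AMINO_ACIDS[best])
    return AncestralVariant(node_id=post.node_id, kind="ML", sequence="".join(chars))


def altall_sequence(
    post: PosteriorTable,
    p_ml_threshold: float = 0.90,
    p_alt_threshold: float = 0.10,
) -> AncestralVariant:
    """AltAll ancestor: swap in the runner-up at every ambiguous column.

    A column is ambiguous when the ML residue's posterior is below
    ``p_ml_threshold`` (default 0.90) and the second-most-likely residue's
    posterior is at least ``p_alt_threshold`` (default 0.10).  All other
    columns carry the ML residue.
    """
    for name, thr in (("p_ml_threshold", p_ml_threshold), ("p_alt_threshold", p_alt_threshold)):
        if not 0 < thr <= 1:
            raise ValueError(f"{name} must be in (0, 1], got {thr}")
    chars = []
    sites: list[tuple[int, str, str, float, float]] = []
    for j in range(post.n_columns):
        if post.missing[j]:
            chars.append("-")
            continue
        p = post.probs[j]
        best, second = _argmax_two(p)
        if p[best] < p_ml_threshold and p[second] >= p_alt_threshold:
            chars.append(AMINO_ACIDS[second])
            sites.append(
                (j + 1, AMINO_ACIDS[best], AMINO_ACIDS[second], float(p[best]), float(p[second]))
            )
        else:
            chars.append(AMINO_ACIDS[best])
    return AncestralVariant(
        node_id=post.node_id, kind="AltAll", sequence="".join(chars), substituted_sites=sites
    )


def uncertainty_report(
    post: PosteriorTable, thresholds: list[float] = (0.50, 0.90)
) -> dict[float, int]:
    """Count non-missing columns whose ML posterior falls below each threshold.

    Counts are monotone non-decreasing in the threshold: every column below
    0.50 is also below 0.90.
    """
    thresholds = sorted(thresholds)
    ok = ~post.missing
    p_ml = post.probs.max(axis=1)
    return {float(t): int(np.sum(ok & (p_ml < t))) for t in thresholds}


def variants_to_fasta(variants: list[AncestralVariant], path: str | Path) -> None:
    """Write ancestral variants as FASTA with kind-tagged headers."""
    with open(path, "w") as fh:
        for v in variants:
            fh.write(f">{v.fasta_header}\n{v.sequence}\n")
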