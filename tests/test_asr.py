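"""ASR engine: pruning likelihood, marginal posteriors, variant emission."""

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_alignment
from oracles import enumerate_log_likelihood, enumerate_posterior

from paleoaffinity.alignment import Alignment
from paleoaffinity.asr import (
    PosteriorTable,
    altall_sequence,
    marginal_posteriors,
    ml_sequence,
    tree_log_likelihood,
    uncertainty_report,
)
from paleoaffinity.substitution import AA_INDEX
from paleoaffinity.synthetic import evolve_sequences, make_balanced_tree


# ---------------------------------------------------------------------------
# likelihood

def test_single_leaf_likelihood_is_prior(jtt):
    tree = dendropy.Tree.get(data="(L1:0.0):0.0;", schema="newick")
    # degenerate: root with one zero-length child
    aln = Alignment([("L1", "W")])
    ll = tree_log_likelihood(aln, tree, jtt)
    assert np.isclose(ll, np.log(jtt.pi[AA_INDEX["W"]]), atol=1e-12)


def test_two_leaf_likelihood_matches_direct_sum(jtt):
    t1, t2 = 0.12, 0.37
    tree = dendropy.Tree.get(data=f"(L1:{t1},L2:{t2})N1;", schema="newick",
                             preserve_underscores=True)
    x, y = AA_INDEX["F"], AA_INDEX["L"]
    aln = Alignment([("L1", "F"), ("L2", "L")])
    P1, P2 = jtt.transition_matrix(t1), jtt.transition_matrix(t2)
    direct = np.log(np.sum(jtt.pi * P1[:, x] * P2[:, y]))
    assert np.isclose(tree_log_likelihood(aln, tree, jtt), direct, atol=1e-12)


def test_pruning_matches_enumeration_four_leaves(jtt, four_leaf_tree):
    aln = random_alignment(["L1", "L2", "L3", "L4"], 10, seed=3)
    ll = tree_log_likelihood(aln, four_leaf_tree, jtt)
    brute = enumerate_log_likelihood(four_leaf_tree, jtt, dict(aln.records), 10)
    assert abs(ll - brute) < 1e-10


def test_missing_data_drops_leaf_contribution(jtt, four_leaf_tree):
    # an all-gap leaf must not change the likelihood relative to pruning it
    aln = Alignment([("L1", "F"), ("L2", "L"), ("L3", "-"), ("L4", "X")])
    ll = tree_log_likelihood(aln, four_leaf_tree, jtt)
    brute = enumerate_log_likelihood(four_leaf_tree, jtt, dict(aln.records), 1)
    assert abs(ll - brute) < 1e-10


def test_likelihood_rejects_bad_inputs(jtt, four_leaf_tree):
    aln = random_alignment(["L1", "L2", "L3"], 5, seed=0)
    with pytest.raises(ValueError, match="leaf labels"):
        tree_log_likelihood(aln, four_leaf_tree, jtt)
    bad = dendropy.Tree.get(data="(L1:0.1,L2:-0.2)N1;", schema="newick",
                            preserve_underscores=True)
    with pytest.raises(ValueError, match="branch length"):
        tree_log_likelihood(random_alignment(["L1", "L2"], 3, seed=1), bad, jtt)


# ---------------------------------------------------------------------------
# marginal posteriors

def test_star_tree_zero_branches_pin_posterior(jtt):
    tree = dendropy.Tree.get(data="(L1:0.0,L2:0.0,L3:0.0)N1;", schema="newick",
                             preserve_underscores=True)
    aln = Alignment([("L1", "W"), ("L2", "W"), ("L3", "W")])
    post = marginal_posteriors(aln, tree, jtt, "N1")
    assert np.isclose(post.probs[0, AA_INDEX["W"]], 1.0, atol=1e-12)


def test_three_leaf_posterior_matches_bayes(jtt, three_leaf_tree):
    aln = Alignment([("L1", "F"), ("L2", "W"), ("L3", "L")])
    post = marginal_posteriors(aln, three_leaf_tree, jtt, "N1")
    brute = enumerate_posterior(three_leaf_tree, jtt, dict(aln.records), 0, "N1")
    assert np.allclose(post.probs[0], brute, atol=1e-12)


def test_internal_node_posterior_matches_enumeration(jtt, four_leaf_tree):
    aln = random_alignment(["L1", "L2", "L3", "L4"], 6, seed=11)
    for node in ("N1", "N2", "N3"):
        post = marginal_posteriors(aln, four_leaf_tree, jtt, node)
        for site in range(6):
            brute = enumerate_posterior(four_leaf_tree, jtt, dict(aln.records), site, node)
            assert np.allclose(post.probs[site], brute, atol=1e-10)


def test_posteriors_sum_to_one_and_ignore_leaf_order(jtt, four_leaf_tree):
    aln = random_alignment(["L1", "L2", "L3", "L4"], 8, seed=5)
    post = marginal_posteriors(aln, four_leaf_tree, jtt, "N2")
    assert np.allclose(post.probs.sum(axis=1), 1.0, atol=1e-10)
    shuffled = Alignment(list(reversed(aln.records)))
    post2 = marginal_posteriors(shuffled, four_leaf_tree, jtt, "N2")
    assert np.allclose(post.probs, post2.probs, atol=1e-12)


def test_leaf_node_request_rejected(jtt, four_leaf_tree):
    aln = random_alignment(["L1", "L2", "L3", "L4"], 3, seed=2)
    with pytest.raises(ValueError, match="internal"):
        marginal_posteriors(aln, four_leaf_tree, jtt, "L1")
    with pytest.raises(KeyError):
        marginal_posteriors(aln, four_leaf_tree, jtt, "nonsense")


def test_reconstruction_beats_leaf_majority_on_simulated_data(jtt):
    """On a 16-leaf simulated phylogeny the model-based posterior puts more
    mass on the true ancestral residue than naive leaf-majority voting."""
    tree = make_balanced_tree(depth=4, branch_length=0.25)
    aln, truth = evolve_sequences(tree, jtt, n_sites=100, seed=42)
    node = "N2"  # an internal node one level below the root
    post = marginal_posteriors(aln, tree, jtt, node)
    true_states = np.array([AA_INDEX[c] for c in truth[node]])
    post_mass = post.probs[np.arange(100), true_states].mean()

    target = next(n for n in tree.preorder_node_iter() if n.label == node)
    desc = [leaf.taxon.label for leaf in target.leaf_iter()]
    seqs = dict(aln.records)
    counts = np.zeros((100, 20))
    for lab in desc:
        for site, c in enumerate(seqs[lab]):
            counts[site, AA_INDEX[c]] += 1
    majority_mass = (counts / counts.sum(axis=1, keepdims=True))[
        np.arange(100), true_states
    ].mean()
    assert post_mass > majority_mass


# ---------------------------------------------------------------------------
# variant emission

def _table(columns, node="anc"):
    probs = np.zeros((len(columns), 20))
    for i, col in enumerate(columns):
        for aa, p in col.items():
            probs[i, AA_INDEX[aa]] = p
        rest = 1.0 - probs[i].sum()
        # spread any remainder over unused residues to keep rows normalised
        unused = probs[i] == 0
        probs[i, unused] = rest / unused.sum()
    return PosteriorTable(node_id=node, probs=probs)


def test_ml_sequence_takes_argmax_with_alphabetical_ties():
    table = _table([{"F": 0.97}, {"L": 0.5, "M": 0.5}])
    ml = ml_sequence(table)
    assert ml.sequence == "FL"
    assert ml.kind == "ML"
    assert ml.substituted_sites == []


def test_ml_sequence_emits_gap_for_missing_columns():
    probs = np.full((2, 20), 0.05)
    table = PosteriorTable(node_id="anc", probs=probs, missing=np.array([False, True]))
    assert ml_sequence(table).sequence[1] == "-"


def test_altall_swaps_only_qualifying_columns():
    table = _table([
        {"L": 0.85, "M": 0.12},    # ambiguous: swap to M
        {"L": 0.85, "M": 0.08},    # runner-up below 0.10: keep L
        {"L": 0.95, "M": 0.04},    # confident: keep L
    ])
    alt = altall_sequence(table)
    assert alt.sequence == "MLL"
    assert len(alt.substituted_sites) == 1
    col, ml_res, alt_res, p_ml, p_alt = alt.substituted_sites[0]
    assert (col, ml_res, alt_res) == (1, "L", "M")
    assert p_ml == pytest.approx(0.85) and p_alt == pytest.approx(0.12)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.lists(
    st.lists(st.floats(0.01, 1.0), min_size=20, max_size=20),
    min_size=1, max_size=30,
))
def test_altall_hamming_distance_equals_substituted_sites(raw):
    probs = np.array(raw)
    probs = probs / probs.sum(axis=1, keepdims=True)
    table = PosteriorTable(node_id="x", probs=probs)
    ml = ml_sequence(table)
    alt = altall_sequence(table)
    hamming = sum(a != b for a, b in zip(ml.sequence, alt.sequence))
    assert hamming == len(alt.substituted_sites)
    for col, ml_res, alt_res, p_ml, p_alt in alt.substituted_sites:
        assert p_ml < 0.90 and p_alt >= 0.10
        assert ml.sequence[col - 1] == ml_res
        assert alt.sequence[col - 1] == alt_res


def test_uncertainty_report_counts_planted_values():
    cols = [{"A": 0.95}] * 5 + [{"A": 0.8}] * 3 + [{"A": 0.4}] * 2
    table = _table(cols)
    counts = uncertainty_report(table, [0.50, 0.90])
    assert counts[0.90] == 5
    assert counts[0.50] == 2


def test_uncertainty_report_all_certain_is_zero():
    probs = np.zeros((4, 20))
    probs[:, 0] = 1.0
    counts = uncertainty_report(PosteriorTable(node_id="x", probs=probs), [0.5, 0.9])
    assert counts == {0.5: 0, 0.9: 0}


def test_posterior_table_tsv_round_trip(tmp_path, jtt, four_leaf_tree):
    aln = random_alignment(["L1", "L2", "L3", "L4"], 5, seed=9)
    post = marginal_posteriors(aln, four_leaf_tree, jtt, "N2")
    path = tmp_path / "post.tsv"
    post.to_tsv(path)
    back = PosteriorTable.from_tsv(path)
    assert back.node_id == post.node_id
    assert np.allclose(back.probs, post.probs, atol=1e-9)
    assert ml_sequence(back).sequence == ml_sequence(post).sequence
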