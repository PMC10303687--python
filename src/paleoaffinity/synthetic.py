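"""Seeded generators for every input the analysis pipeline consumes.

Each generator is a deterministic function of its parameters and a seed,
and produces objects that pass the corresponding module's validators, so
the whole pipeline is testable with known ground truth and no external
data.  Defaults mirror the experimental regimes of the study the package
models: stopped-flow mixes at 0.5-2 uM protein against 1-10 uM peptide,
displacement at 10-20 uM displacer over a 1 uM : 1 uM complex, FP tracers
at 6-10 nM, and GdnCl denaturation from 0 to 6 M.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alignment import Alignment
from .cd_stability import DenaturationCurve, two_state_signal, R_KCAL
from .fp import FPTitration, solve_competitive_equilibrium
from .kinetics import (
    AssociationSeries,
    DisplacementSeries,
    KineticTrace,
    kobs_reversible,
)
from .substitution import AMINO_ACIDS, AA_INDEX, SubstitutionModel


@dataclass
class SimulationConfig:
    """A named simulation: experiment kind, true parameters, seed."""

    kind: str                      # evolve | stopped_flow | fp | denaturation
    seed: int
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sequence evolution

def make_balanced_tree(depth: int, branch_length: float) -> dendropy.Tree:
    """Balanced binary tree with 2**depth leaves and equal branch lengths.

    Internal nodes are labelled N1, N2, ... in preorder (N1 is the root);
    leaves are labelled L1, L2, ...
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    tree = dendropy.Tree()
    namespace = tree.taxon_namespace
    counter = {"internal": 0, "leaf": 0}

    def grow(node, level):
        if level == depth:
            counter["leaf"] += 1
            node.taxon = namespace.new_taxon(label=f"L{counter['leaf']}")
            return
        for _ in range(2):
            child = node.new_child(edge_length=branch_length)
            grow(child, level + 1)

    counter["internal"] += 1
    tree.seed_node.label = f"N{counter['internal']}"
    grow(tree.seed_node, 0)
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.label is None:
            counter["internal"] += 1
            node.label = f"N{counter['internal']}"
    return tree


def evolve_sequences(
    tree: dendropy.Tree,
    model: SubstitutionModel,
    n_sites: int | None = None,
    root_sequence: str | None = None,
    seed: int = 0,
) -> tuple[Alignment, dict[str, str]]:
    """Evolve amino-acid sequences down a tree under the model.

    The root state is either the given ``root_sequence`` or drawn site-wise
    from the model's stationary distribution (``n_sites`` long); each child
    state is sampled from the transition matrix of its branch.  Returns the
    leaf alignment and the true sequence at every node (keyed by label), so
    reconstruction accuracy can be scored against known ancestors.
    """
    if (root_sequence is None) == (n_sites is None):
        raise ValueError("give exactly one of root_sequence or n_sites")
    rng = np.random.default_rng(seed)
    if root_sequence is not None:
        root_states = np.array([AA_INDEX[c] for c in root_sequence.upper()])
    else:
        root_states = rng.choice(20, size=n_sites, p=model.pi)
    n = root_states.size

    states: dict[dendropy.Node, np.ndarray] = {}
    truth: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[node] = root_states
        else:
            P = model.transition_matrix(node.edge.length or 0.0)
            parent = states[node.parent_node]
            # one categorical draw per site, row chosen by the parent state
            u = rng.random(n)
            cdf = np.cumsum(P[parent], axis=1)
            states[node] = (u[:, None] > cdf).sum(axis=1)
        label = node.taxon.label if node.taxon is not None else node.label
        if label:
            truth[label] = "".join(AMINO_ACIDS[i] for i in states[node])

    leaves = [
        (leaf.taxon.label, truth[leaf.taxon.label])
        for leaf in tree.leaf_node_iter()
    ]
    return Alignment(leaves), truth


# ---------------------------------------------------------------------------
# stopped-flow kinetics

def simulate_trace(
    k_obs: float = 25.0,
    amplitude: float = 1.0,
    offset: float = 5.0,
    protein_total: float = 1.0,
    ligand_total: float = 5.0,
    n_points: int = 200,
    noise_frac: float = 0.02,
    seed: int = 0,
) -> KineticTrace:
    """One single-exponential fluorescence trace with Gaussian noise.

    The time window spans ~7 relaxation times; noise is ``noise_frac`` of
    the amplitude (default 2%, instrument-like).
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 7.0 / k_obs, n_points + 1)[1:]
    y = offset + amplitude * np.exp(-k_obs * t)
    y = y + rng.normal(0.0, noise_frac * abs(amplitude), size=t.size)
    return KineticTrace(time=t, signal=y, protein_total=protein_total,
                        ligand_total=ligand_total)


def simulate_association_series(
    k_on: float = 20.0,
    k_off: float = 2.0,
    protein_total: float = 1.0,
    ligand_concs: np.ndarray | None = None,
    noise_frac: float = 0.02,
    seed: int = 0,
) -> AssociationSeries:
    """k_obs versus ligand concentration with multiplicative Gaussian noise.

    True k_obs values come from the reversible-bimolecular relaxation rate
    at the configured concentrations (protein fixed at 0.5-2 uM, ligand
    sweeping 1-10 uM by default); 2% noise emulates the scatter of
    trace-level exponential fits.
    """
    rng = np.random.default_rng(seed)
    if ligand_concs is None:
        ligand_concs = np.linspace(1.0, 10.0, 10)
    k_true = np.array([
        kobs_reversible(protein_total, B, k_on, k_off) for B in ligand_concs
    ])
    # instrument-like noise: constant sigma, 2% of the series' dynamic range
    sigma = noise_frac * (k_true.max() - k_true.min())
    noisy = k_true + rng.normal(0.0, sigma, k_true.size)
    points = [(float(B), float(k), float(sigma))
              for B, k in zip(ligand_concs, noisy)]
    return AssociationSeries(protein_total=protein_total, points=points)


def simulate_displacement_series(
    k_off: float = 2.0,
    k_half: float = 0.5,
    complex_conc: tuple[float, float] = (1.0, 1.0),
    displacer_concs: np.ndarray | None = None,
    baseline_frac: float = 0.05,
    replicates: int = 2,
    noise_frac: float = 0.02,
    seed: int = 0,
) -> DisplacementSeries:
    """Displacement k_obs series saturating to k_off at high displacer.

    k_obs([D]) approaches k_off hyperbolically with half-point ``k_half``
    (uM); the default 10-20 uM displacer grid over a 1 uM : 1 uM complex
    sits deep in the saturated regime, where k_obs ~= k_off.
    """
    rng = np.random.default_rng(seed)
    if displacer_concs is None:
        displacer_concs = np.linspace(10.0, 20.0, 6)
    base = baseline_frac * k_off
    sigma = noise_frac * k_off      # constant sigma, 2% of the plateau scale
    points = []
    for _ in range(replicates):
        for D in displacer_concs:
            k_true = base + (k_off - base) * D / (k_half + D)
            points.append((float(D), float(k_true + rng.normal(0.0, sigma)), float(sigma)))
    return DisplacementSeries(complex_conc=complex_conc, points=points)


def simulate_stopped_flow(config: SimulationConfig):
    """Dispatch a stopped-flow simulation from a config object."""
    p = dict(config.params)
    what = p.pop("experiment", "association")
    if what == "trace":
        return simulate_trace(seed=config.seed, **p)
    if what == "association":
        return simulate_association_series(seed=config.seed, **p)
    if what == "displacement":
        return simulate_displacement_series(seed=config.seed, **p)
    raise ValueError(f"unknown stopped-flow experiment {what!r}")


# ---------------------------------------------------------------------------
# fluorescence polarization

def _dilution_series(top: float, n: int) -> np.ndarray:
    """1:1 (two-fold) dilution series from ``top`` downward, ascending order."""
    return top / 2.0 ** np.arange(n)[::-1]


def simulate_fp_saturation(
    K_D_label: float,
    labeled_total_nM: float = 10.0,
    top_protein: float = 90.0,
    n_dilutions: int = 12,
    mP_free: float = 60.0,
    mP_bound: float = 260.0,
    noise_mP: float = 4.0,
    seed: int = 0,
) -> FPTitration:
    """Saturation titration: protein 1:1 dilutions against a fixed tracer."""
    rng = np.random.default_rng(seed)
    P = _dilution_series(top_protein, n_dilutions)
    L = labeled_total_nM * 1e-3
    frac = np.array([
        solve_competitive_equilibrium(pt, L, 0.0, K_D_label, 1.0).fraction_bound
        for pt in P
    ])
    mP = mP_free + (mP_bound - mP_free) * frac + rng.normal(0.0, noise_mP, P.size)
    return FPTitration(mode="saturation", labeled_total_nM=labeled_total_nM,
                       conc=P, polarization=mP)


def simulate_fp_displacement(
    K_D_competitor: float,
    K_D_label: float = 5.0,
    protein_total: float = 10.0,
    labeled_total_nM: float = 10.0,
    top_competitor: float = 1000.0,
    n_dilutions: int = 14,
    replicates: int = 3,
    mP_free: float = 60.0,
    mP_bound: float = 260.0,
    noise_mP: float = 4.0,
    seed: int = 0,
) -> FPTitration:
    """Displacement titration: competitor 1:1 dilutions at fixed protein/tracer.

    Polarization follows the label's bound fraction from the exact
    competitive equilibrium, so the planted competitor K_D can be recovered
    through the IC50 -> K_D conversion.
    """
    rng = np.random.default_rng(seed)
    I = _dilution_series(top_competitor, n_dilutions)
    L = labeled_total_nM * 1e-3
    conc, mP, rep = [], [], []
    for r in range(replicates):
        frac = np.array([
            solve_competitive_equilibrium(protein_total, L, i, K_D_label, K_D_competitor).fraction_bound
            for i in I
        ])
        y = mP_free + (mP_bound - mP_free) * frac + rng.normal(0.0, noise_mP, I.size)
        conc.append(I)
        mP.append(y)
        rep.append(np.full(I.size, r))
    return FPTitration(
        mode="displacement", labeled_total_nM=labeled_total_nM,
        conc=np.concatenate(conc), polarization=np.concatenate(mP),
        replicate=np.concatenate(rep), protein_total=protein_total,
    )


def simulate_fp(config: SimulationConfig) -> FPTitration:
    p = dict(config.params)
    what = p.pop("experiment", "saturation")
    if what == "saturation":
        return simulate_fp_saturation(seed=config.seed, **p)
    if what == "displacement":
        return simulate_fp_displacement(seed=config.seed, **p)
    raise ValueError(f"unknown FP experiment {what!r}")


# ---------------------------------------------------------------------------
# chemical denaturation

def simulate_denaturation(
    m: float = 2.0,
    D50: float = 3.0,
    native_baseline: tuple[float, float] = (-30.0, 0.3),
    denatured_baseline: tuple[float, float] = (-5.0, 0.1),
    max_denaturant: float = 6.0,
    n_points: int = 25,
    noise_mdeg: float = 1.0,
    temperature_C: float = 25.0,
    seed: int = 0,
) -> DenaturationCurve:
    """Two-state GdnCl unfolding curve with additive Gaussian noise (mdeg)."""
    rng = np.random.default_rng(seed)
    D = np.linspace(0.0, max_denaturant, n_points)
    RT = R_KCAL * (temperature_C + 273.15)
    y = two_state_signal(
        D, m, D50, native_baseline[0], native_baseline[1],
        denatured_baseline[0], denatured_baseline[1], RT,
    )
    y = y + rng.normal(0.0, noise_mdeg, D.size)
    return DenaturationCurve(denaturant=D, signal=y, temperature_C=temperature_C)
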