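# Methods

This note documents the models, estimators, defaults and design choices
behind `paleoaffinity`, and what the simulation-based validation does and
does not establish.

## Ancestral sequence reconstruction

**Model.** A general-time-reversible amino-acid substitution process with
the JTT exchangeabilities and equilibrium frequencies embedded as package
constants (`substitution.py`). The rate matrix is built as
Q_ij = S_ij π_j, made conservative row-wise, and rescaled so that one unit
of branch length equals one expected substitution per site — the
convention of trees produced by standard ML software, so input trees can
be used as-is. Transition matrices P(t) = exp(Qt) come from the spectral
decomposition of the π-symmetrised rate matrix, which is stable for any
t ≥ 0; rows are clipped and renormalised against rounding noise. A single
rate class is used across sites; among-site rate variation is a deliberate
non-feature (the reconstruction contract is defined on the input tree and
model as given), left as an extension point.

**Likelihood and posteriors.** `tree_log_likelihood` is the standard
post-order pruning recursion with per-site log scaling; the root prior is
the stationary distribution. `marginal_posteriors` adds a pre-order pass:
for node v, the posterior at a site is proportional to
(outside message at v) × (partial likelihood below v). For a reversible
model this is exactly equivalent to re-rooting the tree at v. Both paths
are certified against brute-force enumeration over all internal-state
assignments on 3–4-leaf instances (agreement to ~1e-14, asserted at 1e-9).

**Missing data.** Gaps and 'X' contribute all-ones partial vectors. The
likelihood therefore marginalises them out; ancestral gap placement is not
inferred (no indel model). A posterior column is flagged `missing` when
every leaf below the node is missing there; the ML emitter prints '-' at
such columns.

**Variant emission.** The ML ancestor takes the argmax residue per column;
exact probability ties break toward the alphabetically first residue, so
emission is deterministic. The AltAll variant swaps in the second-most-
likely residue at every column where the ML posterior is below 0.90 and
the runner-up is at least 0.10 (both thresholds are parameters). By
construction the Hamming distance between ML and AltAll equals the number
of recorded substituted sites; this is property-tested on random tables.
`uncertainty_report` counts non-missing columns with ML posterior below
each requested threshold (0.50 and 0.90 by default).

**Gap-column filtering.** A column is removed when its gap fraction
strictly exceeds the tolerance (default 0.95). The alternative reading —
requiring ≥ 5% non-gap residues — is one flag away since the tolerance is
a parameter. The old→new column map is always reported so positions can be
traced back; reports are 1-based, and `report.motif_position` maps
alignment columns onto the human-p53 motif numbering (15–26).

**Interfaces.** FASTA alignments (biopython), Newick trees (dendropy,
optionally re-rooted on a named outgroup leaf), posteriors as TSV with 20
probability columns, variants as FASTA with `node|kind` headers.

## Stopped-flow kinetics

Units are fixed: concentrations in μM, time in s, k_on in μM⁻¹s⁻¹.
Temperature is metadata only (the assays run at a fixed 10 °C; no
temperature correction is modelled).

**Trace fits.** signal(t) = offset + amplitude·e^(−k_obs·t), by
least squares (lmfit), with uncertainties from the fit covariance. A trace
whose |amplitude| is below 3× its standard error is flagged `no_signal` —
the numeric rule standing in for "no change in fluorescence upon mixing",
which is a real outcome for non-binding pairs, not an error.

**Association.** k_obs versus ligand at fixed protein is fitted to the
exact relaxation rate of A + B ⇌ C,

    k_obs = sqrt( (k_on(A0+B0) + k_off)² − 4 k_on² A0 B0 ),

with inverse-variance weights when per-point σ are available. The form
reduces to k_on[B] + k_off when one side is in large excess (asserted to
1e-6 relative at a 10⁶ concentration ratio). Note that k_obs is symmetric
in the two totals but monotone in ligand only from equimolarity upward; at
B0 < A0 − K_D it passes through a minimum, so association experiments keep
the ligand in excess.

**Displacement.** k_off is the high-displacer plateau of k_obs. The
default estimator fits a hyperbola
baseline + (k_off − baseline)[D]/(k_half + [D]) — but a series already
sitting on its plateau contains no information about k_half, and the
unconstrained hyperbola then chases noise. The estimator therefore
compares the hyperbola against a constant by AICc and, when the constant
wins, reports the mean k_obs over the two highest concentrations (the
"k_obs equals k_off at high displacer" reading; also available directly as
`mode="plateau_mean"`). A fitted half-point beyond half the top displacer
concentration marks the value `extrapolated`. σ(k_off) is the replicate
spread at the top concentration when replicates exist, else the fit error.

**K_D.** K_D = k_off/k_on exactly; σ_KD combines the relative errors in
quadrature (σ_KD/K_D = sqrt((σ_kon/k_on)² + (σ_koff/k_off)²)). This is
first-order propagation under independence; published tables in this field
sometimes print slightly different ± values, so σ is treated as a
consistency quantity, not an exactly reproducible one. `round_sig` /
`format_sig` implement half-away-from-zero significant-figure rounding for
table-style output.

## Fluorescence polarization

**Equilibrium.** Two ligands (tracer L, competitor I) compete for one site
on P. Free protein solves
p + L_t·p/(K_L+p) + I_t·p/(K_I+p) = P_t, the physical root of the
underlying cubic, by bracketed Brent root-finding on [0, P_t] (the left
side is strictly increasing, so the root is unique). An independent damped
fixed-point iteration serves as the oracle in the tests and acceptance
script; the two agree to better than 1e-10 relative over wide random
parameter ranges.

**Saturation.** mP(P) = mP_free + (mP_bound − mP_free)·P/(K_D + P) with
total protein standing in for free protein — justified because the tracer
(≤ 10 nM) sits orders of magnitude below micromolar K_D values; a
depletion-corrected mode using the exact solver is available and agrees to
< 1% in that regime. A fitted K_D above the highest protein concentration
is flagged a lower bound (the curve never approached saturation); the
degenerate linear case converges against the parameter bound and is
flagged the same way rather than raising.

**Displacement.** mP([I]) = bottom + (top − bottom)/(1 + ([I]/IC50)^h),
fitted on log10(IC50) for optimizer stability. When the competitor cannot
reach complete displacement within the dilution series (weak binders), the
bottom plateau is unidentifiable from the titration alone; the analysis
accepts the free-label polarization — known from the saturation experiment
always run first with the same tracer — as a fixed bottom. "No
displacement" is declared when the fitted span is indistinguishable from
zero (< 3× its standard error); that verdict, like `no_signal` above, is a
result, not a failure.

**IC50 → K_D.** The exact conversion
K_i = [I]₅₀ / ( [L]₅₀/K_D_label + [P]₀/K_D_label + 1 ), with free
competitor and free label at 50% displacement and free protein at 0%
displacement all derived from the mass balance. The classical
K_i ≈ IC50/(1 + P/K_D_label) limit is kept as a cross-check mode
(`exact=False`) and as the asymptotic test case. IC50 values at or below
the stoichiometric floor (free competitor at 50% ≤ 0) are flagged
`tight_binding` and unreliable. With technical replicates the competitor
K_D error is the SEM over replicate-wise conversions.

## Chemical denaturation

Two-state N ⇌ D with linear baselines (the standard treatment):

    Y([D]) = [ (αN + βN[D]) + (αD + βD[D])·e^{m([D]−D50)/RT} ]
             / [ 1 + e^{m([D]−D50)/RT} ]

with R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹ and T configurable (default 25 °C).
ΔG_H₂O = m·D50 is exposed as a derived property; the reparameterization
changes nothing about the fitted curve (tested to 1e-8). A flat-baseline
mode supports sensitivity analysis. The "folded" verdict requires a
transition whose amplitude exceeds 3× the residual noise, a midpoint
interior to the measured range, *and* an AICc preference of the two-state
model over a straight line — flexible baselines can otherwise absorb a
sloping line into a sham sigmoid. Curves truncated before the denatured
plateau come back "unresolved" with an extrapolation note, and fits with
fewer than 3 points in a baseline region have their σ estimates doubled
rather than reported overconfidently.

## Synthetic data: what it emulates and what it does not

Every generator is a deterministic function of its parameters and a seed
(numpy `default_rng`), and its output passes the corresponding module's
validators. Defaults encode the assay regimes the pipeline targets:

| generator | defaults |
|---|---|
| `evolve_sequences` | root drawn from π (or given), children sampled via P(t); balanced trees with labelled internals for ground truth |
| `simulate_trace` | 200 points over ~7 relaxation times; Gaussian noise 2% of amplitude |
| `simulate_association_series` | protein 1 μM, ligand 1–10 μM (10 points); constant σ = 2% of the series' dynamic range |
| `simulate_displacement_series` | displacer 10–20 μM over a 1:1 μM complex, half-point 0.5 μM (deep in the saturated regime), 2 replicates, σ = 2% of the plateau |
| `simulate_fp_saturation` | tracer 10 nM, protein 1:1 dilutions from 90 μM, mP 60→260, σ = 4 mP (2% of range) |
| `simulate_fp_displacement` | tracer 10 nM with K_D 5 μM, protein 10 μM, competitor 1:1 dilutions from 1 mM, 3 technical replicates |
| `simulate_denaturation` | 0–6 M GdnCl, 25 points, baselines (−30, +0.3) and (−5, +0.1) mdeg, σ = 1 mdeg |

Noise is additive Gaussian, instrument-like. The generators do **not**
emulate instrument dead time, photobleaching, drift, inner-filter effects,
pipetting error structure, double-exponential (induced-fit) kinetics, or
alignment/tree error in the phylogenetic stage — the tree and alignment
are taken as correct. Passing the recovery studies therefore shows the
estimators are consistent and well-calibrated *under the stated model*,
not that real data are free of these systematic effects.

## Validation problem sizes

The acceptance script and acceptance tests use: brute-force enumeration on
3–4-leaf trees with ≤ 10 sites (exactness to 1e-9); 100 simulated
association+displacement experiments per planted K_D in
{0.01, 0.1, 2, 15} μM (k_on mean within 1%, K_D median within 5%); 11
displacement titrations per planted competitor K_D in {1, 15, 100, 250} μM
(median recovery within 10%); 50 denaturation curves (median m and D50
within 5%); 1,000 random equilibrium-solver draws against the fixed-point
oracle (1e-8). These sizes make the whole validation run in seconds while
keeping the Monte-Carlo margins comfortable.

## Known limitations and open edges

- The JTT single-rate model is the only packaged substitution model;
  adding Γ-distributed rates or other empirical matrices would require a
  small extension of `substitution.py`.
- Reconstruction is marginal (per-node); joint reconstruction is not
  implemented. Marginal posteriors are the quantities the AltAll rule and
  the uncertainty reports are defined on.
- Published affinity tables occasionally print a K_D that is not exactly
  k_off/k_on at the printed precision (author-side rounding); records can
  carry a verbatim `K_D_printed` string for table reproduction, while the
  computed identity K_D = k_off/k_on always holds internally.
- The affinity category bin edges (1 and 100 μM) are editorial
  conveniences for summarising, configurable per call.
- σ values from single fits are covariance-based and can be optimistic;
  where replicates exist the package prefers spread-based errors (SD for
  k_off, SEM for FP conversions).
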