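"""Fluorescence-polarization titrations: saturation, displacement, Ki.

Saturation experiments titrate protein into a low-nanomolar fluorescently
labelled peptide and fit the polarization to a hyperbola for the label's
K_D.  Displacement experiments hold protein and label fixed while an
unlabelled competitor titrates the label out of the complex; the sigmoidal
dose-response yields an IC50, which is converted to the competitor's K_D
with the exact competitive-binding correction of Nikolovska-Coleska et al.
(free concentrations at the 0%- and 50%-displacement points obtained from
the two-ligand/one-site mass balance rather than the Cheng-Prusoff limit).

Concentrations are in uM unless a name says otherwise; polarization in mP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize
from scipy.optimize import brentq

from .kinetics import FitError


@dataclass
class FPTitration:
    """One FP titration (saturation or displacement), possibly replicated.

    For ``mode="saturation"`` the varied concentration is total protein;
    for ``mode="displacement"`` it is total competitor, with
    ``protein_total`` fixed.  ``labeled_total`` is the tracer concentration
    in nM (held at the 6-10 nM scale).
    """

    mode: str                                  # "saturation" | "displacement"
    labeled_total_nM: float
    conc: np.ndarray                           # uM, the varied species
    polarization: np.ndarray                   # mP
    replicate: np.ndarray = None               # replicate index per point
    protein_total: float | None = None         # uM, displacement only
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.mode not in ("saturation", "displacement"):
            raise ValueError("mode must be 'saturation' or 'displacement'")
        self.conc = np.asarray(self.conc, dtype=float)
        self.polarization = np.asarray(self.polarization, dtype=float)
        if self.conc.shape != self.polarization.shape:
            raise ValueError("conc and polarization must have equal length")
        if np.any(self.conc <= 0):
            raise ValueError("concentrations must be positive")
        if self.replicate is None:
            self.replicate = np.zeros(self.conc.size, dtype=int)
        self.replicate = np.asarray(self.replicate, dtype=int)
        if not 3.0 <= self.labeled_total_nM <= 20.0:
            self.warnings.append(
                f"labelled peptide at {self.labeled_total_nM:g} nM is outside the "
                "usual 6-10 nM regime"
            )
        if self.mode == "displacement" and (self.protein_total is None or self.protein_total <= 0):
            raise ValueError("displacement titrations need a positive protein_total")


@dataclass
class EquilibriumState:
    """Free/bound concentrations for protein P, label L and competitor I (uM)."""

    P_free: float
    L_free: float
    I_free: float
    PL: float
    PI: float
    fraction_bound: float     # of the label


@dataclass
class SaturationResult:
    K_D: float                # uM
    K_D_err: float
    mP_free: float
    mP_bound: float
    lower_bound: bool         # True when the data never approach saturation


@dataclass
class CompetitionResult:
    IC50: float               # uM
    IC50_err: float
    hill_slope: float
    K_D_competitor: float     # uM
    K_D_competitor_err: float
    no_displacement: bool = False
    tight_binding: bool = False
    K_D_label: float | None = None
    protein_total: float | None = None
    labeled_total_nM: float | None = None


# ---------------------------------------------------------------------------
# competitive equilibrium

def solve_competitive_equilibrium(
    P_total: float, L_total: float, I_total: float,
    K_D_L: float, K_D_I: float,
) -> EquilibriumState:
    """Exact equilibrium of two ligands L and I competing for one site on P.

    Solves the mass balance
    p + L_t p/(K_L + p) + I_t p/(K_I + p) = P_t for the free protein
    concentration p (the physical root of the underlying cubic) by bracketed
    root-finding; bound species follow from the binding isotherms.
    """
    if min(P_total, L_total, I_total) < 0 or K_D_L <= 0 or K_D_I <= 0:
        raise ValueError("totals must be >= 0 and dissociation constants > 0")
    if P_total == 0:
        return EquilibriumState(0.0, L_total, I_total, 0.0, 0.0, 0.0)

    def balance(p):
        return p + L_total * p / (K_D_L + p) + I_total * p / (K_D_I + p) - P_total

    # balance is strictly increasing in p with balance(0) = -P_t < 0
    p_free = brentq(balance, 0.0, P_total, xtol=1e-15, rtol=1e-14, maxiter=200)
    PL = L_total * p_free / (K_D_L + p_free)
    PI = I_total * p_free / (K_D_I + p_free)
    frac = PL / L_total if L_total > 0 else 0.0
    return EquilibriumState(
        P_free=p_free, L_free=L_total - PL, I_free=I_total - PI,
        PL=PL, PI=PI, fraction_bound=frac,
    )


# ---------------------------------------------------------------------------
# saturation

def fit_saturation(titration: FPTitration, depletion_corrected: bool = False) -> SaturationResult:
    """Fit a saturation titration to a hyperbolic binding isotherm.

    mP(P) = mP_free + (mP_bound - mP_free) * P / (K_D + P), with total
    protein standing in for free protein (the tracer, at <= 10 nM, is far
    below any micromolar K_D).  Set ``depletion_corrected=True`` for the
    quadratic (tracer-depletion) form.  When the fitted K_D exceeds the
    highest protein concentration the curve never approaches saturation and
    the estimate is flagged as a lower bound.
    """
    if titration.mode != "saturation":
        raise ValueError("fit_saturation expects a saturation titration")
    P = titration.conc
    y = titration.polarization
    L_uM = titration.labeled_total_nM * 1e-3

    params = Parameters()
    params.add("K_D", value=float(np.median(P)), min=1e-9, max=1e7)
    params.add("mP_free", value=float(y[np.argmin(P)]))
    params.add("mP_bound", value=float(y[np.argmax(P)]))

    def residual(p):
        kd, lo, hi = p["K_D"].value, p["mP_free"].value, p["mP_bound"].value
        if depletion_corrected:
            frac = np.array([
                solve_competitive_equilibrium(pt, L_uM, 0.0, kd, 1.0).fraction_bound
                for pt in P
            ])
        else:
            frac = P / (kd + P)
        return lo + (hi - lo) * frac - y

    res = minimize(residual, params)
    # a singular covariance ("could not estimate error-bars") is the expected
    # outcome for degenerate far-from-saturation data: K_D unbounded above
    degenerate = "error-bars" in str(res.message) and np.all(np.isfinite(res.residual))
    if not res.success and not degenerate:
        raise FitError(f"saturation fit did not converge: {res.message}")
    kd = float(res.params["K_D"].value)
    kd_err = float(res.params["K_D"].stderr or np.nan)
    lower_bound = kd > float(P.max())
    if lower_bound:
        titration.warnings.append(
            f"saturation not reached (K_D {kd:.3g} uM above top protein "
            f"{P.max():.3g} uM); treat K_D as a lower bound"
        )
    return SaturationResult(
        K_D=kd, K_D_err=kd_err,
        mP_free=float(res.params["mP_free"].value),
        mP_bound=float(res.params["mP_bound"].value),
        lower_bound=bool(lower_bound),
    )


# ---------------------------------------------------------------------------
# displacement

def fit_displacement(
    titration: FPTitration, bottom: float | None = None
) -> tuple[float, float, float, bool]:
    """Fit a displacement titration to a variable-slope dose-response curve.

    mP([I]) = bottom + (top - bottom) / (1 + ([I]/IC50)^h), parameterised on
    log10(IC50) internally for optimizer stability.  When the competitor
    does not reach complete displacement the lower plateau is unidentifiable
    from the titration alone; pass ``bottom`` (the free-label polarization,
    known from the saturation experiment run with the same tracer) to pin
    it.  Returns (IC50, IC50_err, hill_slope, no_displacement); the verdict
    is ``no_displacement`` when the fitted span is indistinguishable from
    zero (|top - bottom| < 3 x its standard error) or the curve does not
    descend.
    """
    if titration.mode != "displacement":
        raise ValueError("fit_displacement expects a displacement titration")
    I = titration.conc
    y = titration.polarization

    params = Parameters()
    params.add("log_ic50", value=float(np.log10(np.median(I))), min=-6, max=6)
    params.add("top", value=float(y[np.argmin(I)]))
    if bottom is None:
        params.add("span", value=float(y[np.argmin(I)] - y[np.argmax(I)]))
    else:
        params.add("bottom_fixed", value=float(bottom), vary=False)
        params.add("span", expr="top - bottom_fixed")
    params.add("hill", value=1.0, min=0.1, max=5.0)

    def residual(p):
        ic50 = 10.0 ** p["log_ic50"].value
        model = (p["top"].value - p["span"].value) + p["span"].value / (
            1.0 + (I / ic50) ** p["hill"].value
        )
        return model - y

    res = minimize(residual, params)
    if not res.success:
        raise FitError(f"displacement fit did not converge: {res.message}")
    span = float(res.params["span"].value)
    span_err = res.params["span"].stderr
    span_err = float(span_err) if span_err is not None else np.inf
    no_displacement = (not np.isfinite(span_err)) or span < 3 * span_err
    ic50 = float(10.0 ** res.params["log_ic50"].value)
    lerr = res.params["log_ic50"].stderr
    ic50_err = float(ic50 * math.log(10) * lerr) if lerr is not None else np.nan
    return ic50, ic50_err, float(res.params["hill"].value), bool(no_displacement)


def ic50_to_kd(
    IC50: float, K_D_label: float, P_total: float, L_total_nM: float,
    exact: bool = True,
) -> tuple[float, bool]:
    """Convert a displacement IC50 to the competitor's K_D (Ki), in uM.

    The exact conversion evaluates
    K_i = [I]_50 / ( [L]_50/K_D_label + [P]_0/K_D_label + 1 )
    with the free competitor and free label at 50% displacement and the free
    protein at 0% displacement all taken from the competitive-equilibrium
    mass balance.  ``exact=False`` uses the classical approximation with
    total concentrations (cross-check mode).  Returns (K_i, tight_binding);
    the flag marks IC50 values at or below the stoichiometric floor, where
    the conversion is unreliable.
    """
    if min(IC50, K_D_label, P_total, L_total_nM) <= 0:
        raise ValueError("all inputs must be positive")
    L_total = L_total_nM * 1e-3

    # 0% displacement: binary P/L equilibrium
    ref = solve_competitive_equilibrium(P_total, L_total, 0.0, K_D_label, 1.0)
    f0 = ref.fraction_bound
    P0_free = ref.P_free

    if not exact:
        ki = IC50 / (1.0 + P_total / K_D_label)
        return ki, False

    # 50% displacement: the label's bound fraction halves
    PL_50 = 0.5 * f0 * L_total
    L_free_50 = L_total - PL_50
    P_free_50 = K_D_label * PL_50 / L_free_50
    PI_50 = P_total - P_free_50 - PL_50
    I_free_50 = IC50 - PI_50
    tight = I_free_50 <= 0 or PI_50 <= 0
    if tight:
        # stoichiometric floor: fall back on totals so a number is returned
        I_free_50 = max(I_free_50, 0.5 * IC50)
    # denominator uses free protein at 0% displacement, free label at 50%
    ki = I_free_50 / (L_free_50 / K_D_label + P0_free / K_D_label + 1.0)
    return float(ki), bool(tight)


def analyze_displacement(
    titration: FPTitration, K_D_label: float, mP_free: float | None = None
) -> CompetitionResult:
    """Full displacement analysis: dose-response fit plus IC50 -> K_D.

    ``mP_free`` (from the matching saturation fit) pins the dose-response
    bottom plateau; without it the bottom floats.  With replicated
    titrations the IC50 is fitted per replicate and the competitor K_D
    error is the SEM over replicate-wise conversions; single titrations
    propagate the IC50 fit error instead.
    """
    reps = np.unique(titration.replicate)
    per_rep: list[float] = []
    if reps.size > 1:
        for r in reps:
            m = titration.replicate == r
            sub = FPTitration(
                mode="displacement",
                labeled_total_nM=titration.labeled_total_nM,
                conc=titration.conc[m], polarization=titration.polarization[m],
                protein_total=titration.protein_total,
            )
            ic50_r, _, _, nd_r = fit_displacement(sub, bottom=mP_free)
            if not nd_r:
                ki_r, _ = ic50_to_kd(
                    ic50_r, K_D_label, titration.protein_total, titration.labeled_total_nM
                )
                per_rep.append(ki_r)

    ic50, ic50_err, hill, no_disp = fit_displacement(titration, bottom=mP_free)
    if no_disp:
        return CompetitionResult(
            IC50=ic50, IC50_err=ic50_err, hill_slope=hill,
            K_D_competitor=math.nan, K_D_competitor_err=math.nan,
            no_displacement=True, K_D_label=K_D_label,
            protein_total=titration.protein_total,
            labeled_total_nM=titration.labeled_total_nM,
        )
    ki, tight = ic50_to_kd(
        ic50, K_D_label, titration.protein_total, titration.labeled_total_nM
    )
    if len(per_rep) >= 2:
        ki_err = float(np.std(per_rep, ddof=1) / math.sqrt(len(per_rep)))
    elif np.isfinite(ic50_err):
        ki_err = ki * ic50_err / ic50
    else:
        ki_err = math.nan
    return CompetitionResult(
        IC50=ic50, IC50_err=ic50_err, hill_slope=hill,
        K_D_competitor=ki, K_D_competitor_err=ki_err, tight_binding=tight,
        K_D_label=K_D_label, protein_total=titration.protein_total,
        labeled_total_nM=titration.labeled_total_nM,
    )
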