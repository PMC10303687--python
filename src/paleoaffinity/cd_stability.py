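"""Two-state chemical denaturation analysis of CD unfolding curves.

The CD signal at 222 nm versus GdnCl concentration is fitted to the
standard two-state (native <=> denatured) model with linear baselines:

    Y([D]) = [ (aN + bN [D]) + (aD + bD [D]) exp( m ([D] - D50) / RT ) ]
             / [ 1 + exp( m ([D] - D50) / RT ) ]

where m (kcal mol^-1 M^-1) is the denaturant dependence of the unfolding
free energy and D50 (M) the midpoint.  A cooperative sigmoid inside the
measured range certifies a folded domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

from .kinetics import FitError

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL = 1.987e-3


@dataclass
class DenaturationCurve:
    """CD signal versus denaturant concentration at fixed temperature."""

    denaturant: np.ndarray      # M GdnCl, increasing, within 0-6 M
    signal: np.ndarray          # CD at 222 nm, mdeg
    temperature_C: float = 25.0

    def __post_init__(self):
        self.denaturant = np.asarray(self.denaturant, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.denaturant.shape != self.signal.shape:
            raise ValueError("denaturant and signal must have equal length")
        if self.denaturant.size < 8:
            raise ValueError("a denaturation curve needs at least 8 points")
        if np.any(self.denaturant < 0):
            raise ValueError("denaturant concentrations must be non-negative")
        if np.any(np.diff(self.denaturant) <= 0):
            raise ValueError("denaturant concentrations must be increasing")

    @property
    def RT(self) -> float:
        return R_KCAL * (self.temperature_C + 273.15)


@dataclass
class StabilityFit:
    """Two-state fit: m-value, midpoint, baselines and a cooperativity verdict."""

    m_DN: float                 # kcal mol^-1 M^-1
    m_DN_err: float
    D50: float                  # M
    D50_err: float
    native_baseline: tuple[float, float]     # (intercept, slope)
    denatured_baseline: tuple[float, float]
    residual_rms: float
    verdict: str = "folded"     # "folded" | "unresolved"
    notes: list[str] = field(default_factory=list)

    @property
    def dG_H2O(self) -> float:
        """Unfolding free energy in water, m * D50 (kcal/mol)."""
        return self.m_DN * self.D50


def two_state_signal(D, m, D50, aN, bN, aD, bD, RT):
    """Model CD signal for the two-state unfolding equilibrium."""
    expo = np.exp(np.clip(m * (D - D50) / RT, -500, 500))
    return ((aN + bN * D) + (aD + bD * D) * expo) / (1.0 + expo)


def fraction_unfolded(D, m, D50, RT):
    expo = np.exp(np.clip(m * (D - D50) / RT, -500, 500))
    return expo / (1.0 + expo)


def fit_two_state(curve: DenaturationCurve, flat_baselines: bool = False) -> StabilityFit:
    """Least-squares two-state fit of a denaturation curve.

    ``flat_baselines=True`` fixes both baseline slopes at zero (sensitivity
    mode).  When the fit cannot place a positive-m transition inside the
    measured denaturant range the verdict is "unresolved"; a midpoint in
    the outer 10% of the range additionally carries an extrapolation note.
    """
    D, y = curve.denaturant, curve.signal
    RT = curve.RT
    span = float(y.max() - y.min())
    mid0 = float(D[np.argmin(np.abs(y - (y.max() + y.min()) / 2.0))])

    params = Parameters()
    params.add("m", value=2.0, min=1e-3, max=50.0)
    params.add("D50", value=max(mid0, 0.1), min=0.0, max=float(D.max()) * 2.0)
    params.add("aN", value=float(y[0]))
    params.add("aD", value=float(y[-1]))
    params.add("bN", value=0.0, vary=not flat_baselines)
    params.add("bD", value=0.0, vary=not flat_baselines)

    def residual(p):
        return two_state_signal(
            D, p["m"].value, p["D50"].value, p["aN"].value, p["bN"].value,
            p["aD"].value, p["bD"].value, RT,
        ) - y

    res = minimize(residual, params)
    if not res.success:
        raise FitError(f"two-state fit did not converge: {res.message}")
    m = float(res.params["m"].value)
    d50 = float(res.params["D50"].value)
    rms = float(np.sqrt(np.mean(res.residual**2)))

    notes: list[str] = []
    verdict = "folded"
    amplitude = abs(
        (res.params["aD"].value + res.params["bD"].value * d50)
        - (res.params["aN"].value + res.params["bN"].value * d50)
    )
    noise = max(rms, 1e-12)
    interior = D.min() < d50 < D.max()

    # a cooperative transition must beat a plain straight line (AICc):
    # flexible baselines can absorb a line into a sham sigmoid
    n = D.size
    rss_two_state = float(np.sum(res.residual**2))
    slope, icept = np.polyfit(D, y, 1)
    rss_line = float(np.sum((icept + slope * D - y) ** 2))
    n_par = 4 if flat_baselines else 6

    def aicc(rss, k):
        if n - k - 1 <= 0:
            return np.inf
        return n * np.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)

    cooperative = aicc(rss_two_state, n_par) < aicc(rss_line, 2)
    if m <= 0 or not interior or amplitude < 3 * noise or span == 0 or not cooperative:
        verdict = "unresolved"
        if not interior:
            notes.append("midpoint outside the measured denaturant range")
        if amplitude < 3 * noise:
            notes.append("transition amplitude indistinguishable from noise")
        if not cooperative:
            notes.append("no cooperative transition: a straight line fits as well")
    elif d50 > D.max() - 0.1 * (D.max() - D.min()):
        notes.append("midpoint near the end of the range; post-transition baseline extrapolated")
        verdict = "unresolved"

    # widen sigma estimates when a baseline region is data-starved
    frac = fraction_unfolded(D, m, d50, RT)
    n_native = int(np.sum(frac < 0.05))
    n_denat = int(np.sum(frac > 0.95))
    m_err = float(res.params["m"].stderr or np.nan)
    d50_err = float(res.params["D50"].stderr or np.nan)
    if not flat_baselines and (n_native < 3 or n_denat < 3):
        notes.append("fewer than 3 points in a baseline region; uncertainties inflated 2x")
        m_err *= 2.0
        d50_err *= 2.0

    return StabilityFit(
        m_DN=m, m_DN_err=m_err, D50=d50, D50_err=d50_err,
        native_baseline=(float(res.params["aN"].value), float(res.params["bN"].value)),
        denatured_baseline=(float(res.params["aD"].value), float(res.params["bD"].value)),
        residual_rms=rms, verdict=verdict, notes=notes,
    )


def cooperativity_check(fit: StabilityFit) -> str:
    """'folded' iff the fit shows a cooperative transition inside the data range."""
    return fit.verdict
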