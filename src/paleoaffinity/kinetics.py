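"""Stopped-flow binding kinetics: k_obs extraction and rate-constant fits.

The observed relaxation rate of a reversible bimolecular association
A + B <=> C, mixed at total concentrations A0 and B0, is

    k_obs = sqrt( (k_on (A0 + B0) + k_off)^2 - 4 k_on^2 A0 B0 )

which reduces to the familiar pseudo-first-order line
k_obs = k_on [B] + k_off when one reactant is in large excess.  Association
experiments (k_obs versus ligand concentration at fixed protein) are fitted
to this form to obtain k_on; displacement experiments yield k_off as the
plateau of k_obs at saturating displacer; K_D = k_off / k_on.

Units are fixed throughout: concentrations in uM, rates in 1/s, k_on in
1/(uM s), K_D in uM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from lmfit import Parameters, minimize
from lmfit.models import ExpressionModel


class FitError(RuntimeError):
    """Raised when a least-squares fit fails to converge or is ill-posed."""


# ---------------------------------------------------------------------------
# data containers

@dataclass
class KineticTrace:
    """A single stopped-flow fluorescence trace."""

    time: np.ndarray          # s, strictly increasing
    signal: np.ndarray        # arbitrary fluorescence units
    protein_total: float      # uM
    ligand_total: float       # uM

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape or self.time.ndim != 1:
            raise ValueError("time and signal must be 1-D arrays of equal length")
        if self.time.size < 10:
            raise ValueError("a trace needs at least 10 points")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.protein_total <= 0 or self.ligand_total <= 0:
            raise ValueError("concentrations must be positive")


@dataclass
class ExpFit:
    """Single-exponential fit result for one trace."""

    k_obs: float
    k_obs_err: float
    amplitude: float
    amplitude_err: float
    offset: float
    residual_rms: float
    no_signal: bool = False


@dataclass
class AssociationSeries:
    """k_obs versus ligand concentration at fixed protein concentration."""

    protein_total: float                       # uM
    points: list[tuple[float, float, float]]   # (ligand_uM, k_obs, sigma)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.protein_total <= 0:
            raise ValueError("protein_total must be positive")
        concs = [c for c, _, _ in self.points]
        if len(set(concs)) < 4:
            raise ValueError("association series needs >= 4 distinct ligand concentrations")
        lo, hi = min(concs), max(concs)
        if lo < 1.0 or hi > 10.0:
            self.warnings.append(
                f"ligand range {lo:g}-{hi:g} uM outside the nominal 1-10 uM regime"
            )


@dataclass
class DisplacementSeries:
    """k_obs versus displacer concentration over a pre-formed complex."""

    complex_conc: tuple[float, float]          # (protein_uM, ligand_uM)
    points: list[tuple[float, float, float]]   # (displacer_uM, k_obs, sigma)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.points) < 3:
            raise ValueError("displacement series needs >= 3 displacer concentrations")
        if min(d for d, _, _ in self.points) <= max(self.complex_conc):
            self.warnings.append("displacer not in excess over the complex")


@dataclass
class RateEstimate:
    """(k_on, k_off, K_D) with propagated uncertainties."""

    k_on: float
    k_on_err: float
    k_off: float
    k_off_err: float
    K_D: float
    K_D_err: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("rate constants must be positive")
        if not math.isclose(self.K_D, self.k_off / self.k_on, rel_tol=0, abs_tol=0):
            raise ValueError("K_D must equal k_off / k_on exactly")


# ---------------------------------------------------------------------------
# fits

def fit_single_exponential(trace: KineticTrace) -> ExpFit:
    """Fit signal(t) = offset + amplitude * exp(-k_obs t) by least squares.

    A trace whose fitted amplitude is indistinguishable from zero
    (|amplitude| < 3 x its standard error) is flagged ``no_signal`` —
    the operational rule for "no change in fluorescence upon mixing".
    """
    t, y = trace.time, trace.signal
    offset0 = float(y[-1])
    amp0 = float(y[0] - y[-1])
    span = y.max() - y.min()
    if span == 0 or abs(amp0) < 1e-12 * max(1.0, abs(offset0)):
        amp0 = span if span > 0 else 1e-9
    # crude rate guess from the time to lose ~63% of the amplitude
    k0 = 1.0 / max(t[len(t) // 3] - t[0], (t[-1] - t[0]) / 10)

    model = ExpressionModel("offset + amplitude * exp(-k_obs * x)")
    params = model.make_params(offset=offset0, amplitude=amp0, k_obs=k0)
    params["k_obs"].set(min=1e-12)
    try:
        res = model.fit(y, params, x=t)
    except Exception as exc:  # pragma: no cover - lmfit raises rarely here
        raise FitError(f"single-exponential fit failed: {exc}") from exc
    if not res.success:
        raise FitError(f"single-exponential fit did not converge: {res.message}")

    k = float(res.params["k_obs"].value)
    k_err = float(res.params["k_obs"].stderr or np.inf)
    amp = float(res.params["amplitude"].value)
    amp_err = res.params["amplitude"].stderr
    amp_err = float(amp_err) if amp_err is not None else np.inf
    rms = float(np.sqrt(np.mean(res.residual**2)))
    no_signal = (not np.isfinite(amp_err)) or abs(amp) < 3 * amp_err
    return ExpFit(
        k_obs=k, k_obs_err=k_err, amplitude=amp, amplitude_err=amp_err,
        offset=float(res.params["offset"].value), residual_rms=rms,
        no_signal=bool(no_signal),
    )


def kobs_reversible(A0, B0, k_on: float, k_off: float):
    """Relaxation rate of A + B <=> C without the pseudo-first-order assumption.

    All concentrations in uM; k_on in 1/(uM s), k_off in 1/s.  Symmetric in
    (A0, B0); reduces to k_on*A0 + k_off at B0 = 0.
    """
    A0 = np.asarray(A0, dtype=float)
    B0 = np.asarray(B0, dtype=float)
    if np.any(A0 < 0) or np.any(B0 < 0) or k_on < 0 or k_off < 0:
        raise ValueError("concentrations and rate constants must be >= 0")
    radicand = (k_on * (A0 + B0) + k_off) ** 2 - 4.0 * k_on**2 * A0 * B0
    out = np.sqrt(np.clip(radicand, 0.0, None))
    return float(out) if out.ndim == 0 else out


def fit_association(series: AssociationSeries) -> tuple[tuple[float, float], tuple[float, float]]:
    """Fit (k_on, k_off) to a k_obs-versus-ligand series.

    Weighted least squares of :func:`kobs_reversible` with the protein
    concentration fixed at the series value; inverse-variance weights when
    per-point sigmas are available.  Returns ((k_on, sigma), (k_off, sigma));
    the intercept k_off is poorly determined by association data alone and
    is usually superseded by a displacement measurement.
    """
    conc = np.array([c for c, _, _ in series.points])
    kobs = np.array([k for _, k, _ in series.points])
    sig = np.array([s for _, _, s in series.points])
    if len(conc) < 3:
        raise FitError("need at least 3 points to fit (k_on, k_off)")
    weights = 1.0 / sig if np.all(sig > 0) else np.ones_like(kobs)

    slope0 = max((kobs[-1] - kobs[0]) / (conc[-1] - conc[0]), 1e-6)
    icept0 = max(kobs[0] - slope0 * conc[0], 1e-6)
    params = Parameters()
    params.add("k_on", value=slope0, min=1e-9)
    params.add("k_off", value=icept0, min=0.0)

    def residual(p):
        model = kobs_reversible(series.protein_total, conc, p["k_on"].value, p["k_off"].value)
        return (model - kobs) * weights

    res = minimize(residual, params)
    if not res.success:
        raise FitError(f"association fit did not converge: {res.message}")
    k_on = float(res.params["k_on"].value)
    k_on_err = float(res.params["k_on"].stderr or np.nan)
    k_off = float(res.params["k_off"].value)
    k_off_err = float(res.params["k_off"].stderr or np.nan)
    return (k_on, k_on_err), (k_off, k_off_err)


@dataclass
class DisplacementFit:
    """k_off from the plateau of a displacement series."""

    k_off: float
    k_off_err: float
    k_half: float             # displacer concentration at half-plateau
    baseline: float
    extrapolated: bool        # True when the data never reach the plateau
    sigma_source: str         # "replicates" | "fit"


def _plateau_mean(D: np.ndarray, kobs: np.ndarray) -> tuple[float, float]:
    """Mean and spread of k_obs over the two highest displacer concentrations."""
    top_two = np.sort(np.unique(D))[-2:]
    sel = np.isin(D, top_two)
    vals = kobs[sel]
    err = float(np.std(vals, ddof=1)) if vals.size >= 2 else np.nan
    return float(np.mean(vals)), err


def koff_from_displacement(series: DisplacementSeries, mode: str = "hyperbola") -> DisplacementFit:
    """Estimate k_off as the high-displacer plateau of k_obs.

    mode="hyperbola" (default) fits
    k_obs([D]) = baseline + (k_off - baseline) [D] / (k_half + [D]) and
    reports the asymptote — but only when the series actually rises: a
    series already sitting on its plateau carries no information about
    k_half, so when the constant model is preferred by AICc the estimate
    falls back to the mean k_obs over the two highest concentrations (the
    "at high displacer, k_obs equals k_off" reading of the experiment).
    mode="plateau_mean" forces that average as a cross-check.  A fitted
    half-saturation point beyond half the top displacer concentration means
    the plateau was never reached and the value is flagged ``extrapolated``.
    Sigma comes from the spread of replicate points at the top concentration
    when replicates exist, otherwise from the fit covariance.
    """
    D = np.array([d for d, _, _ in series.points])
    kobs = np.array([k for _, k, _ in series.points])
    sig = np.array([s for _, _, s in series.points])
    weights = 1.0 / sig if np.all(sig > 0) else np.ones_like(kobs)

    top = D.max()
    top_kobs = kobs[D == top]
    replicated = top_kobs.size >= 2

    if mode == "plateau_mean":
        k_off, err = _plateau_mean(D, kobs)
        return DisplacementFit(k_off=k_off, k_off_err=err, k_half=np.nan,
                               baseline=np.nan, extrapolated=False,
                               sigma_source="replicates" if replicated else "fit")
    if mode != "hyperbola":
        raise ValueError(f"unknown mode {mode!r}")

    params = Parameters()
    params.add("k_off", value=float(kobs.max()), min=1e-12, max=3.0 * float(kobs.max()))
    params.add("k_half", value=float(top) / 10.0, min=0.0, max=2.0 * float(top))
    params.add("baseline", value=float(kobs.min()), min=0.0)

    def residual(p):
        model = p["baseline"].value + (p["k_off"].value - p["baseline"].value) * D / (
            p["k_half"].value + D
        )
        return (model - kobs) * weights

    res = minimize(residual, params)
    if not res.success:
        raise FitError(f"displacement fit did not converge: {res.message}")

    # is there a detectable rise at all?  AICc against the constant model
    n = kobs.size
    rss_hyp = float(np.sum(res.residual**2))
    wmean = float(np.sum(kobs * weights**2) / np.sum(weights**2))
    rss_const = float(np.sum(((kobs - wmean) * weights) ** 2))

    def aicc(rss, k):
        if n - k - 1 <= 0:
            return np.inf
        return n * math.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)

    if aicc(rss_const, 1) <= aicc(rss_hyp, 3):
        k_off, spread = _plateau_mean(D, kobs)
        err = spread if replicated else float(res.params["k_off"].stderr or np.nan)
        return DisplacementFit(
            k_off=k_off, k_off_err=err, k_half=float("nan"), baseline=wmean,
            extrapolated=False, sigma_source="replicates" if replicated else "fit",
        )

    k_off = float(res.params["k_off"].value)
    fit_err = float(res.params["k_off"].stderr or np.nan)
    k_half = float(res.params["k_half"].value)
    extrapolated = k_half > top / 2.0
    if replicated and not extrapolated:
        err, source = float(np.std(top_kobs, ddof=1)), "replicates"
    else:
        err, source = fit_err, "fit"
    if extrapolated:
        series.warnings.append(
            f"displacement series not saturating (half-point {k_half:.3g} uM vs "
            f"top displacer {top:.3g} uM); k_off is an extrapolation"
        )
    return DisplacementFit(
        k_off=k_off, k_off_err=err, k_half=k_half,
        baseline=float(res.params["baseline"].value),
        extrapolated=bool(extrapolated), sigma_source=source,
    )


def compute_kd(
    k_on: float, k_on_err: float, k_off: float, k_off_err: float,
    provenance: dict | None = None,
) -> RateEstimate:
    """K_D = k_off / k_on with relative errors propagated in quadrature."""
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rate constants must be positive")
    kd = k_off / k_on
    rel = math.sqrt((k_on_err / k_on) ** 2 + (k_off_err / k_off) ** 2)
    return RateEstimate(
        k_on=k_on, k_on_err=k_on_err, k_off=k_off, k_off_err=k_off_err,
        K_D=kd, K_D_err=kd * rel, provenance=provenance or {},
    )


# ---------------------------------------------------------------------------
# significant-figure helpers (table-style reporting)

def round_sig(x: float, n_sig: int) -> float:
    """Round ``x`` to ``n_sig`` significant figures, halves away from zero."""
    if x == 0:
        return 0.0
    d = Decimal(repr(float(x)))
    exponent = d.adjusted()  # floor(log10(|x|))
    quantum = Decimal(1).scaleb(exponent - n_sig + 1)
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


def format_sig(x: float, n_sig: int) -> str:
    """Format ``x`` at ``n_sig`` significant figures, keeping trailing zeros."""
    if x == 0:
        return "0"
    exponent = Decimal(repr(float(x))).adjusted()
    decimals = max(n_sig - 1 - exponent, 0)
    return f"{round_sig(x, n_sig):.{decimals}f}"
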