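"""Isotopologue arithmetic for ¹³C labeling experiments.

Fractional enrichment from isotopologue intensity spectra, correction for
natural ¹³C abundance, standard-addition and external-standard
quantification, and the mapping of PTR-MS mass channels (m/z 69-74) to
isoprene isotopologues M+0 ... M+5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import comb
from scipy.stats import linregress
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "IsotopologueSpectrum",
    "StandardAdditionPair",
    "PtrmsTrace",
    "NaturalAbundanceCorrector",
    "enrichment_fraction",
    "natural_abundance_matrix",
    "correct_natural_abundance",
    "standard_addition_amount",
    "external_standard_quantify",
    "isoprene_channels_to_spectrum",
    "normalize_ptrms",
    "emission_rate",
    "NATURAL_13C_ABUNDANCE",
    "ISOPRENE_CARBONS",
]

#: natural abundance of ¹³C
NATURAL_13C_ABUNDANCE = 0.0107
ISOPRENE_CARBONS = 5
#: conventional PTR-MS normalization references
REFERENCE_PRIMARY_CPS = 1.0e6
REFERENCE_DRIFT_PRESSURE = 2.2  # mbar


@dataclass(frozen=True)
class IsotopologueSpectrum:
    """Intensities of the M+0 ... M+n isotopologues of an n-carbon analyte."""

    carbon_count: int
    intensities: np.ndarray
    analyte_id: str = ""

    def __post_init__(self) -> None:
        if self.carbon_count < 1:
            raise ValueError("carbon_count must be >= 1")
        x = np.asarray(self.intensities, dtype=float)
        if x.ndim != 1 or x.size != self.carbon_count + 1:
            raise ValueError(
                f"intensities must have length carbon_count + 1 = {self.carbon_count + 1}"
            )
        if np.any(x < 0):
            raise ValueError("intensities must be >= 0")
        object.__setattr__(self, "intensities", x)

    @property
    def total(self) -> float:
        return float(self.intensities.sum())


@dataclass(frozen=True)
class StandardAdditionPair:
    """Signals of one sample run without and with a known unlabeled spike."""

    signal_unspiked: float
    signal_spiked: float
    spike_amount: float  # ng
    analyte_id: str = ""

    def __post_init__(self) -> None:
        if self.spike_amount <= 0:
            raise ValueError("spike_amount must be > 0")
        if self.signal_unspiked < 0 or self.signal_spiked < 0:
            raise ValueError("signals must be >= 0")


@dataclass(frozen=True)
class PtrmsTrace:
    """PTR-MS channel traces for isoprene and its ¹³C isotopologues.

    ``channel_cps`` has one row per time point and one column per mass
    channel m/z 69 ... 74 (protonated isoprene M+0 ... M+5).
    """

    times: np.ndarray
    channel_cps: np.ndarray
    primary_ion_cps: np.ndarray
    water_cluster_cps: np.ndarray
    drift_pressure: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        ch = np.asarray(self.channel_cps, dtype=float)
        if ch.ndim != 2 or ch.shape != (t.size, ISOPRENE_CARBONS + 1):
            raise ValueError("channel_cps must be (n_times, 6): m/z 69..74")
        if np.any(ch < 0):
            raise ValueError("channel counts must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "channel_cps", ch)
        for name in ("primary_ion_cps", "water_cluster_cps", "drift_pressure"):
            v = np.broadcast_to(np.asarray(getattr(self, name), dtype=float), t.shape).copy()
            object.__setattr__(self, name, v)


def enrichment_fraction(spec: IsotopologueSpectrum) -> float:
    """Fraction of ¹³C among all carbon atoms of the analyte pool.

    Sums the ¹³C atoms carried by each isotopologue (i atoms in M+i,
    weighted by its intensity) and divides by the total number of carbon
    atoms, n times the summed intensity.
    """
    total = spec.total
    if total <= 0:
        raise ValueError("total intensity must be > 0 for enrichment computation")
    shifts = np.arange(spec.carbon_count + 1)
    return float((shifts * spec.intensities).sum() / (spec.carbon_count * total))


def natural_abundance_matrix(n: int, p: float = NATURAL_13C_ABUNDANCE) -> np.ndarray:
    """Binomial natural-abundance convolution operator for an n-carbon analyte.

    Column j gives the mass-shift distribution produced when the n - j
    carbons not labeled by the tracer each carry ¹³C with probability p:
    entry (j + k, j) = C(n-j, k) p^k (1-p)^(n-j-k).  Columns sum to 1, so
    the operator conserves total intensity.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p < 0.5:
        raise ValueError("p must be in [0, 0.5)")
    mat = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        k = np.arange(n - j + 1)
        # explicit binomial pmf: stable for any p in [0, 0.5), small n
        mat[j + k, j] = comb(n - j, k) * p**k * (1.0 - p) ** (n - j - k)
    return mat


class NaturalAbundanceCorrector(TransformerMixin, BaseEstimator):
    """Remove natural ¹³C abundance from isotopologue spectra.

    Solves the lower-triangular linear system M · corrected = observed,
    where M is the binomial convolution operator over the tracer-unlabeled
    carbons.  Small negative solutions (measurement noise) are clamped to
    zero and the spectrum renormalized to its observed total; a warning is
    issued when clamping removes more than 5% of the signal.

    Parameters
    ----------
    carbon_count : number of carbons n of the analyte
    p : natural ¹³C abundance, default 0.0107
    """

    def __init__(self, carbon_count: int = ISOPRENE_CARBONS,
                 p: float = NATURAL_13C_ABUNDANCE) -> None:
        self.carbon_count = carbon_count
        self.p = p

    def fit(self, X=None, y=None):
        self.matrix_ = natural_abundance_matrix(self.carbon_count, self.p)
        self.n_features_in_ = self.carbon_count + 1
        return self

    def transform(self, X):
        """Correct spectra.  ``X``: (n_samples, n+1) intensities."""
        check_is_fitted(self, "matrix_")
        x = np.atleast_2d(np.asarray(X, dtype=float))
        if x.shape[1] != self.carbon_count + 1:
            raise ValueError(f"expected {self.carbon_count + 1} intensity columns")
        out = np.empty_like(x)
        for i, row in enumerate(x):
            sol = solve_triangular(self.matrix_, row, lower=True)
            neg = sol < 0
            if np.any(neg):
                removed = -sol[neg].sum()
                total = sol.sum()
                sol = np.clip(sol, 0.0, None)
                if total > 0 and removed > 0.05 * total:
                    warnings.warn(
                        f"natural-abundance correction clamped "
                        f"{100 * removed / total:.1f}% of total signal",
                        UserWarning,
                        stacklevel=2,
                    )
                if sol.sum() > 0:
                    sol *= row.sum() / sol.sum()
            out[i] = sol
        return out

    def inverse_transform(self, X):
        """Re-apply the natural-abundance convolution (for simulation)."""
        check_is_fitted(self, "matrix_")
        x = np.atleast_2d(np.asarray(X, dtype=float))
        return x @ self.matrix_.T


def correct_natural_abundance(
    spec: IsotopologueSpectrum, p: float = NATURAL_13C_ABUNDANCE
) -> IsotopologueSpectrum:
    """Natural-abundance-corrected copy of a spectrum."""
    corr = NaturalAbundanceCorrector(spec.carbon_count, p).fit()
    out = corr.transform(spec.intensities[None, :])[0]
    return IsotopologueSpectrum(spec.carbon_count, out, spec.analyte_id)


def standard_addition_amount(pair: StandardAdditionPair) -> float:
    """Analyte amount (ng) from an unlabeled-standard addition pair.

    The spike's signal increment calibrates the response:
    amount = spike x unspiked / (spiked - unspiked).
    """
    delta = pair.signal_spiked - pair.signal_unspiked
    if delta <= 0:
        raise ValueError("spike not recovered: spiked signal must exceed unspiked")
    return pair.spike_amount * pair.signal_unspiked / delta


def external_standard_quantify(signal: float, curve) -> float:
    """Concentration by inverse prediction on a linear calibration curve.

    ``curve`` is a sequence of (concentration, signal) points; an ordinary
    least-squares line is fitted and inverted.  A warning flags signals
    outside the calibrated response range.
    """
    pts = np.asarray(curve, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("curve needs >= 2 (concentration, signal) points")
    conc, resp = pts[:, 0], pts[:, 1]
    if np.ptp(conc) == 0:
        raise ValueError("degenerate calibration: all concentrations equal")
    fit = linregress(conc, resp)
    if fit.slope == 0:
        raise ValueError("calibration slope is zero")
    if not resp.min() <= signal <= resp.max():
        warnings.warn("signal outside calibrated range; extrapolating",
                      UserWarning, stacklevel=2)
    return float((signal - fit.intercept) / fit.slope)


def isoprene_channels_to_spectrum(trace: PtrmsTrace, t_index: int) -> IsotopologueSpectrum:
    """Isoprene isotopologue spectrum at one time point of a PTR-MS trace.

    Channel m/z 69 + k maps to isotopologue M+k of protonated isoprene
    (C5H9+), k = 0 ... 5.
    """
    row = trace.channel_cps[t_index]
    return IsotopologueSpectrum(ISOPRENE_CARBONS, row, "isoprene")


def normalize_ptrms(
    cps,
    primary_cps,
    water_cluster_cps,
    drift_pressure,
    reference_pressure: float = REFERENCE_DRIFT_PRESSURE,
    reference_primary: float = REFERENCE_PRIMARY_CPS,
):
    """Normalized counts per second (ncps).

    Raw counts are scaled to a reference primary-ion level (primary ion +
    water cluster) and to a reference drift-tube pressure.
    """
    denom = np.asarray(primary_cps, dtype=float) + np.asarray(water_cluster_cps, dtype=float)
    press = np.asarray(drift_pressure, dtype=float)
    if np.any(denom <= 0):
        raise ValueError("primary + water-cluster counts must be > 0")
    if np.any(press <= 0) or reference_pressure <= 0:
        raise ValueError("pressures must be > 0")
    out = np.asarray(cps, dtype=float) * (reference_primary / denom) * (reference_pressure / press)
    return float(out) if np.ndim(out) == 0 else out


def emission_rate(
    steady_ncps: float,
    background_ncps: float,
    calibration_slope: float,
    dry_weight: float,
) -> float:
    """Isoprene emission rate, nmol g⁻¹ DW min⁻¹.

    Background (empty chamber) is subtracted from the steady-state
    normalized signal before applying the gas-standard calibration and
    dividing by needle dry weight.
    """
    if dry_weight <= 0:
        raise ValueError("dry_weight must be > 0")
    if calibration_slope <= 0:
        raise ValueError("calibration_slope must be > 0")
    net = steady_ncps - background_ncps
    if net < 0:
        warnings.warn("background exceeds signal; emission floored at 0",
                      UserWarning, stacklevel=2)
        net = 0.0
    return net * calibration_slope / dry_weight
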