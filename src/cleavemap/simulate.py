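"""Synthetic-data generators for end-to-end testing of the pipeline.

Three generators emulate the statistical structure of the three input
kinds the analysis consumes:

* ``simulate_digest_peaks`` — an in-silico digest turned into a noisy peak
  list: true fragment [M+H]+ masses perturbed by additive Gaussian mass
  error (Da-scale, matching instrument discrepancies of a few mDa to tens
  of mDa), thinned by random dropout, and contaminated with spurious peaks
  uniform over a mass window.  Ground-truth spans are returned alongside.
* ``simulate_dose_response`` — logistic mean response plus i.i.d. Gaussian
  noise on a geometric dilution grid (default: 250 nM top dose, 5-fold
  dilution, 10 steps).
* ``simulate_pk_profile`` — a one-compartment first-order absorption /
  elimination (Bateman) curve, C(t) = A (e^(-ke t) - e^(-ka t)), with
  additive noise clipped at zero.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assignment import ObservedPeak
from .digestion import ProteaseRule, digest_partial
from .peptide import FragmentSpan, PeptideSequence, protonated_mass
from .pharmacology import DoseResponseDataset, PKSeries

__all__ = [
    "DigestSimSpec",
    "PKSimSpec",
    "simulate_digest_peaks",
    "simulate_dose_response",
    "simulate_pk_profile",
    "dilution_grid",
]


@dataclass(frozen=True)
class DigestSimSpec:
    """Parameters of a simulated digest peak list."""

    peptide: PeptideSequence
    rule: ProteaseRule
    max_missed: int = 0
    mass_error_sd: float = 0.0  # Da
    dropout_rate: float = 0.0
    n_spurious_peaks: int = 0
    spurious_mass_range: tuple[float, float] = (200.0, 3000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mass_error_sd < 0:
            raise ValueError("mass_error_sd must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_spurious_peaks < 0:
            raise ValueError("n_spurious_peaks must be >= 0")


def simulate_digest_peaks(
    spec: DigestSimSpec,
) -> tuple[list[ObservedPeak], list[FragmentSpan]]:
    """Generate a noisy peak list for a digest; returns (peaks, true spans).

    True spans are the partial digest of the peptide at ``max_missed``;
    each contributes one peak at its [M+H]+ mass plus N(0, mass_error_sd)
    noise, dropped with probability ``dropout_rate``.  Spurious peaks are
    drawn uniformly over ``spurious_mass_range``.  Retention times are
    synthetic ordinals (minutes) carried for format compatibility only.
    """
    rng = np.random.default_rng(spec.seed)
    true_spans = digest_partial(spec.peptide, spec.rule, spec.max_missed)
    peaks: list[ObservedPeak] = []
    label = 0
    for span in true_spans:
        if rng.random() < spec.dropout_rate:
            continue
        label += 1
        mass = protonated_mass(spec.peptide, span)
        if spec.mass_error_sd > 0:
            mass += rng.normal(0.0, spec.mass_error_sd)
        peaks.append(
            ObservedPeak(apparent_mass=mass, retention_time=float(label), label=label)
        )
    lo, hi = spec.spurious_mass_range
    for _ in range(spec.n_spurious_peaks):
        label += 1
        peaks.append(
            ObservedPeak(
                apparent_mass=float(rng.uniform(lo, hi)),
                retention_time=float(label),
                label=label,
            )
        )
    return peaks, true_spans


def dilution_grid(top: float = 250.0, fold: float = 5.0, steps: int = 10) -> np.ndarray:
    """Serial-dilution concentration grid, highest first (nM)."""
    return top / fold ** np.arange(steps)


def simulate_dose_response(
    baseline: float,
    emax: float,
    ec50: float,
    concentrations: np.ndarray | None = None,
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
) -> DoseResponseDataset:
    """Logistic mean response plus i.i.d. Gaussian noise on a dilution grid."""
    if not ec50 > 0:
        raise ValueError("ec50 must be > 0")
    if concentrations is None:
        concentrations = dilution_grid()
    c = np.repeat(np.asarray(concentrations, dtype=float), replicates)
    mean = baseline + (emax - baseline) / (1.0 + ec50 / c)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=c.shape) if noise_sd > 0 else 0.0
    return DoseResponseDataset(concentrations=c, responses=mean + noise)


@dataclass(frozen=True)
class PKSimSpec:
    """Parameters of a simulated one-compartment concentration-time profile."""

    ka: float  # absorption rate, 1/h
    ke: float  # elimination rate, 1/h
    scale: float = 1.0  # amplitude A (ng/mL), absorbs dose/volume/F
    times: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0)
    noise_sd: float = 0.0
    route: str = "OG"
    dose: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.ke <= 0:
            raise ValueError("ka and ke must be > 0")
        if self.ka == self.ke:
            raise ValueError("ka must differ from ke (Bateman form is degenerate)")


def simulate_pk_profile(spec: PKSimSpec) -> PKSeries:
    """Bateman concentration-time profile with additive noise, clipped at 0.

    Noise-free peak time is ln(ka/ke)/(ka - ke); the noise-free AUC over an
    infinite horizon is A (1/ke - 1/ka).
    """
    t = np.asarray(spec.times, dtype=float)
    mean = spec.scale * (np.exp(-spec.ke * t) - np.exp(-spec.ka * t))
    rng = np.random.default_rng(spec.seed)
    conc = mean + (rng.normal(0.0, spec.noise_sd, size=t.shape) if spec.noise_sd > 0 else 0.0)
    return PKSeries(
        times=t,
        concentrations=np.clip(conc, 0.0, None),
        route=spec.route,
        dose=spec.dose,
    )
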