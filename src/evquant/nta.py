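"""Nanoparticle-tracking size distributions, peak calling and per-cell yield.

NTA instruments report a diameter for each tracked particle plus a total
particle concentration for the (possibly diluted) sample.  This module turns
per-particle diameters from several technical replicates into a binned
concentration density (particles ml^-1 nm^-1) with a t-based 95% confidence
band, calls peaks on the smoothed mean density, and normalizes EV counts to
the source culture as EVs per cell.

The per-replicate density is scaled so that summing ``density * bin_width``
over all bins returns exactly that replicate's dilution-corrected particle
concentration (mass conservation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal, stats

from .errors import ConfigurationError, EmptyInputError, ValidationError

DEFAULT_BIN_WIDTH_NM = 1.0
DEFAULT_SMOOTH_WINDOW = 5
DEFAULT_PROMINENCE_FRACTION = 0.1


@dataclass
class ParticleSample:
    """Diameters and concentration scaling for one technical replicate.

    ``concentration_scale`` is the particle concentration (ml^-1) of the
    measured sample; multiplied by ``dilution_factor`` it gives the
    concentration in the source preparation that the diameters represent.
    """

    diameters_nm: np.ndarray
    concentration_scale: float
    replicate_id: str = "rep1"
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        self.diameters_nm = np.asarray(self.diameters_nm, dtype=float)
        if self.diameters_nm.size == 0:
            raise EmptyInputError(f"replicate {self.replicate_id!r} has no particles")
        if np.any(self.diameters_nm <= 0):
            raise ValidationError(
                f"replicate {self.replicate_id!r} contains non-positive diameters"
            )
        if self.concentration_scale < 0:
            raise ValidationError("concentration_scale must be >= 0")
        if self.dilution_factor < 1:
            raise ValidationError("dilution_factor must be >= 1")

    @property
    def total_concentration(self) -> float:
        """Dilution-corrected particle concentration (ml^-1)."""
        return self.concentration_scale * self.dilution_factor


@dataclass
class SizeDistribution:
    """Replicate-averaged size distribution with confidence band and peaks."""

    bin_centers_nm: np.ndarray
    mean_density: np.ndarray  # particles ml^-1 nm^-1
    ci_low: np.ndarray
    ci_high: np.ndarray
    bin_width_nm: float
    n_replicates: int
    replicate_density: np.ndarray = field(repr=False, default=None)  # reps x bins
    detected_peaks_nm: np.ndarray = field(default_factory=lambda: np.array([]))


def _replicate_density(sample: ParticleSample, edges: np.ndarray) -> np.ndarray:
    counts, _ = np.histogram(sample.diameters_nm, bins=edges)
    width = edges[1] - edges[0]
    # counts/N is the fraction of the replicate's concentration in the bin
    return counts / sample.diameters_nm.size * sample.total_concentration / width


def size_distribution(
    samples: Sequence[ParticleSample],
    bin_width_nm: float = DEFAULT_BIN_WIDTH_NM,
    *,
    confidence: float = 0.95,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    min_prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
) -> SizeDistribution:
    """Bin, scale and average technical replicates; attach detected peaks.

    The confidence band is the t-interval of the per-bin replicate mean
    (``mean +- t_{1-(1-c)/2, n-1} * sd/sqrt(n)``); with a single replicate it
    collapses onto the mean.
    """
    if not samples:
        raise EmptyInputError("at least one particle sample is required")
    if bin_width_nm <= 0:
        raise ConfigurationError(f"bin width must be positive, got {bin_width_nm}")
    max_d = max(float(s.diameters_nm.max()) for s in samples)
    n_bins = int(np.ceil(max_d / bin_width_nm)) + 1
    edges = np.arange(n_bins + 1) * bin_width_nm
    centers = edges[:-1] + bin_width_nm / 2.0

    dens = np.vstack([_replicate_density(s, edges) for s in samples])
    mean = dens.mean(axis=0)
    n = dens.shape[0]
    if n > 1:
        sem = dens.std(axis=0, ddof=1) / np.sqrt(n)
        tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
        lo, hi = mean - tcrit * sem, mean + tcrit * sem
    else:
        lo, hi = mean.copy(), mean.copy()

    dist = SizeDistribution(
        bin_centers_nm=centers,
        mean_density=mean,
        ci_low=lo,
        ci_high=hi,
        bin_width_nm=bin_width_nm,
        n_replicates=n,
        replicate_density=dens,
    )
    dist.detected_peaks_nm = detect_peaks(
        dist, min_prominence_fraction=min_prominence_fraction, smooth_window=smooth_window
    )
    return dist


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered boxcar average; edges are averaged over the covered bins only."""
    if window <= 1:
        return y.astype(float)
    kernel = np.ones(window)
    num = np.convolve(y, kernel, mode="same")
    cov = np.convolve(np.ones_like(y, dtype=float), kernel, mode="same")
    return num / cov


def detect_peaks(
    distribution: SizeDistribution,
    min_prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> np.ndarray:
    """Peak diameters of the smoothed mean density, ascending.

    Local maxima are kept when their prominence reaches
    ``min_prominence_fraction`` times the global maximum of the smoothed
    density.  Peaks are reported at bin-center resolution.
    """
    if not (0.0 <= min_prominence_fraction <= 1.0):
        raise ConfigurationError("min_prominence_fraction must lie in [0, 1]")
    y = _moving_average(distribution.mean_density, smooth_window)
    top = float(y.max())
    if top <= 0:
        return np.array([])
    idx, _ = signal.find_peaks(y, prominence=min_prominence_fraction * top)
    return np.sort(distribution.bin_centers_nm[idx])


def evs_per_cell(ev_concentration: float, cell_concentration: float) -> float:
    """EVs per cell: EV concentration divided by cell concentration.

    Both concentrations must be on the same volume basis after dilution
    correction (e.g. particles ml^-1 of the source culture).
    """
    if cell_concentration <= 0:
        raise ValidationError(
            f"cell concentration must be positive, got {cell_concentration}"
        )
    if ev_concentration < 0:
        raise ValidationError(f"EV concentration must be >= 0, got {ev_concentration}")
    return ev_concentration / cell_concentration
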