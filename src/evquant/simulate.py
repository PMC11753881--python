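"""Seeded generators for synthetic inputs with the structure the pipeline assumes.

Four generators mirror the four kinds of raw measurement the analyses
consume:

* :func:`simulate_proteome` — log-normal protein intensities for two groups
  of replicates with a planted enriched subset, multiplicative replicate
  noise and abundance-dependent (left-censored) dropout.  Truth labels are
  returned alongside so detection can be scored.
* :func:`simulate_diel` — a deterministic growth/secretion/uptake time
  course over light-dark cycles, sampled at chosen times, with optional
  log-normal measurement noise per biological replicate.
* :func:`simulate_morphometry` — vesicle long/short axes from a two-component
  mixture of axis ratios (near-spherical vs elongated).
* :func:`simulate_nta` — per-particle diameters from a Gaussian mixture,
  Poisson particle counts per technical replicate.

Every generator takes an explicit seed through its config; no global random
state is touched, and identical configs give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .enrichment import AbundanceMatrix
from .errors import ConfigurationError
from .morphometry import EllipseMeasurement
from .nta import ParticleSample

TRUTH_NULL = "null"


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteomeSimConfig:
    """Two-group label-free proteome simulation.

    Defaults emulate a cell-lysate vs EV comparison: 998 proteins, three
    biological replicates per group, 217 proteins enriched in group 1 and
    23 in group 2 at a 4-fold (log2 = 2) planted effect.  Abundances are
    log-normal on the log2 scale (mean 20, sd 2, a typical MS intensity
    range); replicate noise is multiplicative with coefficient of variation
    ``noise_cv``; dropout probability is ``logistic(intercept +
    slope * log2 abundance)`` with a negative slope so low-abundance
    proteins are censored more often.
    """

    n_proteins: int = 998
    n_replicates_per_group: int = 3
    n_enriched_group1: int = 217
    n_enriched_group2: int = 23
    log2_effect: float = 2.0
    base_log_mean: float = 20.0
    base_log_sd: float = 2.0
    noise_cv: float = 0.1
    missing_logit_slope: float = -0.5
    missing_logit_intercept: float = 7.8
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_proteins,
            self.n_replicates_per_group,
            self.n_enriched_group1,
            self.n_enriched_group2,
        )
        if any(c < 0 for c in counts):
            raise ConfigurationError("all counts must be >= 0")
        if self.n_replicates_per_group < 1:
            raise ConfigurationError("need at least one replicate per group")
        if self.n_enriched_group1 + self.n_enriched_group2 > self.n_proteins:
            raise ConfigurationError(
                "planted enriched proteins exceed the number of proteins"
            )
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if self.base_log_sd < 0:
            raise ConfigurationError("base_log_sd must be >= 0")
        if self.missing_logit_slope > 0:
            raise ConfigurationError(
                "missing_logit_slope must be <= 0 (low abundance drops out more)"
            )


def simulate_proteome(
    config: ProteomeSimConfig,
    group_names: Tuple[str, str] = ("group1", "group2"),
) -> Tuple[AbundanceMatrix, pd.Series]:
    """Simulate an intensity matrix plus planted truth labels.

    Returns
    -------
    matrix
        ``AbundanceMatrix`` of ``n_proteins x 2*n_replicates_per_group``
        raw intensities with NaN for dropped-out cells.
    truth
        Per-protein labels ``{"null", "enriched_<group1>", "enriched_<group2>"}``.
    """
    rng = np.random.default_rng(config.seed)
    n, r = config.n_proteins, config.n_replicates_per_group
    g1, g2 = group_names

    proteins = [f"P{i:05d}" for i in range(1, n + 1)]
    order = rng.permutation(n)
    labels = np.full(n, TRUTH_NULL, dtype=object)
    labels[order[: config.n_enriched_group1]] = f"enriched_{g1}"
    labels[
        order[config.n_enriched_group1 : config.n_enriched_group1 + config.n_enriched_group2]
    ] = f"enriched_{g2}"
    truth = pd.Series(labels, index=proteins, name="truth")

    base = rng.normal(config.base_log_mean, config.base_log_sd, size=n)
    mean_log2 = np.tile(base[:, None], (1, 2 * r))
    mean_log2[labels == f"enriched_{g1}", :r] += config.log2_effect
    mean_log2[labels == f"enriched_{g2}", r:] += config.log2_effect

    # multiplicative log-normal noise with the requested CV
    sigma_log2 = math.sqrt(math.log1p(config.noise_cv**2)) / math.log(2)
    log2_vals = mean_log2 + rng.normal(0.0, sigma_log2, size=mean_log2.shape)
    values = np.exp2(log2_vals)

    p_miss = expit(config.missing_logit_intercept + config.missing_logit_slope * log2_vals)
    values[rng.random(size=values.shape) < p_miss] = np.nan

    samples = [f"{g1}_r{i + 1}" for i in range(r)] + [f"{g2}_r{i + 1}" for i in range(r)]
    data = pd.DataFrame(values, index=pd.Index(proteins, name="protein_id"), columns=samples)
    groups = pd.Series([g1] * r + [g2] * r, index=samples, name="group")
    return AbundanceMatrix(data, groups), truth


# ---------------------------------------------------------------------------
# diel time course
# ---------------------------------------------------------------------------

DEFAULT_SAMPLE_TIMES = (0.5, 12.0, 14.5, 16.0, 24.5)

# measurement noise (CV) for replicate concentration readings; back-calculated
# so that the paired light/dark contrast at n = 11 and the 3-replicate
# division-arrest contrast land in the significance regime the assays report
DEFAULT_MEASUREMENT_NOISE_CV = 0.05


@dataclass(frozen=True)
class DielSimConfig:
    """Phased growth/secretion/uptake model on a light-dark cycle.

    The process follows per-phase linear dynamics ``dC/dt = mu*C`` and
    ``dV/dt = s*C - u*V`` where C is cell and V is EV concentration
    (ml^-1), s the secretion rate (EVs cell^-1 h^-1), u the uptake rate
    (h^-1) and mu the growth rate (h^-1); the phase (light/dark) is set by
    time since first lights-on modulo 24 h.  Integration is explicit Euler
    with step ``dt``.  Defaults place division and the bulk of secretion in
    the 10 h dark phase, producing a falling EVs-per-cell ratio in the
    light and a rising one in the dark, starting from ~3 EVs per cell.

    ``sample_times`` are hours since first lights-on (values past 24 fall in
    the next cycle); ``noise_cv`` applies independent log-normal measurement
    noise to every sampled concentration of every replicate.
    """

    light_hours: float = 14.0
    dark_hours: float = 10.0
    growth_rate_light: float = 0.005
    growth_rate_dark: float = 0.07
    secretion_light: float = 0.05
    secretion_dark: float = 0.35
    uptake_light: float = 0.03
    uptake_dark: float = 0.02
    initial_cells: float = 1e8
    initial_evs: float = 3e8
    dt: float = 0.01
    noise_cv: float = 0.0
    n_replicates: int = 1
    sample_times: Tuple[float, ...] = DEFAULT_SAMPLE_TIMES
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            self.growth_rate_light,
            self.growth_rate_dark,
            self.secretion_light,
            self.secretion_dark,
            self.uptake_light,
            self.uptake_dark,
        )
        if any(r < 0 for r in rates):
            raise ConfigurationError("all rates must be >= 0")
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if abs(self.light_hours + self.dark_hours - 24.0) > 1e-9:
            raise ConfigurationError("light_hours + dark_hours must equal 24")
        if self.dt > min(self.light_hours, self.dark_hours):
            raise ConfigurationError("dt must not exceed the shorter phase length")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.initial_cells < 0 or self.initial_evs < 0:
            raise ConfigurationError("initial concentrations must be >= 0")
        if not self.sample_times:
            raise ConfigurationError("at least one sample time is required")
        if any(t < 0 for t in self.sample_times):
            raise ConfigurationError("sample times must be >= 0")


def _is_light(t: float, light_hours: float) -> bool:
    return (t % 24.0) < light_hours


def diel_trajectory(config: DielSimConfig) -> pd.DataFrame:
    """Deterministic Euler trajectory on the integration grid.

    Returns a frame with columns ``time_h``, ``cell_concentration``,
    ``ev_concentration`` covering [0, max(sample_times)].
    """
    t_end = max(config.sample_times)
    n_steps = int(round(t_end / config.dt))
    times = np.arange(n_steps + 1) * config.dt
    cells = np.empty(n_steps + 1)
    evs = np.empty(n_steps + 1)
    cells[0], evs[0] = config.initial_cells, config.initial_evs
    for k in range(n_steps):
        t = times[k]
        if _is_light(t, config.light_hours):
            mu, s, u = config.growth_rate_light, config.secretion_light, config.uptake_light
        else:
            mu, s, u = config.growth_rate_dark, config.secretion_dark, config.uptake_dark
        c = cells[k]
        evs[k + 1] = evs[k] + (s * c - u * evs[k]) * config.dt
        cells[k + 1] = c * (1.0 + mu * config.dt)
    return pd.DataFrame(
        {"time_h": times, "cell_concentration": cells, "ev_concentration": evs}
    )


def simulate_diel(config: DielSimConfig, treatment: str = "control") -> pd.DataFrame:
    """Sampled diel table: one row per (replicate, sample time).

    Columns: ``replicate_id``, ``treatment``, ``zeitgeber_time`` (hours since
    first lights-on; values past 24 belong to the next cycle),
    ``cell_concentration``, ``ev_concentration``.
    """
    traj = diel_trajectory(config)
    rng = np.random.default_rng(config.seed)
    idx = [int(round(t / config.dt)) for t in config.sample_times]
    base_c = traj["cell_concentration"].to_numpy()[idx]
    base_v = traj["ev_concentration"].to_numpy()[idx]

    sigma = math.sqrt(math.log1p(config.noise_cv**2)) if config.noise_cv > 0 else 0.0
    rows = []
    for r in range(1, config.n_replicates + 1):
        if sigma > 0:
            # mean-one log-normal noise, independent per measured concentration
            fc = rng.lognormal(-sigma**2 / 2.0, sigma, size=base_c.size)
            fv = rng.lognormal(-sigma**2 / 2.0, sigma, size=base_v.size)
        else:
            fc = fv = np.ones(base_c.size)
        for j, t in enumerate(config.sample_times):
            rows.append(
                {
                    "replicate_id": f"rep{r}",
                    "treatment": treatment,
                    "zeitgeber_time": t,
                    "cell_concentration": base_c[j] * fc[j],
                    "ev_concentration": base_v[j] * fv[j],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# morphometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorphometrySimConfig:
    """Vesicle axis generator: mixture of near-spherical and elongated shapes.

    The short/long axis ratio is drawn from a two-component Gaussian mixture
    (means ``axis_ratio_sphere_mean`` and ``axis_ratio_elong_mean``, common
    sd) and clipped to (0, 1]; the long axis is Gaussian in nm.  Defaults
    give 52 vesicles with ~65% elongated and a mean shape score near 0.6.
    """

    n_vesicles: int = 52
    frac_elongated: float = 0.65
    axis_ratio_sphere_mean: float = 0.92
    axis_ratio_elong_mean: float = 0.45
    axis_ratio_sd: float = 0.08
    diameter_mean_nm: float = 110.0
    diameter_sd_nm: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vesicles < 0:
            raise ConfigurationError("n_vesicles must be >= 0")
        if not (0.0 <= self.frac_elongated <= 1.0):
            raise ConfigurationError("frac_elongated must lie in [0, 1]")
        for ratio in (self.axis_ratio_sphere_mean, self.axis_ratio_elong_mean):
            if not (0.0 < ratio <= 1.0):
                raise ConfigurationError("axis ratio means must lie in (0, 1]")
        if self.axis_ratio_sd < 0:
            raise ConfigurationError("axis_ratio_sd must be >= 0")
        if self.diameter_mean_nm <= 0 or self.diameter_sd_nm < 0:
            raise ConfigurationError("diameter parameters must be positive")


def simulate_morphometry(config: MorphometrySimConfig) -> list[EllipseMeasurement]:
    """Draw long/short axis pairs; every row satisfies long >= short > 0."""
    rng = np.random.default_rng(config.seed)
    n = config.n_vesicles
    elongated = rng.random(n) < config.frac_elongated
    means = np.where(
        elongated, config.axis_ratio_elong_mean, config.axis_ratio_sphere_mean
    )
    ratios = np.clip(rng.normal(means, config.axis_ratio_sd), 1e-3, 1.0)
    longs = np.clip(
        rng.normal(config.diameter_mean_nm, config.diameter_sd_nm, size=n), 1.0, None
    )
    return [
        EllipseMeasurement(
            vesicle_id=f"v{i + 1:04d}",
            longer_diameter_nm=float(longs[i]),
            shorter_diameter_nm=float(longs[i] * ratios[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# NTA particle sizes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NtaSimConfig:
    """Gaussian-mixture particle diameters over technical replicates.

    Defaults plant the two-mode EV size structure (77 and 110 nm, equal
    weight, 8 nm spread) at a dilution-corrected concentration of
    3.3e8 particles ml^-1.
    """

    modes_nm: Tuple[float, ...] = (77.0, 110.0)
    mode_weights: Tuple[float, ...] = (0.5, 0.5)
    mode_sd_nm: Tuple[float, ...] = (8.0, 8.0)
    n_particles_per_replicate: int = 5000
    n_replicates: int = 3
    concentration_scale: float = 3.3e8
    dilution_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.modes_nm)
        if k == 0:
            raise ConfigurationError("at least one mode is required")
        if len(self.mode_weights) != k or len(self.mode_sd_nm) != k:
            raise ConfigurationError("modes, weights and sds must have equal length")
        if any(m <= 0 for m in self.modes_nm):
            raise ConfigurationError("mode diameters must be > 0")
        if any(w < 0 for w in self.mode_weights):
            raise ConfigurationError("mode weights must be >= 0")
        if abs(sum(self.mode_weights) - 1.0) > 1e-9:
            raise ConfigurationError("mode weights must sum to 1")
        if any(s < 0 for s in self.mode_sd_nm):
            raise ConfigurationError("mode sds must be >= 0")
        if self.n_particles_per_replicate < 1 or self.n_replicates < 1:
            raise ConfigurationError("particle and replicate counts must be >= 1")
        if self.concentration_scale < 0:
            raise ConfigurationError("concentration_scale must be >= 0")
        if self.dilution_factor < 1:
            raise ConfigurationError("dilution_factor must be >= 1")


def simulate_nta(config: NtaSimConfig) -> list[ParticleSample]:
    """One ParticleSample per technical replicate.

    Particle counts are Poisson around the configured mean; diameters are
    drawn from the mixture and truncated at zero by redrawing.
    """
    rng = np.random.default_rng(config.seed)
    modes = np.asarray(config.modes_nm)
    sds = np.asarray(config.mode_sd_nm)
    weights = np.asarray(config.mode_weights)
    samples = []
    for r in range(1, config.n_replicates + 1):
        n = max(1, int(rng.poisson(config.n_particles_per_replicate)))
        comp = rng.choice(modes.size, size=n, p=weights)
        d = rng.normal(modes[comp], sds[comp])
        bad = d <= 0
        while np.any(bad):  # truncate the mixture at zero
            d[bad] = rng.normal(modes[comp[bad]], sds[comp[bad]])
            bad = d <= 0
        samples.append(
            ParticleSample(
                diameters_nm=d,
                concentration_scale=config.concentration_scale,
                replicate_id=f"rep{r}",
                dilution_factor=config.dilution_factor,
            )
        )
    return samples
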