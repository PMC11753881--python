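"""Proportion-based differential-enrichment analysis for label-free proteomics.

Two analysis paths share one container, :class:`AbundanceMatrix`
(proteins x samples with two or more replicate groups; NaN marks a
missing/not-quantified cell):

* the *volcano* path — per-sample proportion normalization, a presence
  partition (shared vs group-unique proteins), group-mean fold change of
  proportions and an unmoderated equal-variance Student's t per protein
  (suited to e.g. a cell-lysate vs EV comparison with few replicates);
* the *paired-timepoint* path (:func:`dusk_dawn_analysis`) — presence
  filtering, log2 transform, left-censored Gaussian imputation of missing
  values and an empirical-Bayes moderated t with variance shrinkage
  across proteins.

The moderated t follows the standard hierarchical model: per-protein
residual variances s_g^2 with d residual degrees of freedom are assumed
scaled-F around a prior (d0, s0^2) estimated by moment matching on
log s_g^2; the posterior variance (d0*s0^2 + d*s_g^2)/(d0 + d) replaces
s_g^2 in the t-statistic, which gains d0 degrees of freedom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .errors import (
    ConfigurationError,
    DegenerateVarianceError,
    EmptyInputError,
    InsufficientReplicatesError,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_LOG2FC_CUTOFF = 0.58  # ~1.5-fold
DEFAULT_P_CUTOFF = 0.05
DEFAULT_MIN_VALID = 2
DEFAULT_DOWNSHIFT_SD = 1.8
DEFAULT_WIDTH_SD = 0.3

CLASS_SHARED = "shared"
CLASS_ABSENT = "absent"
CLASS_NS = "NS"
CLASS_FILTERED = "filtered"


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------

@dataclass
class AbundanceMatrix:
    """Protein x sample intensity matrix with a group label per sample.

    ``data`` holds nonnegative intensities (or proportions, or log2 values
    downstream) with NaN for missing cells; ``groups`` maps every sample
    column to its group label.
    """

    data: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.data.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValidationError(f"samples without a group assignment: {missing}")
        if self.data.index.duplicated().any():
            dups = list(self.data.index[self.data.index.duplicated()].unique())
            raise ValidationError(f"duplicate protein ids: {dups[:5]}")

    @property
    def protein_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    def group_names(self) -> list[str]:
        """Group labels in order of first appearance across samples."""
        return list(dict.fromkeys(self.groups))

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def group_pair(
        self, group1: Optional[str] = None, group2: Optional[str] = None
    ) -> Tuple[str, str]:
        names = self.group_names()
        if group1 is None and group2 is None:
            if len(names) != 2:
                raise ConfigurationError(
                    f"matrix has groups {names}; name the two groups to compare"
                )
            return names[0], names[1]
        if group1 is None or group2 is None:
            raise ConfigurationError("provide both group names or neither")
        for g in (group1, group2):
            if g not in names:
                raise ConfigurationError(f"unknown group {g!r}; matrix has {names}")
        return group1, group2

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.copy(), self.groups.copy())


# ---------------------------------------------------------------------------
# normalization and presence partition
# ---------------------------------------------------------------------------

def normalize_total(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Per-sample proportions: each cell divided by its sample's total.

    Missing cells stay missing; each sample's detected proportions then sum
    to 1.  A sample whose detected total is zero (or that is entirely
    missing) is a validation error naming the sample.
    """
    totals = matrix.data.sum(axis=0, skipna=True)
    bad = totals.index[(totals <= 0) | matrix.data.isna().all(axis=0)]
    if len(bad):
        raise ValidationError(
            f"samples with zero or all-missing total intensity: {list(bad)}"
        )
    if (matrix.data < 0).any().any():
        raise ValidationError("intensities must be nonnegative")
    return AbundanceMatrix(matrix.data.div(totals, axis=1), matrix.groups.copy())


def presence_partition(
    matrix: AbundanceMatrix,
    min_valid: int = DEFAULT_MIN_VALID,
    group1: Optional[str] = None,
    group2: Optional[str] = None,
) -> pd.Series:
    """Classify each protein: shared / unique to one group / absent.

    A protein is *identified* in a group iff it has at least ``min_valid``
    non-missing values among that group's replicates.  Classes are
    ``shared`` (both), ``unique_<group>`` (exactly one) and ``absent``
    (neither); the class counts always sum to the number of proteins.
    """
    g1, g2 = matrix.group_pair(group1, group2)
    if min_valid < 1:
        raise ConfigurationError("min_valid must be >= 1")
    n1, n2 = len(matrix.samples_in(g1)), len(matrix.samples_in(g2))
    if min_valid > min(n1, n2):
        raise ConfigurationError(
            f"min_valid={min_valid} exceeds the smaller group size ({min(n1, n2)})"
        )
    valid1 = matrix.data[matrix.samples_in(g1)].notna().sum(axis=1) >= min_valid
    valid2 = matrix.data[matrix.samples_in(g2)].notna().sum(axis=1) >= min_valid
    out = pd.Series(CLASS_ABSENT, index=matrix.protein_ids, name="presence", dtype=object)
    out[valid1 & valid2] = CLASS_SHARED
    out[valid1 & ~valid2] = f"unique_{g1}"
    out[~valid1 & valid2] = f"unique_{g2}"
    return out


# ---------------------------------------------------------------------------
# unmoderated volcano path
# ---------------------------------------------------------------------------

def _students_t(x1: np.ndarray, x2: np.ndarray) -> Tuple[float, float, str]:
    """Equal-variance two-sided t on two 1-d samples (NaN dropped).

    Returns (t, p, flag); degenerate zero-variance cases are resolved
    explicitly instead of propagating NaN.
    """
    a = x1[~np.isnan(x1)]
    b = x2[~np.isnan(x2)]
    if a.size < 2 or b.size < 2:
        return np.nan, np.nan, "insufficient_replicates"
    # exact-value ties, not var == 0: identical inputs can leave ~1e-33 of
    # floating-point variance which would otherwise yield a meaningless t
    if np.all(a == a[0]) and np.all(b == b[0]):
        if a[0] == b[0]:
            return 0.0, 1.0, "degenerate"
        return math.copysign(np.inf, b[0] - a[0]), 0.0, "zero_variance"
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), ""


def _paired_t(x1: np.ndarray, x2: np.ndarray) -> Tuple[float, float, str]:
    keep = ~(np.isnan(x1) | np.isnan(x2))
    a, b = x1[keep], x2[keep]
    if a.size < 2:
        return np.nan, np.nan, "insufficient_replicates"
    d = b - a
    if np.all(d == d[0]):
        if d[0] == 0:
            return 0.0, 1.0, "degenerate"
        return math.copysign(np.inf, d[0]), 0.0, "zero_variance"
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), ""


def volcano(
    matrix: AbundanceMatrix,
    group1: Optional[str] = None,
    group2: Optional[str] = None,
    log2fc_cutoff: float = DEFAULT_LOG2FC_CUTOFF,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    min_valid: int = DEFAULT_MIN_VALID,
    *,
    paired: bool = False,
    fdr_cutoff: Optional[float] = None,
) -> pd.DataFrame:
    """Proportion fold-change volcano with Student's t on shared proteins.

    The matrix is proportion-normalized per sample; proteins identified in
    both groups (the presence partition's ``shared`` class) are tested with
    a two-sided equal-variance Student's t on their replicate proportions
    and classified against ``log2fc_cutoff``/``p_cutoff``.  The log2 fold
    change is ``log2(mean proportion in group2 / mean proportion in
    group1)``, so positive values mean enrichment in ``group2``.

    Returns one row per non-absent protein with columns
    ``prop_<g1>, prop_<g2>, log2fc, stat, p, fdr, flag, class``; classes are
    ``enriched_<g2>``, ``enriched_<g1>``, ``NS``, ``unique_<g>`` and
    ``filtered`` (shared but with a zero group-mean proportion).  FDR is
    Benjamini-Hochberg over the tested proteins and is reported always;
    pass ``fdr_cutoff`` to classify on FDR instead of raw p.
    """
    if log2fc_cutoff <= 0 or not (0 < p_cutoff < 1):
        raise ConfigurationError("cutoffs must be positive (p_cutoff in (0, 1))")
    g1, g2 = matrix.group_pair(group1, group2)
    props = normalize_total(matrix)
    part = presence_partition(matrix, min_valid=min_valid, group1=g1, group2=g2)
    s1, s2 = props.data[matrix.samples_in(g1)], props.data[matrix.samples_in(g2)]
    m1, m2 = s1.mean(axis=1, skipna=True), s2.mean(axis=1, skipna=True)

    rows = []
    for pid in matrix.protein_ids:
        cls = part[pid]
        if cls == CLASS_ABSENT:
            continue
        row = {
            "protein_id": pid,
            f"prop_{g1}": m1[pid],
            f"prop_{g2}": m2[pid],
            "log2fc": np.nan,
            "stat": np.nan,
            "p": np.nan,
            "fdr": np.nan,
            "flag": "",
            "class": cls,
        }
        if cls == CLASS_SHARED:
            if m1[pid] <= 0 or m2[pid] <= 0:
                row["class"] = CLASS_FILTERED
                row["flag"] = "zero_mean_proportion"
                logger.warning(
                    "protein %s excluded: zero mean proportion in one group", pid
                )
            else:
                lfc = math.log2(m2[pid] / m1[pid])
                test = _paired_t if paired else _students_t
                t, p, flag = test(s1.loc[pid].to_numpy(), s2.loc[pid].to_numpy())
                row.update(log2fc=lfc, stat=t, p=p, flag=flag)
        rows.append(row)

    out = pd.DataFrame(rows).set_index("protein_id")
    tested = out.index[out["p"].notna()]
    if len(tested):
        out.loc[tested, "fdr"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    sig = out["fdr"] < fdr_cutoff if fdr_cutoff is not None else out["p"] < p_cutoff
    shared = out["class"] == CLASS_SHARED
    out.loc[shared & sig & (out["log2fc"] > log2fc_cutoff), "class"] = f"enriched_{g2}"
    out.loc[shared & sig & (out["log2fc"] < -log2fc_cutoff), "class"] = f"enriched_{g1}"
    out.loc[out["class"] == CLASS_SHARED, "class"] = CLASS_NS
    return out


# ---------------------------------------------------------------------------
# left-censored imputation
# ---------------------------------------------------------------------------

def impute_left_censored(
    matrix: AbundanceMatrix,
    downshift_sd: float = DEFAULT_DOWNSHIFT_SD,
    width_sd: float = DEFAULT_WIDTH_SD,
    seed: int = 0,
    *,
    log_transform: bool = True,
) -> Tuple[AbundanceMatrix, pd.DataFrame]:
    """Fill missing cells with draws from a down-shifted per-sample Gaussian.

    Intensities are log2-transformed (unless ``log_transform=False``, for a
    matrix already on a log scale); for each sample, missing cells are drawn
    from ``Normal(mean_obs - downshift_sd * sd_obs, (width_sd * sd_obs)^2)``
    computed on that sample's observed values.  This models detection-limit
    dropout in label-free MS.  Returns the completed log-scale matrix plus a
    boolean mask of imputed cells.
    """
    if downshift_sd < 0 or width_sd < 0:
        raise ConfigurationError("downshift_sd and width_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if log_transform:
        if (matrix.data <= 0).any().any():
            raise ValidationError("nonpositive intensities cannot be log-transformed")
        data = np.log2(matrix.data)
    else:
        data = matrix.data.copy()
    mask = data.isna()
    for sample in data.columns:
        obs = data[sample].dropna()
        if obs.size < 2:
            raise ValidationError(
                f"sample {sample!r} has {obs.size} observed values; need >= 2 to impute"
            )
        miss = mask[sample]
        n_miss = int(miss.sum())
        if n_miss == 0:
            continue
        mu = obs.mean() - downshift_sd * obs.std(ddof=1)
        sd = width_sd * obs.std(ddof=1)
        data.loc[miss, sample] = rng.normal(mu, sd, size=n_miss)
    return AbundanceMatrix(data, matrix.groups.copy()), mask


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t
# ---------------------------------------------------------------------------

@dataclass
class ModeratedStats:
    """Moderated-t results for one two-group contrast (group2 - group1)."""

    protein_ids: pd.Index
    effect: np.ndarray  # mean(group2) - mean(group1) on the input (log) scale
    prior_df: float  # d0
    prior_var: float  # s0^2
    residual_var: np.ndarray = field(repr=False, default=None)
    posterior_var: np.ndarray = field(repr=False, default=None)
    t: np.ndarray = field(repr=False, default=None)
    p: np.ndarray = field(repr=False, default=None)
    df_residual: float = 0.0
    df_total: float = 0.0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "effect": self.effect,
                "residual_var": self.residual_var,
                "posterior_var": self.posterior_var,
                "t": self.t,
                "p": self.p,
            },
            index=self.protein_ids,
        )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += step
        if abs(step) < 1e-10 * x:
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df: float) -> Tuple[float, float]:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Under the scaled-F model, z = log(s2) has mean ``log(s0^2) +
    digamma(d/2) - log(d/2) - digamma(d0/2) + log(d0/2)`` and excess
    variance ``trigamma(d0/2)`` beyond ``trigamma(d/2)``; matching the
    sample mean and variance of z yields (d0, s0^2).  Nonpositive excess
    variance gives an infinite prior df (all variances equal s0^2).
    """
    pos = s2[s2 > 0]
    if pos.size == 0:
        raise DegenerateVarianceError("all residual variances are zero")
    z = np.log(pos)
    e = z - digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) if e.size > 1 else 0.0
    excess = evar - float(polygamma(1, df / 2.0))
    if excess <= 1e-8:
        return math.inf, math.exp(emean)
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_2 = math.exp(emean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return d0, s0_2


def moderated_t(
    matrix: AbundanceMatrix,
    group1: Optional[str] = None,
    group2: Optional[str] = None,
    prior_df: Optional[float] = None,
) -> ModeratedStats:
    """Empirical-Bayes moderated t per protein on a complete log-scale matrix.

    ``prior_df`` overrides the estimated d0: 0 recovers the ordinary
    Student's t exactly, ``inf`` shrinks every variance fully to s0^2.
    The effect column is mean(group2) - mean(group1), i.e. a log2 fold
    change when the input is log2.
    """
    g1, g2 = matrix.group_pair(group1, group2)
    x1 = matrix.data[matrix.samples_in(g1)].to_numpy(dtype=float)
    x2 = matrix.data[matrix.samples_in(g2)].to_numpy(dtype=float)
    if np.isnan(x1).any() or np.isnan(x2).any():
        raise ValidationError("moderated t requires a complete matrix; impute first")
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise InsufficientReplicatesError("need >= 2 replicates per group")
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    effect = m2 - m1
    df = float(n1 + n2 - 2)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    if np.all(s2 == 0):
        raise DegenerateVarianceError("all residual variances are zero")

    if prior_df is None:
        d0, s0_2 = estimate_variance_prior(s2, df)
    else:
        if prior_df < 0:
            raise ConfigurationError("prior_df must be >= 0")
        d0 = float(prior_df)
        _, s0_2 = estimate_variance_prior(s2, df)

    if math.isinf(d0):
        post = np.full_like(s2, s0_2)
        df_total = math.inf
    elif d0 == 0:
        post = s2.copy()
        df_total = df
    else:
        post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df

    scale = math.sqrt(1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / (np.sqrt(post) * scale)
    # zero posterior variance (possible only when d0 == 0 and s2 == 0)
    t = np.where((post == 0) & (effect == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df=df_total if math.isfinite(df_total) else np.inf)
    p = np.where(np.isnan(t), np.nan, p)

    return ModeratedStats(
        protein_ids=matrix.protein_ids,
        effect=effect,
        prior_df=d0,
        prior_var=s0_2,
        residual_var=s2,
        posterior_var=post,
        t=t,
        p=p,
        df_residual=df,
        df_total=df_total,
    )


# ---------------------------------------------------------------------------
# DUSK/DAWN path
# ---------------------------------------------------------------------------

@dataclass
class DuskDawnResult:
    """Unique-protein lists plus the moderated differential table."""

    group1: str
    group2: str
    partition: pd.Series
    unique_group1: list[str]
    unique_group2: list[str]
    table: pd.DataFrame  # shared proteins: effect/t/p/fdr/class
    stats: ModeratedStats
    n_imputed: int

    @property
    def n_differential(self) -> int:
        return int((self.table["class"] != "similar").sum())


def dusk_dawn_analysis(
    matrix: AbundanceMatrix,
    group1: Optional[str] = None,
    group2: Optional[str] = None,
    min_valid: int = DEFAULT_MIN_VALID,
    log2fc_cutoff: float = DEFAULT_LOG2FC_CUTOFF,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    downshift_sd: float = DEFAULT_DOWNSHIFT_SD,
    width_sd: float = DEFAULT_WIDTH_SD,
    seed: int = 0,
    prior_df: Optional[float] = None,
) -> DuskDawnResult:
    """Timepoint contrast: presence filter, impute, moderated t, classify.

    Proteins identified (>= ``min_valid`` valid values per group) in exactly
    one group are reported as that group's unique list; proteins identified
    in both are log2-transformed, missing cells are imputed with the
    left-censored model, and a moderated t (group2 over group1) classifies
    each shared protein as ``more_enriched_<group2>`` (log2fc >
    ``log2fc_cutoff`` and p < ``p_cutoff``), ``more_enriched_<group1>``
    (log2fc < -cutoff, p < cutoff) or ``similar``.
    """
    g1, g2 = matrix.group_pair(group1, group2)
    part = presence_partition(matrix, min_valid=min_valid, group1=g1, group2=g2)
    unique1 = list(part.index[part == f"unique_{g1}"])
    unique2 = list(part.index[part == f"unique_{g2}"])
    shared = part.index[part == CLASS_SHARED]
    if len(shared) == 0:
        raise EmptyInputError("no shared proteins to test")

    sub = AbundanceMatrix(matrix.data.loc[shared], matrix.groups.copy())
    completed, mask = impute_left_censored(
        sub, downshift_sd=downshift_sd, width_sd=width_sd, seed=seed
    )
    ms = moderated_t(completed, group1=g1, group2=g2, prior_df=prior_df)
    table = ms.as_frame().rename(columns={"effect": "log2fc"})
    table["fdr"] = multipletests(table["p"], method="fdr_bh")[1]
    cls = pd.Series("similar", index=table.index, dtype=object)
    sig = table["p"] < p_cutoff
    cls[sig & (table["log2fc"] > log2fc_cutoff)] = f"more_enriched_{g2}"
    cls[sig & (table["log2fc"] < -log2fc_cutoff)] = f"more_enriched_{g1}"
    table["class"] = cls

    return DuskDawnResult(
        group1=g1,
        group2=g2,
        partition=part,
        unique_group1=unique1,
        unique_group2=unique2,
        table=table,
        stats=ms,
        n_imputed=int(mask.to_numpy().sum()),
    )
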