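"""Vesicle shape scoring from electron-microscopy axis measurements.

Negative-stain TEM of purified extracellular vesicles yields, per vesicle,
a longer diameter *a* and a shorter diameter *b* (nm).  The shape score used
here is

    e = 1 - b**2 / a**2

which is 0 for a perfect sphere (a = b) and approaches 1 as the vesicle
becomes rod-like.  Note this equals the *square* of the textbook ellipse
eccentricity sqrt(1 - b^2/a^2); the squared form is the field's reporting
convention for these vesicles and is the default.  Pass ``textbook=True``
for the square-root form.

Vesicles with e at or above a cutoff (default 0.5) are classified
"elliptical", the rest "spherical".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError, ValidationError

SPHERICAL = "spherical"
ELLIPTICAL = "elliptical"

DEFAULT_ECCENTRICITY_CUTOFF = 0.5


@dataclass(frozen=True)
class EllipseMeasurement:
    """Axis measurements for one vesicle.

    ``longer_diameter_nm`` (a) must be >= ``shorter_diameter_nm`` (b) > 0;
    the TSV reader swaps reversed pairs before constructing this type.
    """

    vesicle_id: str
    longer_diameter_nm: float
    shorter_diameter_nm: float

    def __post_init__(self) -> None:
        a, b = self.longer_diameter_nm, self.shorter_diameter_nm
        if not (b > 0 and a > 0):
            raise ValidationError(
                f"vesicle {self.vesicle_id!r}: diameters must be positive, "
                f"got a={a}, b={b}"
            )
        if a < b:
            raise ValidationError(
                f"vesicle {self.vesicle_id!r}: longer diameter ({a}) is "
                f"smaller than shorter diameter ({b}); swap the axes"
            )

    @property
    def eccentricity(self) -> float:
        return eccentricity(self.longer_diameter_nm, self.shorter_diameter_nm)


@dataclass(frozen=True)
class ShapeSummary:
    """Population summary of shape scores."""

    n: int
    mean_e: float
    sd_e: float
    fraction_above_cutoff: float
    cutoff: float
    degenerate: bool = False  # True when n == 1 and sd is reported as 0


def eccentricity(longer_nm: float, shorter_nm: float, *, textbook: bool = False) -> float:
    """Shape score ``1 - b**2/a**2`` for axes a >= b > 0.

    Parameters
    ----------
    longer_nm, shorter_nm
        The longer (a) and shorter (b) vesicle diameters, any common unit.
    textbook
        If True, return the classical ellipse eccentricity
        ``sqrt(1 - b**2/a**2)`` instead of the squared-form default.
    """
    a, b = float(longer_nm), float(shorter_nm)
    if a <= 0 or b <= 0:
        raise ValidationError(f"diameters must be positive, got a={a}, b={b}")
    if a < b:
        raise ValidationError(
            f"longer diameter ({a}) < shorter diameter ({b}); axes must be ordered"
        )
    e = 1.0 - (b * b) / (a * a)
    return math.sqrt(e) if textbook else e


def classify_shape(e: float, cutoff: float = DEFAULT_ECCENTRICITY_CUTOFF) -> str:
    """Label a score: ``elliptical`` iff ``e >= cutoff`` (boundary inclusive)."""
    if not (0.0 <= cutoff < 1.0):
        raise ConfigurationError(f"cutoff must lie in [0, 1), got {cutoff}")
    if not (0.0 <= e < 1.0):
        raise ValidationError(f"eccentricity score must lie in [0, 1), got {e}")
    return ELLIPTICAL if e >= cutoff else SPHERICAL


def score_table(
    measurements: Iterable[EllipseMeasurement],
    cutoff: float = DEFAULT_ECCENTRICITY_CUTOFF,
    *,
    textbook: bool = False,
) -> pd.DataFrame:
    """Per-vesicle table of axes, score and shape label."""
    rows = []
    for m in measurements:
        e = eccentricity(m.longer_diameter_nm, m.shorter_diameter_nm, textbook=textbook)
        rows.append(
            {
                "vesicle_id": m.vesicle_id,
                "longer_diameter_nm": m.longer_diameter_nm,
                "shorter_diameter_nm": m.shorter_diameter_nm,
                "eccentricity": e,
                "shape": classify_shape(e, cutoff) if e < 1.0 else ELLIPTICAL,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "vesicle_id",
            "longer_diameter_nm",
            "shorter_diameter_nm",
            "eccentricity",
            "shape",
        ],
    )


def summarize_shapes(
    measurements: Sequence[EllipseMeasurement],
    cutoff: float = DEFAULT_ECCENTRICITY_CUTOFF,
    *,
    textbook: bool = False,
) -> ShapeSummary:
    """Mean, sample s.d. (n-1 denominator) and elliptical fraction of scores.

    A single measurement is summarized with sd reported as 0 and the
    ``degenerate`` flag set.
    """
    ms = list(measurements)
    if not ms:
        raise EmptyInputError("no morphometry measurements supplied")
    e = np.array(
        [eccentricity(m.longer_diameter_nm, m.shorter_diameter_nm, textbook=textbook) for m in ms]
    )
    n = len(e)
    sd = float(np.std(e, ddof=1)) if n > 1 else 0.0
    frac = float(np.mean(e >= cutoff))
    return ShapeSummary(
        n=n,
        mean_e=float(np.mean(e)),
        sd_e=sd,
        fraction_above_cutoff=frac,
        cutoff=cutoff,
        degenerate=(n == 1),
    )
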