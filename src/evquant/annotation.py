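"""Functional-annotation summaries: COG proportions, GO and localization percentages.

The annotation map links protein ids to COG single-letter functional
categories, GO terms and a predicted subcellular localization.  Summaries
are abundance-weighted (COG) or membership percentages over a protein list
(GO, localization); proteins without an annotation are reported in an
explicit ``unannotated`` bucket rather than silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import EmptyInputError, ValidationError

logger = logging.getLogger(__name__)

UNANNOTATED = "unannotated"

# the standard COG single-letter functional alphabet
COG_LETTERS = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ")


@dataclass
class AnnotationMap:
    """Protein-level annotations; unknown proteins are permitted everywhere."""

    cog: Mapping[str, Sequence[str]] = field(default_factory=dict)
    go: Mapping[str, Sequence[str]] = field(default_factory=dict)
    localization: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, letters in self.cog.items():
            bad = [c for c in letters if c not in COG_LETTERS]
            if bad:
                raise ValidationError(
                    f"protein {pid!r}: invalid COG letters {bad}; expected A-Z"
                )


def _check_list(proteins: Sequence[str]) -> list[str]:
    plist = list(proteins)
    if not plist:
        raise EmptyInputError("protein list is empty")
    if len(set(plist)) != len(plist):
        dups = sorted({p for p in plist if plist.count(p) > 1})
        raise ValidationError(f"duplicate protein ids in list: {dups[:5]}")
    return plist


def cog_proportions(
    abundances: pd.Series,
    annotation: AnnotationMap,
    *,
    split_equally: bool = True,
) -> pd.Series:
    """Abundance-weighted COG category proportions.

    Each protein's abundance is split equally among its COG letters
    (default) and category sums are normalized to fractions of the total
    abundance; unannotated abundance goes to the ``unannotated`` bucket so
    the output sums to 1.  With ``split_equally=False`` a protein counts
    fully toward each of its letters, which inflates the sum above 1 for
    multi-letter proteins (the ``unannotated`` bucket is still a fraction
    of total abundance).
    """
    if abundances.empty:
        raise EmptyInputError("abundance series is empty")
    if (abundances < 0).any():
        raise ValidationError("abundances must be nonnegative")
    total = float(abundances.sum())
    if total <= 0:
        raise ValidationError("total abundance must be positive")
    weights: dict[str, float] = {}
    unannot = 0.0
    for pid, ab in abundances.items():
        letters = list(annotation.cog.get(pid, []))
        if not letters:
            unannot += ab
            continue
        share = ab / len(letters) if split_equally else ab
        for c in letters:
            weights[c] = weights.get(c, 0.0) + share
    if unannot == total:
        logger.warning("no protein in the list carries a COG annotation")
    out = pd.Series(weights, dtype=float).sort_index() / total
    out[UNANNOTATED] = unannot / total
    out.name = "proportion"
    return out


def go_percentages(
    proteins: Sequence[str],
    annotation: AnnotationMap,
    terms: Iterable[str],
) -> pd.Series:
    """Percentage of the list annotated with each queried GO term.

    A protein may count toward several terms; percentages are over the full
    list size and kept at full precision (see :func:`round_percentages` for
    report-time rounding).
    """
    plist = _check_list(proteins)
    n = len(plist)
    out = {}
    for term in terms:
        hits = sum(1 for p in plist if term in annotation.go.get(p, ()))
        out[term] = 100.0 * hits / n
    return pd.Series(out, name="percentage")


def localization_percentages(
    proteins: Sequence[str],
    annotation: AnnotationMap,
) -> pd.Series:
    """Percentage of the list per predicted localization label.

    Proteins without a localization are reported under ``unannotated``;
    percentages are over the full list and sum to 100.
    """
    plist = _check_list(proteins)
    counts: dict[str, int] = {}
    for p in plist:
        label = annotation.localization.get(p, UNANNOTATED)
        counts[label] = counts.get(label, 0) + 1
    out = pd.Series(counts, dtype=float).sort_index() * 100.0 / len(plist)
    out.name = "percentage"
    return out


def round_percentages(percentages: pd.Series) -> pd.Series:
    """Round percentages half-up to whole percent for reporting."""
    import math

    return percentages.map(lambda v: math.floor(v + 0.5))
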