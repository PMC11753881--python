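"""Readers and writers for the pipeline's tabular formats.

One dialect everywhere: tab-separated UTF-8 with a header row.  Missing
values are written as the empty string; ``""``, ``NA`` and ``NaN`` are
accepted on read.  Floats are written with ``%.12g`` so that
write -> read -> write is byte-stable.

Schemas
-------
abundance      protein_id <tab> <sample columns...>          (values >= 0 or missing)
group map      sample_id, group
morphometry    vesicle_id, longer_diameter_nm, shorter_diameter_nm
diel           replicate_id, treatment, zeitgeber_time, cell_concentration, ev_concentration
particles      replicate_id, diameter_nm
scales         replicate_id, concentration_scale, dilution_factor
annotation     protein_id, cog_letters, go_terms (";"-separated), localization
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .annotation import AnnotationMap
from .enrichment import AbundanceMatrix
from .errors import ParseError, SchemaError, ValidationError
from .morphometry import EllipseMeasurement
from .nta import ParticleSample

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

MISSING_TOKENS = ["", "NA", "NaN", "nan"]
FLOAT_FORMAT = "%.12g"


def _read_tsv(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype=str,
        keep_default_na=False,
        na_values=[],
        encoding="utf-8",
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def _to_float(df: pd.DataFrame, columns: Sequence[str], path: PathLike) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        raw = out[col].astype(str).str.strip()
        blank = raw.isin(MISSING_TOKENS)
        vals = pd.to_numeric(raw.mask(blank), errors="coerce")
        bad = vals.isna() & ~blank
        if bad.any():
            where = raw[bad].iloc[0]
            raise ParseError(f"{path}: non-numeric value {where!r} in column {col!r}")
        out[col] = vals
    return out


def write_table(df: pd.DataFrame, path: PathLike, *, index: bool = False) -> None:
    """Canonical TSV writer used for every output table."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, na_rep="", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# abundance matrix + group map
# ---------------------------------------------------------------------------

def read_group_map(path: PathLike) -> dict[str, str]:
    df = _read_tsv(path, ["sample_id", "group"])
    if df["sample_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate sample ids in group map")
    return dict(zip(df["sample_id"], df["group"]))


def read_abundance_matrix(
    path: PathLike, group_map: Union[Mapping[str, str], PathLike]
) -> AbundanceMatrix:
    """Read a protein x sample intensity TSV plus its sample-group mapping.

    The first column must be ``protein_id``; every other column is a sample
    and must appear in ``group_map`` (a mapping or the path of a two-column
    TSV).  Empty cells and NA/NaN are recorded as missing, not zero.
    """
    if not isinstance(group_map, Mapping):
        group_map = read_group_map(group_map)
    df = _read_tsv(path, ["protein_id"])
    samples = [c for c in df.columns if c != "protein_id"]
    if not samples:
        raise SchemaError(f"{path}: no sample columns")
    unassigned = [s for s in samples if s not in group_map]
    if unassigned:
        raise SchemaError(f"{path}: samples without group assignment: {unassigned}")
    if df["protein_id"].duplicated().any():
        dups = list(df.loc[df["protein_id"].duplicated(), "protein_id"].unique())
        raise SchemaError(f"{path}: duplicate protein ids {dups[:5]}")
    df = _to_float(df, samples, path)
    data = df.set_index("protein_id")[samples].astype(float)
    if (data < 0).any().any():
        raise ValidationError(f"{path}: negative intensities present")
    groups = pd.Series({s: group_map[s] for s in samples}, name="group")
    return AbundanceMatrix(data, groups)


def write_abundance_matrix(matrix: AbundanceMatrix, path: PathLike) -> None:
    out = matrix.data.copy()
    out.index.name = "protein_id"
    write_table(out.reset_index(), path)


def write_group_map(matrix: AbundanceMatrix, path: PathLike) -> None:
    write_table(
        pd.DataFrame(
            {"sample_id": matrix.groups.index, "group": matrix.groups.to_numpy()}
        ),
        path,
    )


# ---------------------------------------------------------------------------
# morphometry
# ---------------------------------------------------------------------------

def read_morphometry(path: PathLike) -> list[EllipseMeasurement]:
    """Read vesicle axis measurements; reversed axis pairs are swapped with
    a logged warning, nonpositive diameters are a validation error."""
    df = _read_tsv(path, ["vesicle_id", "longer_diameter_nm", "shorter_diameter_nm"])
    df = _to_float(df, ["longer_diameter_nm", "shorter_diameter_nm"], path)
    out = []
    n_swapped = 0
    for row in df.itertuples(index=False):
        a, b = row.longer_diameter_nm, row.shorter_diameter_nm
        if not np.isfinite(a) or not np.isfinite(b) or a <= 0 or b <= 0:
            raise ValidationError(
                f"{path}: vesicle {row.vesicle_id!r} has nonpositive or missing diameters"
            )
        if b > a:
            a, b = b, a
            n_swapped += 1
            logger.warning(
                "vesicle %s: axes given in reverse order; swapped", row.vesicle_id
            )
        out.append(EllipseMeasurement(str(row.vesicle_id), float(a), float(b)))
    if n_swapped:
        logger.warning("%d vesicle row(s) had swapped axes", n_swapped)
    return out


def write_morphometry(measurements: Sequence[EllipseMeasurement], path: PathLike) -> None:
    write_table(
        pd.DataFrame(
            {
                "vesicle_id": [m.vesicle_id for m in measurements],
                "longer_diameter_nm": [m.longer_diameter_nm for m in measurements],
                "shorter_diameter_nm": [m.shorter_diameter_nm for m in measurements],
            }
        ),
        path,
    )


# ---------------------------------------------------------------------------
# diel
# ---------------------------------------------------------------------------

DIEL_COLUMNS = [
    "replicate_id",
    "treatment",
    "zeitgeber_time",
    "cell_concentration",
    "ev_concentration",
]


def read_diel(path: PathLike) -> pd.DataFrame:
    """Read and validate a diel time-course table.

    ``zeitgeber_time`` is hours since the first lights-on; values past 24
    belong to the next cycle.  Concentrations must be nonnegative.
    """
    df = _read_tsv(path, DIEL_COLUMNS)
    df = _to_float(df, ["zeitgeber_time", "cell_concentration", "ev_concentration"], path)
    if df[["zeitgeber_time", "cell_concentration", "ev_concentration"]].isna().any().any():
        raise ValidationError(f"{path}: missing numeric values in diel table")
    if (df["zeitgeber_time"] < 0).any():
        raise ValidationError(f"{path}: negative zeitgeber times")
    if (df[["cell_concentration", "ev_concentration"]] < 0).any().any():
        raise ValidationError(f"{path}: negative concentrations")
    return df[DIEL_COLUMNS]


def write_diel(table: pd.DataFrame, path: PathLike) -> None:
    write_table(table[DIEL_COLUMNS], path)


# ---------------------------------------------------------------------------
# NTA particles
# ---------------------------------------------------------------------------

def read_particles(
    particles_path: PathLike, scales_path: Optional[PathLike] = None
) -> list[ParticleSample]:
    """Read per-particle diameters, one sample per replicate id.

    Without a scales table every replicate gets ``concentration_scale = 1``
    (densities are then per-tracked-particle rather than absolute).
    """
    df = _read_tsv(particles_path, ["replicate_id", "diameter_nm"])
    df = _to_float(df, ["diameter_nm"], particles_path)
    if df["diameter_nm"].isna().any() or (df["diameter_nm"] <= 0).any():
        raise ValidationError(f"{particles_path}: diameters must be positive")
    scales: dict[str, tuple[float, float]] = {}
    if scales_path is not None:
        sdf = _read_tsv(scales_path, ["replicate_id", "concentration_scale"])
        cols = ["concentration_scale"]
        if "dilution_factor" in sdf.columns:
            cols.append("dilution_factor")
        sdf = _to_float(sdf, cols, scales_path)
        for row in sdf.itertuples(index=False):
            dil = getattr(row, "dilution_factor", 1.0)
            scales[str(row.replicate_id)] = (
                float(row.concentration_scale),
                float(dil) if np.isfinite(dil) else 1.0,
            )
    samples = []
    for rep, grp in df.groupby("replicate_id", sort=True):
        conc, dil = scales.get(str(rep), (1.0, 1.0))
        samples.append(
            ParticleSample(
                diameters_nm=grp["diameter_nm"].to_numpy(dtype=float),
                concentration_scale=conc,
                replicate_id=str(rep),
                dilution_factor=dil,
            )
        )
    return samples


def write_particles(samples: Sequence[ParticleSample], path: PathLike) -> None:
    frames = [
        pd.DataFrame({"replicate_id": s.replicate_id, "diameter_nm": s.diameters_nm})
        for s in samples
    ]
    write_table(pd.concat(frames, ignore_index=True), path)


def write_particle_scales(samples: Sequence[ParticleSample], path: PathLike) -> None:
    write_table(
        pd.DataFrame(
            {
                "replicate_id": [s.replicate_id for s in samples],
                "concentration_scale": [s.concentration_scale for s in samples],
                "dilution_factor": [s.dilution_factor for s in samples],
            }
        ),
        path,
    )


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def read_annotation(path: PathLike) -> AnnotationMap:
    """Read the annotation TSV (cog letters concatenated, GO terms ';'-separated)."""
    df = _read_tsv(path, ["protein_id"])
    if df["protein_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate protein ids in annotation")
    cog: dict[str, list[str]] = {}
    go: dict[str, list[str]] = {}
    loc: dict[str, str] = {}
    for row in df.itertuples(index=False):
        pid = str(row.protein_id)
        letters = str(getattr(row, "cog_letters", "") or "").strip()
        if letters and letters not in MISSING_TOKENS:
            cog[pid] = list(letters)
        terms = str(getattr(row, "go_terms", "") or "").strip()
        if terms and terms not in MISSING_TOKENS:
            go[pid] = [t.strip() for t in terms.split(";") if t.strip()]
        label = str(getattr(row, "localization", "") or "").strip()
        if label and label not in MISSING_TOKENS:
            loc[pid] = label
    return AnnotationMap(cog=cog, go=go, localization=loc)
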