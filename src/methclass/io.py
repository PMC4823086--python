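"""Readers, writers and validation for the delimited formats the pipeline touches.

Everything on disk is plain TSV: matrices have row ids (CpG or probe ids) in
the first column and sample ids in the header row, with ``NA`` marking missing
values.  In memory every matrix is a :class:`pandas.DataFrame` with rows =
CpGs/probes and columns = samples — the same layout as the files, and the
layout all module-level functions in this package expect.  27K-scale data is
small enough that transparency and diffability beat any binary format.

Sample groups use a closed vocabulary (``Normal``, ``Basal``, ``HER2``,
``LumA``, ``LumB``) and are case-normalised at load, since published sample
sheets spell the intrinsic subtypes inconsistently ("Her2+", "luminalA", ...).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed vocabulary of sample groups: four intrinsic breast-cancer subtypes
#: plus normal tissue.
GROUPS = ("Normal", "Basal", "HER2", "LumA", "LumB")

#: The four tumor subtypes (GROUPS without Normal).
SUBTYPES = ("Basal", "HER2", "LumA", "LumB")

ER_STATUSES = ("pos", "neg", "unknown")

MATRIX_KINDS = ("beta", "m", "expression", "intensity")


class ValidationError(ValueError):
    """Raised when a file or matrix violates its format contract."""


# ---------------------------------------------------------------------------
# matrix validation


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dup[:5]}")


def validate_matrix(df: pd.DataFrame, kind: str, name: str = "matrix") -> pd.DataFrame:
    """Validate a matrix of the given kind, returning it unchanged.

    ``beta`` values must lie in [0, 1]; ``intensity`` values must be
    non-negative.  ``m`` and ``expression`` are unconstrained reals.
    Errors name the offending cell (row id, column id).
    """
    if kind not in MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}; expected one of {MATRIX_KINDS}")
    _check_unique(df.index, f"row ids in {name}")
    _check_unique(df.columns, f"sample ids in {name}")
    values = df.to_numpy(dtype=float)
    if kind == "beta":
        bad = (values < 0) | (values > 1)
    elif kind == "intensity":
        bad = values < 0
    else:
        bad = np.zeros(values.shape, dtype=bool)
    bad &= ~np.isnan(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{name}: {kind} value {values[i, j]!r} out of range at "
            f"row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return df


def read_matrix(
    path,
    kind: str,
    max_missing_frac: float = 0.2,
) -> pd.DataFrame:
    """Read a tab-delimited matrix (rows × samples) and validate it.

    Parameters
    ----------
    path : path-like
        TSV file; first column row ids, first row sample ids, ``NA`` missing.
    kind : {"beta", "m", "expression", "intensity"}
        Controls value-range validation.
    max_missing_frac : float
        Rows with a larger fraction of missing values are dropped at load,
        with the count logged.  Downstream statistics use pairwise-complete
        observations for whatever missingness remains.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df = df.astype(float)
    validate_matrix(df, kind, name=str(path))
    if max_missing_frac is not None and len(df):
        frac_missing = df.isna().mean(axis=1)
        drop = frac_missing > max_missing_frac
        if drop.any():
            logger.info(
                "%s: dropped %d/%d rows with >%d%% missing values",
                path, int(drop.sum()), len(df), round(100 * max_missing_frac),
            )
            df = df.loc[~drop]
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a matrix as TSV with ``NA`` for missing values.

    Values are printed with 6 significant digits, so matrices whose entries
    carry at most 6 significant digits round-trip exactly through
    :func:`read_matrix`.  Row and column order is preserved as given
    (deterministic).
    """
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


# ---------------------------------------------------------------------------
# sample sheets and annotations

_GROUP_ALIASES = {
    "normal": "Normal",
    "basal": "Basal",
    "basallike": "Basal",
    "her2": "HER2",
    "luma": "LumA",
    "luminala": "LumA",
    "lumb": "LumB",
    "luminalb": "LumB",
}

_ER_ALIASES = {
    "pos": "pos", "positive": "pos", "+": "pos", "erpos": "pos",
    "neg": "neg", "negative": "neg", "-": "neg", "erneg": "neg",
    "unknown": "unknown", "na": "unknown", "": "unknown",
}


def normalize_group(label: str) -> str:
    """Map a free-form subtype spelling onto the closed group vocabulary."""
    # "Basal-like" and "Her2+" reduce to "basallike" / "her2"
    key = "".join(c for c in str(label).lower() if c.isalnum())
    if key not in _GROUP_ALIASES:
        raise ValidationError(
            f"unknown sample group {label!r}; expected one of {GROUPS}"
        )
    return _GROUP_ALIASES[key]


def normalize_er(status) -> str:
    key = "".join(c for c in str(status).lower() if not c.isspace())
    if pd.isna(status):
        return "unknown"
    if key not in _ER_ALIASES:
        raise ValidationError(
            f"unknown ER status {status!r}; expected one of {ER_STATUSES}"
        )
    return _ER_ALIASES[key]


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet TSV with columns sample_id, group, er_status.

    Returns a DataFrame indexed by sample_id with ``group`` and ``er_status``
    normalised to the closed vocabularies.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    required = {"sample_id", "group"}
    if not required.issubset(df.columns):
        raise ValidationError(f"sample sheet must have columns {sorted(required)}")
    df = df.set_index("sample_id")
    _check_unique(df.index, "sample ids")
    df["group"] = df["group"].map(normalize_group)
    if "er_status" in df.columns:
        df["er_status"] = df["er_status"].map(normalize_er)
    else:
        df["er_status"] = "unknown"
    return df[["group", "er_status"]]


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index_label="sample_id")


def read_cpg_annotation(path) -> pd.DataFrame:
    """Read CpG annotation (cpg_id, gene_id, tss_distance).

    ``tss_distance`` is a signed integer in bp: negative = upstream of the
    transcription start site, 0 = at the TSS.
    """
    df = pd.read_csv(path, sep="\t", dtype={"cpg_id": str, "gene_id": str})
    if not {"cpg_id", "gene_id", "tss_distance"}.issubset(df.columns):
        raise ValidationError(
            "CpG annotation must have columns cpg_id, gene_id, tss_distance"
        )
    df = df.set_index("cpg_id")
    _check_unique(df.index, "CpG ids")
    df["tss_distance"] = df["tss_distance"].astype(int)
    return df[["gene_id", "tss_distance"]]


def read_probe_annotation(path) -> pd.DataFrame:
    """Read expression-probe annotation (probe_id, gene_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_id"}.issubset(df.columns):
        raise ValidationError("probe annotation must have columns probe_id, gene_id")
    df = df.set_index("probe_id")
    _check_unique(df.index, "probe ids")
    return df[["gene_id"]]


def write_annotation(df: pd.DataFrame, path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)
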