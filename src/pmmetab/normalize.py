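"""Normalization strategies: pool-based batch correction, IS division, PQN.

Three ratio-based corrections for positive peak-area tables:

``batch_correct``
    divides every area by the mean pool-sample area of the same analyte in
    the same measurement batch, removing batch-level instrument drift (each
    batch's pool mean becomes exactly 1);

``is_normalize``
    divides each analyte by its mapped isotope-labelled internal standard,
    cancelling per-sample extraction/dilution factors;

``pqn_normalize``
    probabilistic quotient normalization: per sample, the median of the
    analyte-wise quotients against a reference spectrum (grand pool mean by
    default) is taken as that sample's dilution factor and divided out.
    PQN assumes that fewer than half of the analytes carry real effects; on
    panels where most analytes drift with time since death the factor
    absorbs part of the drift and attenuates it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NormalizedTable",
    "NormalizationError",
    "DEFAULT_IS_MAP",
    "DEFAULT_IS",
    "batch_correct",
    "is_normalize",
    "pqn_normalize",
]


class NormalizationError(ValueError):
    """Raised when a normalization contract is violated."""


#: Analyte -> matching isotope-labelled standard; everything unmapped falls
#: back to phenylalanine-d1.
DEFAULT_IS_MAP = {
    "Creatinine": "creatinine-d3",
    "Arginine": "arginine-13C6",
    "Phenylalanine": "phenylalanine-d1",
}
DEFAULT_IS = "phenylalanine-d1"


@dataclass
class NormalizedTable:
    """Normalized sample x analyte matrix with provenance.

    ``values`` has the same shape and labels as the input table; positivity
    is preserved by construction.
    """

    values: pd.DataFrame
    mode: str
    pool_means: pd.DataFrame | None = None  # batch x analyte
    pqn_factors: pd.Series | None = None  # per sample
    notes: list[str] = field(default_factory=list)


def _check_positive(table: pd.DataFrame, label: str) -> None:
    arr = table.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise NormalizationError(f"{label} must be strictly positive and finite")


def batch_correct(
    areas: pd.DataFrame,
    meta: pd.DataFrame,
) -> NormalizedTable:
    """Divide each area by the batch's mean pool area of that analyte.

    ``areas``: sample x analyte matrix (study and pool rows); ``meta``:
    frame indexed like ``areas`` with ``batch_id`` and ``sample_type``
    columns.  Every batch present must have at least one pool record; pool
    rows are normalized by their own batch mean, so corrected pool means
    equal 1 exactly.
    """
    _check_positive(areas, "peak areas")
    meta = meta.loc[areas.index]
    pool_mask = meta["sample_type"] == "pool"
    if not pool_mask.any():
        raise NormalizationError("no pool records in table")
    pool_means = (
        areas[pool_mask].groupby(meta.loc[pool_mask, "batch_id"]).mean()
    )
    missing_batches = set(meta["batch_id"]) - set(pool_means.index)
    if missing_batches:
        raise NormalizationError(
            f"batches without pool records: {sorted(missing_batches)}"
        )
    bad = pool_means.isna() | (pool_means <= 0)
    if bad.to_numpy().any():
        rows, cols = np.where(bad.to_numpy())
        pairs = [(pool_means.index[r], pool_means.columns[c])
                 for r, c in zip(rows, cols)]
        raise NormalizationError(f"missing/invalid pool mean for {pairs[:5]}")
    divisor = pool_means.loc[meta["batch_id"]].to_numpy()
    corrected = pd.DataFrame(
        areas.to_numpy() / divisor, index=areas.index, columns=areas.columns
    )
    return NormalizedTable(corrected, mode="batch_only", pool_means=pool_means)


def is_normalize(
    areas: pd.DataFrame,
    is_areas: pd.DataFrame,
    is_map: dict[str, str] | None = None,
    default_is: str = DEFAULT_IS,
) -> NormalizedTable:
    """Divide each analyte by its mapped internal-standard area.

    ``is_areas``: sample x IS matrix (columns named like ``is_<name>`` or
    plain names).  Unmapped analytes fall back to ``default_is`` with a
    logged notice; a missing or non-positive IS area is a sample-level
    error.
    """
    _check_positive(areas, "peak areas")
    is_map = dict(DEFAULT_IS_MAP if is_map is None else is_map)
    columns = {c.removeprefix("is_"): c for c in is_areas.columns}
    notes = []
    out = pd.DataFrame(index=areas.index, columns=areas.columns, dtype=float)
    for analyte in areas.columns:
        is_name = is_map.get(analyte)
        if is_name is None:
            is_name = default_is
            notes.append(f"{analyte}: no matching IS, using {default_is}")
        if is_name not in columns:
            raise NormalizationError(f"internal standard {is_name!r} not in table")
        divisor = is_areas.loc[areas.index, columns[is_name]].astype(float)
        bad = divisor.isna() | (divisor <= 0)
        if bad.any():
            raise NormalizationError(
                f"missing/non-positive {is_name} area for samples "
                f"{list(areas.index[bad])[:5]}"
            )
        out[analyte] = areas[analyte] / divisor
    return NormalizedTable(out, mode="is_norm", notes=notes)


def pqn_normalize(
    table: pd.DataFrame,
    reference: str = "pool_mean",
    meta: pd.DataFrame | None = None,
) -> NormalizedTable:
    """Probabilistic quotient normalization of a (batch-corrected) table.

    ``reference="pool_mean"`` uses the grand mean spectrum of the pool rows
    (requires ``meta`` with ``sample_type``); ``"median_all"`` uses the
    median spectrum over all samples.  The per-sample factor is the median
    over analytes of value/reference; every row is divided by its factor.
    """
    _check_positive(table, "normalized values")
    if table.shape[1] < 2:
        raise NormalizationError("PQN needs at least two analytes")
    if reference == "pool_mean":
        if meta is None or "sample_type" not in meta.columns:
            raise NormalizationError("pool_mean reference needs sample_type metadata")
        pool_mask = meta.loc[table.index, "sample_type"] == "pool"
        if not pool_mask.any():
            raise NormalizationError("no pool records for PQN reference")
        ref = table[pool_mask.to_numpy()].mean(axis=0)
    elif reference == "median_all":
        ref = table.median(axis=0)
    else:
        raise NormalizationError(f"unknown PQN reference {reference!r}")
    if (ref <= 0).any():
        raise NormalizationError("non-positive reference spectrum")
    quotients = table.to_numpy() / ref.to_numpy()[None, :]
    factors = pd.Series(np.median(quotients, axis=1), index=table.index,
                        name="pqn_factor")
    normalized = pd.DataFrame(
        table.to_numpy() / factors.to_numpy()[:, None],
        index=table.index,
        columns=table.columns,
    )
    return NormalizedTable(normalized, mode="pqn", pqn_factors=factors)
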