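"""Observation table for live fuel moisture content (LFMC) monitoring data.

The canonical table has one row per composite field sample with columns
``site`` (W/E), ``plot`` (id within site), ``point`` (within-plot sampling
point), ``leaf_type`` (GW, GE, SM, SS), ``day`` (integer days since the
first sampling date) and ``lfmc`` (percent of dry weight).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, LabelingError, SchemaError

__all__ = ["LfmcDataset", "read_lfmc", "LEAF_TYPES", "SITE_OF_LEAF_TYPE"]

logger = logging.getLogger(__name__)

LEAF_TYPES = ("GW", "GE", "SM", "SS")
#: design constraint: grasses-west only at site W, the other three at site E
SITE_OF_LEAF_TYPE = {"GW": "W", "GE": "E", "SM": "E", "SS": "E"}

CANONICAL_COLUMNS = ("site", "plot", "point", "leaf_type", "day", "lfmc")

# header synonyms tried (case-insensitively) when no explicit mapping is given
_DEFAULT_SYNONYMS = {
    "site": ("site",),
    "plot": ("plot", "plot_id"),
    "point": ("point", "sample", "rep", "replicate"),
    "leaf_type": ("leaf_type", "leaftype", "type", "leaf", "species"),
    "day": ("day", "days", "time", "t", "date"),
    "lfmc": ("lfmc", "moisture", "y", "response"),
}


@dataclass
class LfmcDataset:
    """Validated LFMC observation table.

    Attributes
    ----------
    table : pandas.DataFrame
        Canonical columns plus a ``plot_key`` column (site-qualified plot id,
        e.g. ``"W1"``) making plots unique across sites.
    n_dropped : int
        Rows removed at load time because the response was missing.
    """

    table: pd.DataFrame
    n_dropped: int = 0

    # -- construction -------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame, validate: bool = True,
                   require_nonnegative: bool = True) -> "LfmcDataset":
        df = df.copy()
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns {missing}; have {list(df.columns)}")
        n0 = len(df)
        df = df.dropna(subset=["lfmc"]).reset_index(drop=True)
        n_dropped = n0 - len(df)
        if n_dropped:
            logger.info("dropped %d rows with missing LFMC", n_dropped)
        if df.empty:
            raise EmptyInputError("no rows with a usable LFMC response")
        df["site"] = df["site"].astype(str)
        df["plot"] = df["plot"].astype(str)
        df["point"] = df["point"].astype(str)
        df["leaf_type"] = df["leaf_type"].astype(str)
        df["day"] = pd.to_numeric(df["day"])
        df["lfmc"] = pd.to_numeric(df["lfmc"]).astype(float)
        df["plot_key"] = df["site"] + df["plot"]
        ds = cls(table=df, n_dropped=n_dropped)
        if validate:
            ds._validate(require_nonnegative)
        return ds

    def _validate(self, require_nonnegative: bool = True) -> None:
        df = self.table
        bad = set(df["leaf_type"]) - set(LEAF_TYPES)
        if bad:
            raise LabelingError(f"unknown leaf type(s) {sorted(bad)}; expected {LEAF_TYPES}")
        for lt, site in SITE_OF_LEAF_TYPE.items():
            rows = df[df["leaf_type"] == lt]
            if not rows.empty and not (rows["site"] == site).all():
                raise LabelingError(f"leaf type {lt} must occur only at site {site}")
        if (df["day"] < 0).any():
            raise LabelingError("day must be >= 0 (days since first measurement)")
        if require_nonnegative and (df["lfmc"] < 0).any():
            raise LabelingError("lfmc must be >= 0")

    # -- convenience --------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def plots(self) -> list:
        return sorted(self.table["plot_key"].unique())

    @property
    def leaf_types(self) -> list:
        return [lt for lt in LEAF_TYPES if lt in set(self.table["leaf_type"])]

    @property
    def days(self) -> np.ndarray:
        return np.sort(self.table["day"].unique())

    def __len__(self) -> int:
        return self.n

    # -- io ------------------------------------------------------------
    def write(self, path) -> None:
        """Write the canonical columns as tab-separated text."""
        self.table.loc[:, list(CANONICAL_COLUMNS)].to_csv(path, sep="\t", index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"LfmcDataset(n={self.n}, plots={len(self.plots)}, "
            f"leaf_types={self.leaf_types}, dates={len(self.days)})"
        )


def _resolve_columns(headers, mapping):
    """Map canonical names to actual headers, via config or synonyms."""
    lower = {str(h).lower(): h for h in headers}
    out = {}
    mapping = dict(mapping or {})
    for canon in CANONICAL_COLUMNS:
        if canon in mapping:
            actual = mapping[canon]
            if actual not in headers:
                raise SchemaError(
                    f"mapped column {actual!r} for {canon!r} not in file; headers: {list(headers)}"
                )
            out[canon] = actual
            continue
        for syn in _DEFAULT_SYNONYMS[canon]:
            if syn in lower:
                out[canon] = lower[syn]
                break
        else:
            raise SchemaError(
                f"cannot locate a column for {canon!r}; headers: {list(headers)} "
                f"(provide a column mapping)"
            )
    return out


def read_lfmc(path, columns=None, validate: bool = True) -> LfmcDataset:
    """Read a delimited text file of LFMC observations.

    The delimiter (tab, comma or whitespace) is sniffed automatically and a
    header row is required.  ``columns`` may map canonical names
    (site/plot/point/leaf_type/day/lfmc) to the file's actual headers.
    Calendar dates in the day column are converted to integer days since the
    earliest date present.  Rows with a missing response are dropped and
    counted in ``n_dropped``.
    """
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, csv.Error):
        raise EmptyInputError(f"{path} is empty or undelimited") from None
    if df.empty:
        raise EmptyInputError(f"{path} has a header but no rows")
    resolved = _resolve_columns(df.columns, columns)
    df = df.rename(columns={v: k for k, v in resolved.items()})
    # calendar dates -> day numbers relative to the earliest date
    if not pd.api.types.is_numeric_dtype(df["day"]):
        dates = pd.to_datetime(df["day"], errors="raise")
        df["day"] = (dates - dates.min()).dt.days
    return LfmcDataset.from_frame(df[list(CANONICAL_COLUMNS)], validate=validate)
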