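"""Clonotype tables: the per-sample unit all repertoire metrics consume.

A :class:`ClonotypeTable` holds one sample's clonotypes — each a unique
rearranged TRB sequence keyed by (V call, J call, CDR3) — together with
read counts and frequencies.  Frequencies are always recomputed from
counts; any frequency column carried by an input file is advisory only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .errors import EmptySampleError, ValidationError

#: Canonical column order of the underlying DataFrame.
COLUMNS = ["count", "freq", "cdr3nt", "cdr3aa", "v", "d", "j"]

KeyLevel = Literal["nt", "aa"]


def _key_columns(level: KeyLevel) -> list[str]:
    if level == "nt":
        return ["v", "j", "cdr3nt"]
    if level == "aa":
        return ["v", "j", "cdr3aa"]
    raise ValidationError(f"unknown clonotype identity level: {level!r}")


@dataclass
class ClonotypeTable:
    """One sample's clonotype counts plus its metadata.

    Parameters
    ----------
    sample_id, subject_id : str
        Sample and subject identifiers.
    subset : str
        Sorted cell subset, typically ``"treg"``, ``"tcon"`` or ``"other"``.
    timepoint : int
        Days relative to DLI (may be negative for pre-infusion samples).
    data : pandas.DataFrame
        Columns ``count, freq, cdr3nt, cdr3aa, v, d, j``; one row per
        clonotype. ``freq`` is recomputed from ``count`` on construction.
    flag : str
        Bookkeeping flag set by normalization ("" | "under_depth" |
        "not_normalized").
    """

    sample_id: str
    subject_id: str = ""
    subset: str = "other"
    timepoint: int = 0
    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=COLUMNS))
    flag: str = ""

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"table data missing columns: {missing}")
        df = df[COLUMNS].reset_index(drop=True)
        counts = df["count"].to_numpy()
        if len(counts) and not np.issubdtype(counts.dtype, np.integer):
            frac = np.asarray(counts, dtype=float)
            if np.any(frac != np.floor(frac)):
                bad = int(np.argmax(frac != np.floor(frac)))
                raise ValidationError(f"non-integer count at row {bad}")
            counts = frac.astype(np.int64)
        counts = counts.astype(np.int64, copy=False)
        if np.any(counts < 0):
            bad = int(np.argmax(counts < 0))
            raise ValidationError(f"negative count at row {bad}")
        df["count"] = counts
        total = int(counts.sum())
        df["freq"] = counts / total if total > 0 else 0.0
        self.data = df

    # ------------------------------------------------------------------
    @property
    def total_reads(self) -> int:
        return int(self.data["count"].sum())

    @property
    def n_unique(self) -> int:
        return int(len(self.data))

    def counts(self) -> np.ndarray:
        return self.data["count"].to_numpy()

    def frequencies(self) -> np.ndarray:
        return self.data["freq"].to_numpy()

    def keys(self, level: KeyLevel = "nt") -> pd.Index:
        cols = _key_columns(level)
        return pd.Index(
            self.data[cols].astype(str).agg("|".join, axis=1), name="clonotype_key"
        )

    def require_nonempty(self) -> None:
        if self.n_unique == 0 or self.total_reads == 0:
            raise EmptySampleError(f"sample {self.sample_id!r} has zero reads")

    # ------------------------------------------------------------------
    def aggregate(self, level: KeyLevel = "nt") -> "ClonotypeTable":
        """Merge rows with identical clonotype identity at `level`.

        Counts are summed; frequencies renormalized; the representative
        row for each key is the first occurrence in input order (so CDR3
        nucleotide of an aa-level group is the first variant seen).
        """
        cols = _key_columns(level)
        df = self.data
        if df.empty:
            return replace(self, data=df.copy())
        grouped = df.groupby(df[cols].astype(str).agg("|".join, axis=1), sort=False)
        first = grouped.nth(0).reset_index(drop=True)
        first["count"] = grouped["count"].sum().to_numpy()
        return replace(self, data=first)

    def sorted_by_abundance(self) -> "ClonotypeTable":
        """Rows sorted by decreasing count, ties broken by nt key (lexicographic)."""
        df = self.data.copy()
        df["_key"] = self.keys("nt")
        df = df.sort_values(["count", "_key"], ascending=[False, True], kind="mergesort")
        return replace(self, data=df.drop(columns="_key").reset_index(drop=True))

    def with_counts(self, counts: np.ndarray, flag: str | None = None) -> "ClonotypeTable":
        """Return a copy with new counts; rows drawn to zero are dropped."""
        df = self.data.copy()
        df["count"] = np.asarray(counts, dtype=np.int64)
        df = df[df["count"] > 0]
        return replace(self, data=df.reset_index(drop=True),
                       flag=self.flag if flag is None else flag)
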