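"""Reading and writing clonotype tables in the two common dialects.

Supported dialects:

* ``vdjtools`` — tab-separated with columns ``count, freq, cdr3nt, cdr3aa,
  v, d, j`` (a leading ``#`` on the first header field is tolerated).
* ``airr`` — AIRR Community Rearrangement TSV; we consume
  ``duplicate_count, junction, junction_aa, v_call, j_call`` (and
  ``d_call`` when present).

Frequencies from input files are never trusted: they are recomputed from
counts, with a logged warning when the file's ``freq`` column disagrees.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .errors import EmptySampleError, FormatError, ValidationError
from .tables import COLUMNS, ClonotypeTable

logger = logging.getLogger(__name__)

Dialect = Literal["vdjtools", "airr"]

_VDJTOOLS_REQUIRED = ["count", "freq", "cdr3nt", "cdr3aa", "v", "d", "j"]
_AIRR_REQUIRED = ["duplicate_count", "junction", "junction_aa", "v_call", "j_call"]

_AIRR_TO_CANON = {
    "duplicate_count": "count",
    "junction": "cdr3nt",
    "junction_aa": "cdr3aa",
    "v_call": "v",
    "d_call": "d",
    "j_call": "j",
}


def read_clonotype_table(
    path: str | Path,
    dialect: Dialect = "vdjtools",
    meta: Mapping | None = None,
) -> ClonotypeTable:
    """Read one sample's clonotype table.

    Parameters
    ----------
    path : path to a TSV file in the given dialect.
    dialect : ``"vdjtools"`` or ``"airr"``.
    meta : sample metadata mapping; recognized keys are ``sample_id``,
        ``subject_id``, ``subset`` and ``timepoint``. ``sample_id``
        defaults to the file stem.

    Returns
    -------
    ClonotypeTable with frequencies recomputed from counts and input row
    order preserved (aggregation of duplicate keys is a separate step).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    raw.columns = [c.lstrip("#").strip() for c in raw.columns]

    if dialect == "vdjtools":
        required = _VDJTOOLS_REQUIRED
        rename: Mapping[str, str] = {}
    elif dialect == "airr":
        required = _AIRR_REQUIRED
        rename = _AIRR_TO_CANON
    else:
        raise ValidationError(f"unknown dialect: {dialect!r}")

    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing mandatory {dialect} column(s): {', '.join(missing)}"
        )

    df = raw.rename(columns=rename)
    if "d" not in df.columns:
        df["d"] = "."
    df["d"] = df["d"].fillna(".")

    try:
        counts = pd.to_numeric(df["count"])
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path.name}: non-numeric count column") from exc
    bad = counts.index[counts < 0]
    if len(bad):
        raise ValidationError(f"{path.name}: negative count at row {bad[0]}")
    df["count"] = counts

    file_freq = None
    if "freq" in df.columns:
        file_freq = pd.to_numeric(df["freq"], errors="coerce")
    df["freq"] = 0.0  # recomputed by ClonotypeTable

    meta = dict(meta or {})
    table = ClonotypeTable(
        sample_id=str(meta.get("sample_id", path.stem)),
        subject_id=str(meta.get("subject_id", "")),
        subset=str(meta.get("subset", "other")),
        timepoint=int(meta.get("timepoint", 0)),
        data=df[COLUMNS],
    )
    if table.total_reads == 0:
        raise EmptySampleError(f"{path.name}: zero total count")

    if file_freq is not None and len(file_freq) == table.n_unique:
        recomputed = table.frequencies()
        if np.nanmax(np.abs(file_freq.to_numpy(dtype=float) - recomputed), initial=0.0) > 1e-6:
            logger.warning(
                "%s: freq column disagrees with counts; frequencies recomputed",
                path.name,
            )
    return table


def write_clonotype_table(table: ClonotypeTable, path: str | Path,
                          dialect: Dialect = "vdjtools") -> Path:
    """Write a table to TSV in the given dialect. Returns the path written."""
    path = Path(path)
    df = table.data
    if dialect == "vdjtools":
        out = df[COLUMNS]
    elif dialect == "airr":
        out = df.rename(columns={v: k for k, v in _AIRR_TO_CANON.items()})
        out = out[["duplicate_count", "junction", "junction_aa", "v_call", "d_call", "j_call"]]
        # AIRR requires productive/locus context in full exports; for clonotype
        # round-trips the five schema columns above are sufficient.
    else:
        raise ValidationError(f"unknown dialect: {dialect!r}")
    out.to_csv(path, sep="\t", index=False)
    return path


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    """Write a normalized-sample manifest (sample_id, input_reads, output_reads, flag)."""
    path = Path(path)
    pd.DataFrame(rows, columns=["sample_id", "input_reads", "output_reads", "flag"]).to_csv(
        path, sep="\t", index=False
    )
    return path
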