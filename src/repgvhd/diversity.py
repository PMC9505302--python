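"""Repertoire diversity and clonality statistics.

Three statistics summarize a clonotype table:

* **Inverse Simpson index** ``1/D = 1 / sum_i p_i**2`` with ``p_i`` the
  clone frequencies — the effective number of equally abundant clones.
  Lower values indicate clonal expansion.
* **Clonal-space occupancy** — for a repertoire fraction ``t`` (25, 50,
  75, 100%), the minimal number of most-abundant clonotypes whose summed
  frequency reaches at least ``t``.  Few clones covering 25% of the
  repertoire means strong expansion of dominant clones.
* **Top-N clonal proportion** — the summed frequency of the N (default
  20) most abundant clonotypes.  Large values indicate expansion.

Ties in abundance are broken deterministically (count descending, then
lexicographic clonotype key) so results are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .tables import ClonotypeTable

DEFAULT_THRESHOLDS = (0.25, 0.50, 0.75, 1.00)
DEFAULT_TOP_N = 20


@dataclass
class MetricsBundle:
    """Per-sample repertoire statistics."""

    sample_id: str
    inv_simpson: float
    clonal_space: dict[float, int]
    top_n_proportion: float
    n_unique: int
    top_n: int = DEFAULT_TOP_N
    meta: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "sample_id": self.sample_id,
            **self.meta,
            "inv_simpson": self.inv_simpson,
        }
        for t, k in sorted(self.clonal_space.items()):
            row[f"cs{int(round(t * 100))}"] = k
        row[f"top{self.top_n}"] = self.top_n_proportion
        row["n_unique"] = self.n_unique
        return row


def inverse_simpson(table: ClonotypeTable) -> float:
    """Inverse Simpson diversity 1/D = 1 / sum(p_i^2).

    Equals the number of clones when all frequencies are equal and 1 for
    a monoclonal sample.
    """
    table.require_nonempty()
    p = table.frequencies()
    return float(1.0 / np.sum(p * p))


def _sorted_counts(table: ClonotypeTable) -> np.ndarray:
    return table.sorted_by_abundance().counts()


def clonal_space_occupancy(
    table: ClonotypeTable, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> dict[float, int]:
    """Minimal number of most-abundant clonotypes covering each threshold.

    For each threshold ``t`` in (0, 1], returns the minimal ``k`` such
    that the ``k`` largest frequencies sum to at least ``t``.  Computed
    on integer count cumsums (k largest counts >= t * total_reads) so
    the boundary is exact, not subject to float accumulation.
    """
    table.require_nonempty()
    thresholds = list(thresholds)
    for t in thresholds:
        if not (0.0 < t <= 1.0):
            raise ValidationError(f"clonal-space threshold must be in (0, 1], got {t}")
    cum = np.cumsum(_sorted_counts(table))
    total = cum[-1]
    return {
        t: int(np.searchsorted(cum, t * total - 1e-9, side="left") + 1)
        for t in thresholds
    }


def top_n_proportion(table: ClonotypeTable, n: int = DEFAULT_TOP_N) -> float:
    """Summed frequency of the n most abundant clonotypes (all, if n >= n_unique)."""
    if n < 1:
        raise ValidationError(f"top-N requires n >= 1, got {n}")
    table.require_nonempty()
    counts = _sorted_counts(table)
    return float(counts[:n].sum() / counts.sum())


def compute_metrics(
    table: ClonotypeTable,
    n: int = DEFAULT_TOP_N,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> MetricsBundle:
    """All three statistics for one sample, bundled with its metadata."""
    return MetricsBundle(
        sample_id=table.sample_id,
        inv_simpson=inverse_simpson(table),
        clonal_space=clonal_space_occupancy(table, thresholds),
        top_n_proportion=top_n_proportion(table, n),
        n_unique=table.n_unique,
        top_n=n,
        meta={
            "subject_id": table.subject_id,
            "subset": table.subset,
            "timepoint": table.timepoint,
            "flag": table.flag,
        },
    )
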