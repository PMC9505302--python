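"""Sequencing-depth normalization by random downsampling of reads.

Samples sequenced to different depths are not directly comparable on
diversity/clonality statistics (deeper samples see more rare clones), so
every sample is randomly downsampled to a common target — 20,000 reads by
default — before any metric is computed.

The default scheme draws reads uniformly *without replacement* from the
observed read pool, i.e. the per-clone downsampled counts follow a
multivariate hypergeometric distribution over the input counts.  A
with-replacement (multinomial) variant is available for sensitivity
checks.  Samples below the target cannot be equalized; the `short_policy`
decides their fate (default: flag and exclude downstream).
"""

from __future__ import annotations

from typing import Literal

import numpy as np

from .errors import DepthError, ValidationError
from .tables import ClonotypeTable

ShortPolicy = Literal["skip", "error", "keep"]

DEFAULT_TARGET_READS = 20_000

#: Flag set on tables passed through under depth.
UNDER_DEPTH = "under_depth"


def downsample_reads(
    table: ClonotypeTable,
    target_reads: int = DEFAULT_TARGET_READS,
    seed: int | np.random.Generator = 0,
    short_policy: ShortPolicy = "skip",
    scheme: Literal["hypergeometric", "multinomial"] = "hypergeometric",
) -> ClonotypeTable:
    """Randomly downsample a sample to `target_reads` total reads.

    Parameters
    ----------
    table : validated clonotype table.
    target_reads : common depth to normalize to (> 0).
    seed : integer seed or a numpy Generator. The same (table, target,
        seed) always yields a bit-identical result.
    short_policy : what to do when the sample has fewer reads than the
        target: ``"skip"`` returns the table unchanged but flagged
        ``under_depth`` (callers exclude it from comparisons),
        ``"error"`` raises :class:`DepthError`, ``"keep"`` returns it
        flagged but intended for use as-is.
    scheme : ``"hypergeometric"`` (without replacement; default) or
        ``"multinomial"`` (with replacement; sensitivity checks only).

    Returns
    -------
    ClonotypeTable whose counts sum exactly to `target_reads`; clonotypes
    drawn to count zero are dropped; no new clonotypes ever appear.
    """
    if target_reads <= 0:
        raise ValidationError(f"target_reads must be positive, got {target_reads}")
    total = table.total_reads
    if total < target_reads:
        if short_policy == "error":
            raise DepthError(
                f"sample {table.sample_id!r}: {total} reads < target {target_reads}"
            )
        if short_policy in ("skip", "keep"):
            return table.with_counts(table.counts(), flag=UNDER_DEPTH)
        raise ValidationError(f"unknown short_policy: {short_policy!r}")
    if total == target_reads:
        return table.with_counts(table.counts())

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = table.counts()
    if scheme == "hypergeometric":
        new = rng.multivariate_hypergeometric(counts, target_reads, method="marginals")
    elif scheme == "multinomial":
        new = rng.multinomial(target_reads, counts / counts.sum())
    else:
        raise ValidationError(f"unknown sampling scheme: {scheme!r}")
    return table.with_counts(new)
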