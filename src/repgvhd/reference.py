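"""Healthy-control reference bands, expansion classification, longitudinal pairs.

Patient repertoires are judged against a reference distribution of
inverse Simpson diversity built from repeatedly sampled healthy
individuals.  A sample is called **expanded** when its 1/D falls strictly
below the healthy 25th percentile, and **healthy-like** otherwise
(values exactly at the percentile are healthy-like).

Because healthy individuals contribute several samples each, the band
can be built two ways: over per-individual mean values (default — each
individual counts once) or over every healthy sample.  Both are exposed;
the choice is recorded on the band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import PairingError, ReferenceError_, ValidationError

ReferenceMode = Literal["per_individual", "all_samples"]

EXPANDED = "expanded"
HEALTHY_LIKE = "healthy_like"


@dataclass
class ReferenceBand:
    """Healthy-control summary used for classification and IQR bands."""

    subset: str
    individual_means: dict[str, float]
    p25: float
    p75: float
    mode: ReferenceMode

    @property
    def iqr(self) -> tuple[float, float]:
        return (self.p25, self.p75)


@dataclass
class SampleClassification:
    sample_id: str
    value: float
    label: str  # EXPANDED | HEALTHY_LIKE
    threshold: float


@dataclass
class LongitudinalPair:
    """Pre/post metric values around a clinical anchor for one subject."""

    subject_id: str
    pre_timepoint: int
    post_timepoint: int
    pre_value: float
    post_value: float
    group: str = ""

    @property
    def percent_change(self) -> float:
        return percent_change(self.pre_value, self.post_value)


def build_hc_reference(
    samples: Iterable[tuple[str, float]],
    mode: ReferenceMode = "per_individual",
    subset: str = "other",
) -> ReferenceBand:
    """Build the healthy-control reference band.

    Parameters
    ----------
    samples : iterable of (individual_id, metric value) pairs; repeated
        individuals contribute their arithmetic mean in per_individual mode.
    mode : ``"per_individual"`` pools one mean per healthy individual;
        ``"all_samples"`` pools every sample value.

    Percentiles use linear interpolation between order statistics.
    """
    df = pd.DataFrame(samples, columns=["individual_id", "value"])
    if df["individual_id"].nunique() < 2:
        raise ReferenceError_(
            f"need >= 2 healthy individuals, got {df['individual_id'].nunique()}"
        )
    means = df.groupby("individual_id", sort=True)["value"].mean()
    pooled = means.to_numpy() if mode == "per_individual" else df["value"].to_numpy()
    if mode not in ("per_individual", "all_samples"):
        raise ValidationError(f"unknown reference mode: {mode!r}")
    p25, p75 = np.percentile(pooled, [25, 75])  # linear interpolation
    return ReferenceBand(
        subset=subset,
        individual_means=means.to_dict(),
        p25=float(p25),
        p75=float(p75),
        mode=mode,
    )


class ExpansionClassifier:
    """Percentile-threshold classifier for clonal expansion.

    Follows the fit/predict convention: ``fit`` ingests healthy-control
    (individual_id, 1/D) pairs and stores the 25th-percentile threshold;
    ``predict`` labels values as ``"expanded"`` (strictly below the
    threshold) or ``"healthy_like"`` (at or above it).

    Attributes set by fit: ``band_`` (the ReferenceBand), ``threshold_``.
    """

    def __init__(self, mode: ReferenceMode = "per_individual", percentile: float = 25.0):
        self.mode = mode
        self.percentile = percentile

    def get_params(self, deep: bool = True) -> dict:
        return {"mode": self.mode, "percentile": self.percentile}

    def set_params(self, **params) -> "ExpansionClassifier":
        for k, v in params.items():
            if k not in ("mode", "percentile"):
                raise ValidationError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, samples: Iterable[tuple[str, float]], subset: str = "other"):
        samples = list(samples)
        band = build_hc_reference(samples, mode=self.mode, subset=subset)
        if self.percentile != 25.0:
            df = pd.DataFrame(band.individual_means.items(), columns=["i", "value"])
            pooled = (
                df["value"].to_numpy()
                if self.mode == "per_individual"
                else np.asarray([v for _, v in samples])
            )
            band.p25 = float(np.percentile(pooled, self.percentile))
        self.band_ = band
        self.threshold_ = band.p25
        return self

    def predict(self, values: Sequence[float]) -> np.ndarray:
        if not hasattr(self, "threshold_"):
            raise ValidationError("classifier is not fitted")
        values = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("non-finite metric value")
        return np.where(values < self.threshold_, EXPANDED, HEALTHY_LIKE)


def classify_sample(value: float, band: ReferenceBand,
                    sample_id: str = "") -> SampleClassification:
    """Label one sample against a built reference band (strict-< rule)."""
    if not np.isfinite(value):
        raise ValidationError(f"non-finite metric value: {value}")
    label = EXPANDED if value < band.p25 else HEALTHY_LIKE
    return SampleClassification(sample_id=sample_id, value=float(value),
                                label=label, threshold=band.p25)


def percent_change(pre: float, post: float) -> float:
    """Relative change in percent: 100 * (post - pre) / pre."""
    if not (np.isfinite(pre) and np.isfinite(post)):
        raise ValidationError("percent_change requires finite values")
    if pre == 0:
        raise ValidationError("percent_change undefined for pre == 0")
    return 100.0 * (post - pre) / pre


def pair_longitudinal(
    samples: pd.DataFrame,
    anchors: dict[str, int],
    control_subjects: Sequence[str] = (),
    groups: dict[str, str] | None = None,
) -> list[LongitudinalPair]:
    """Form pre/post value pairs around each subject's clinical anchor.

    Parameters
    ----------
    samples : DataFrame with columns ``subject_id, timepoint, value`` —
        one row per sample (timepoints in days).
    anchors : subject_id -> anchor day (e.g. day of aGVHD onset) for
        event subjects.
    control_subjects : subjects without an event, to be matched for
        timing: the pair of consecutive samples minimizing the summed
        distance to the event group's median pre/post sampling days is
        chosen (ties broken toward earlier timepoints).
    groups : optional subject_id -> group label carried onto the pairs.

    Event subjects pair the latest sample strictly before the anchor with
    the earliest sample at/after it.
    """
    groups = groups or {}
    pairs: list[LongitudinalPair] = []
    by_subject = {
        sid: g.sort_values("timepoint").reset_index(drop=True)
        for sid, g in samples.groupby("subject_id")
    }

    for sid, anchor in sorted(anchors.items()):
        if sid not in by_subject:
            raise PairingError(f"subject {sid!r} has no samples")
        g = by_subject[sid]
        pre = g[g["timepoint"] < anchor]
        post = g[g["timepoint"] >= anchor]
        if pre.empty:
            raise PairingError(f"subject {sid!r} has no sample before anchor day {anchor}")
        if post.empty:
            raise PairingError(f"subject {sid!r} has no sample at/after anchor day {anchor}")
        prow, qrow = pre.iloc[-1], post.iloc[0]
        pairs.append(LongitudinalPair(
            subject_id=sid,
            pre_timepoint=int(prow["timepoint"]), post_timepoint=int(qrow["timepoint"]),
            pre_value=float(prow["value"]), post_value=float(qrow["value"]),
            group=groups.get(sid, "event"),
        ))

    if control_subjects:
        if not pairs:
            raise PairingError("control matching requires at least one event pair")
        med_pre = float(np.median([p.pre_timepoint for p in pairs]))
        med_post = float(np.median([p.post_timepoint for p in pairs]))
        for sid in control_subjects:
            if sid not in by_subject:
                raise PairingError(f"control subject {sid!r} has no samples")
            g = by_subject[sid]
            if len(g) < 2:
                raise PairingError(f"control subject {sid!r} has < 2 timepoints")
            best = None
            for i in range(len(g) - 1):
                cost = abs(g.loc[i, "timepoint"] - med_pre) + abs(
                    g.loc[i + 1, "timepoint"] - med_post
                )
                if best is None or cost < best[0]:  # strict <: ties keep earlier pair
                    best = (cost, i)
            i = best[1]
            pairs.append(LongitudinalPair(
                subject_id=sid,
                pre_timepoint=int(g.loc[i, "timepoint"]),
                post_timepoint=int(g.loc[i + 1, "timepoint"]),
                pre_value=float(g.loc[i, "value"]),
                post_value=float(g.loc[i + 1, "value"]),
                group=groups.get(sid, "control"),
            ))
    return pairs
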