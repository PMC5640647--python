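"""Noise discrimination, quadrant thresholds and viability classification.

Viability is read from a two-colour co-stain: BOX (DiBAC4(3)), a lipophilic
anion that only enters cells with depolarised membranes, on the green FL1
channel; and propidium iodide (PI), excluded by intact membranes, on the
red FL3 channel. One threshold per channel partitions the FL1×FL3 plane
into four quadrants:

===========  =========  =====================================
quadrant     staining   physiological reading
===========  =========  =====================================
Q1 healthy   BOX− PI−   polarised, intact membrane
Q2 injured   BOX+ PI−   depolarised but still intact
Q3 dead      BOX+ PI+   permeabilised
Q4 anomalous BOX− PI+   not interpreted; reported separately
===========  =========  =====================================

Thresholds are placed at a high percentile (nearest-rank, default 99.5) of
an unstained control per channel — standard dye-negative gating. A value
exactly on a cut counts as negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ChannelError, SampleSizeError, ValidationError
from .events_io import EventTable

__all__ = [
    "QuadrantThresholds",
    "ViabilityFractions",
    "log_display",
    "noise_gate",
    "estimate_thresholds",
    "classify_viability",
    "scatter_summary",
    "ScatterSummary",
]

VIABILITY_LABELS = ("healthy", "injured", "dead", "anomalous")


@dataclass(frozen=True)
class QuadrantThresholds:
    """Per-channel positivity cuts on the linear scale, with provenance."""

    fl1_cut: float
    fl3_cut: float
    control_id: str = ""
    percentile: float | None = None

    def __post_init__(self) -> None:
        if self.fl1_cut <= 0 or self.fl3_cut <= 0:
            raise ValidationError("quadrant cuts must be > 0")

    def to_dict(self) -> dict:
        return {
            "fl1_cut": self.fl1_cut,
            "fl3_cut": self.fl3_cut,
            "control_id": self.control_id,
            "percentile": self.percentile,
        }


@dataclass(frozen=True)
class ViabilityFractions:
    """Healthy/injured/dead/anomalous decomposition of a sample."""

    healthy: float
    injured: float
    dead: float
    anomalous: float
    n_events: int
    warning: str | None = None

    def __post_init__(self) -> None:
        for name in VIABILITY_LABELS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} fraction {v} outside [0,1]")
        if self.n_events > 0:
            total = self.healthy + self.injured + self.dead + self.anomalous
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"viability fractions sum to {total}, not 1")

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in VIABILITY_LABELS}
        d["n_events"] = self.n_events
        if self.warning:
            d["warning"] = self.warning
        return d


@dataclass(frozen=True)
class ScatterSummary:
    """Mean, CV and log-scale heterogeneity of the scatter channels."""

    fsc_mean: float
    fsc_cv: float
    ssc_mean: float
    ssc_cv: float
    heterogeneity: float  # CV of log-displayed FSC
    n_events: int

    def to_dict(self) -> dict:
        return {
            "fsc_mean": self.fsc_mean,
            "fsc_cv": self.fsc_cv,
            "ssc_mean": self.ssc_mean,
            "ssc_cv": self.ssc_cv,
            "heterogeneity": self.heterogeneity,
            "n_events": self.n_events,
        }


def log_display(values) -> np.ndarray:
    """Display/threshold transform: ``log10(max(value, 1))``.

    Intensities below 1 arbitrary unit sit on the axis of a log dot plot;
    clipping at 1 keeps the transform defined at zero while leaving decades
    above 1 untouched. Analysis on the linear scale is unaffected.
    """
    values = np.asarray(values, dtype=np.float64)
    if (values < 0).any():
        raise ValidationError("log_display requires non-negative intensities")
    return np.log10(np.maximum(values, 1.0))


def noise_gate(events: EventTable, mode: str = "syto62", cut: float = 0.0) -> EventTable:
    """Separate cells from instrument noise/debris.

    ``mode="syto62"`` keeps events whose far-red DNA-stain signal (FL4)
    exceeds ``cut`` — Syto62 marks anything with a genome, which debris of
    cell-like size lacks. ``mode="scatter"`` thresholds FSC instead. The
    retained fraction is recorded on the returned table's metadata.
    """
    if mode == "syto62":
        channel = "FL4_A"
    elif mode == "scatter":
        channel = "FSC_A"
    else:
        raise ValidationError(f"unknown noise-gate mode {mode!r}")
    if channel not in events.channel_map:
        raise ChannelError(f"noise gate mode {mode!r} requires channel {channel}")
    mask = events.channel(channel) > cut
    gated = events.select(mask)
    gated.meta.retained_fraction = float(mask.mean()) if events.n_events else 1.0
    return gated


def _nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the ceil(p/100·n)-th smallest value."""
    n = len(values)
    rank = int(np.ceil(percentile / 100.0 * n))
    rank = min(max(rank, 1), n)
    return float(np.sort(values)[rank - 1])


def estimate_thresholds(
    control: EventTable, percentile: float = 99.5, control_id: str = ""
) -> QuadrantThresholds:
    """Place the quadrant cuts from an unstained (dye-negative) control.

    The cut on each fluorescence channel is the nearest-rank ``percentile``
    of the control's FL1 and FL3 intensities; with the default 99.5 the
    false-positive rate on a sample distributed like the control is 0.5 %
    per channel. Requires ≥100 control events.
    """
    for ch in ("FL1_A", "FL3_A"):
        if ch not in control.channel_map:
            raise ChannelError(f"control lacks channel {ch}")
    if control.n_events < 100:
        raise SampleSizeError(
            f"threshold estimation needs >=100 control events, got {control.n_events}"
        )
    if not 0.0 < percentile <= 100.0:
        raise ValidationError("percentile must be in (0, 100]")
    return QuadrantThresholds(
        fl1_cut=_nearest_rank_percentile(control.channel("FL1_A"), percentile),
        fl3_cut=_nearest_rank_percentile(control.channel("FL3_A"), percentile),
        control_id=control_id,
        percentile=percentile,
    )


def classify_viability(
    events: EventTable, thr: QuadrantThresholds
) -> tuple[np.ndarray, ViabilityFractions]:
    """Assign each event to a quadrant and summarise the fractions.

    BOX+ ⇔ FL1 strictly above ``fl1_cut``; PI+ ⇔ FL3 strictly above
    ``fl3_cut`` (values exactly equal to a cut are negative). An empty
    table yields zero fractions with a warning flag rather than an error.
    """
    for ch in ("FL1_A", "FL3_A"):
        if ch not in events.channel_map:
            raise ChannelError(f"viability classification requires channel {ch}")
    n = events.n_events
    if n == 0:
        empty = ViabilityFractions(0.0, 0.0, 0.0, 0.0, 0, warning="empty event table")
        return np.empty(0, dtype=object), empty

    box_pos = events.channel("FL1_A") > thr.fl1_cut
    pi_pos = events.channel("FL3_A") > thr.fl3_cut
    labels = np.empty(n, dtype=object)
    labels[~box_pos & ~pi_pos] = "healthy"
    labels[box_pos & ~pi_pos] = "injured"
    labels[box_pos & pi_pos] = "dead"
    labels[~box_pos & pi_pos] = "anomalous"
    fractions = ViabilityFractions(
        healthy=float(np.mean(~box_pos & ~pi_pos)),
        injured=float(np.mean(box_pos & ~pi_pos)),
        dead=float(np.mean(box_pos & pi_pos)),
        anomalous=float(np.mean(~box_pos & pi_pos)),
        n_events=n,
    )
    return labels, fractions


def scatter_summary(events: EventTable) -> ScatterSummary:
    """Size/granularity summary for liquid-vs-plate morphology comparison.

    Reports mean and coefficient of variation of FSC (size proxy) and SSC
    (granularity proxy), plus a heterogeneity index — the CV of the
    log-displayed FSC — which tracks the visual spread of a log-scale size
    histogram.
    """
    for ch in ("FSC_A", "SSC_A"):
        if ch not in events.channel_map:
            raise ChannelError(f"scatter summary requires channel {ch}")
    if events.n_events == 0:
        raise SampleSizeError("scatter summary needs at least one event")

    def _mean_cv(x: np.ndarray) -> tuple[float, float]:
        m = float(np.mean(x))
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        return m, (sd / m if m > 0 else 0.0)

    fsc = events.channel("FSC_A")
    ssc = events.channel("SSC_A")
    fsc_mean, fsc_cv = _mean_cv(fsc)
    ssc_mean, ssc_cv = _mean_cv(ssc)
    _, het = _mean_cv(log_display(fsc))
    return ScatterSummary(
        fsc_mean=fsc_mean,
        fsc_cv=fsc_cv,
        ssc_mean=ssc_mean,
        ssc_cv=ssc_cv,
        heterogeneity=het,
        n_events=events.n_events,
    )
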