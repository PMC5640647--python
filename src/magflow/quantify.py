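"""Fluorescence summaries, subpopulation mixtures, iron index, calibrations.

This module turns gated event tables into the scalar physiology readouts
of the workflow:

* **MFI** — mean fluorescence intensity, the arithmetic mean on the
  linear scale (the instrument-software convention), with dispersion
  reported as the coefficient of variation;
* **PHA subpopulations** — 1- vs 2-component Gaussian mixtures on
  log-displayed Pyr-546 fluorescence, selected by BIC, to detect the
  split between low- and high-PHA cells;
* **iron index** — the fold-quench of PG-SK fluorescence relative to an
  iron-free reference, inverted through the Stern–Volmer law to an
  estimate of chelatable iron in µM;
* **cell-count calibrations** — a through-origin least-squares fit of
  concentration against OD₅₆₅ (the relation is expressed as a per-OD
  equivalence, hence proportional), plus volumetric counting from the
  acquisition metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    ChannelError,
    FitError,
    ParameterError,
    SampleSizeError,
    ValidationError,
)
from .events_io import AcquisitionMeta, EventTable
from .gating import log_display
from .synthetic import QuenchModel

__all__ = [
    "FluorescenceSummary",
    "MixtureFit",
    "IronIndex",
    "CountCalibration",
    "summarize_fluorescence",
    "fit_subpopulations",
    "iron_index",
    "fit_count_calibration",
    "od_to_concentration",
    "events_to_concentration",
]


@dataclass(frozen=True)
class FluorescenceSummary:
    """MFI (linear arithmetic mean) and CV of one channel."""

    channel: str
    mfi: float
    cv: float
    n_events: int

    def __post_init__(self) -> None:
        if self.mfi < 0 or self.cv < 0:
            raise ValidationError("mfi and cv must be >= 0")
        if self.n_events < 1:
            raise ValidationError("n_events must be >= 1")

    def to_dict(self) -> dict:
        return {"channel": self.channel, "mfi": self.mfi, "cv": self.cv, "n_events": self.n_events}


@dataclass(frozen=True)
class MixtureFit:
    """Result of 1-vs-2 component Gaussian mixture selection on log10 intensities.

    ``means``/``sds`` are in log10 units, components ordered by mean;
    ``scores`` maps k → BIC (lower is better).
    """

    k: int
    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    scores: dict[int, float]
    converged: bool

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-6:
            raise ValidationError("mixture weights must sum to 1")
        if any(s <= 0 for s in self.sds):
            raise ValidationError("mixture sds must be > 0")
        if list(self.means) != sorted(self.means):
            raise ValidationError("components must be ordered by mean")


@dataclass(frozen=True)
class IronIndex:
    """Fold-quench of PG-SK fluorescence and the implied chelatable iron."""

    fold_quench: float
    iron_uM: float | None = None

    def to_dict(self) -> dict:
        return {"fold_quench": self.fold_quench, "iron_uM": self.iron_uM}


@dataclass(frozen=True)
class CountCalibration:
    """OD₅₆₅ → concentration proportionality.

    ``mode`` is ``"FCM"`` (event-based counting, includes viable but
    non-culturable cells) or ``"CFU"`` (plate counts). Packaged constants
    carry ``n_points = 0`` with a provenance note instead of a fit.
    """

    mode: str
    slope: float
    r2: float
    n_points: int
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValidationError("calibration slope must be > 0")
        if not 0.0 <= self.r2 <= 1.0:
            raise ValidationError("r2 must be in [0,1]")
        if self.n_points != 0 and self.n_points < 3:
            raise ValidationError("fitted calibrations need >= 3 points")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "slope": self.slope,
            "r2": self.r2,
            "n_points": self.n_points,
            "provenance": self.provenance,
        }


def summarize_fluorescence(events: EventTable, channel: str) -> FluorescenceSummary:
    """MFI and CV of one channel on the linear scale.

    The CV uses the sample standard deviation (n−1 denominator).
    """
    if channel not in events.channel_map:
        raise ChannelError(f"channel {channel!r} absent")
    if events.n_events < 1:
        raise SampleSizeError("fluorescence summary needs at least one event")
    x = events.channel(channel)
    mfi = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    cv = sd / mfi if mfi > 0 else 0.0
    return FluorescenceSummary(channel=channel, mfi=mfi, cv=cv, n_events=events.n_events)


def fit_subpopulations(
    events: EventTable, channel: str = "FL1_A", k_max: int = 2, seed: int = 0
) -> MixtureFit:
    """Detect 1 vs 2 fluorescence subpopulations on the log scale.

    Fits Gaussian mixtures with 1..k_max components to the log-displayed
    intensities by EM (10 random restarts each, tolerance 1e-6), selects
    k by BIC, and returns the components ordered by mean. Needs ≥200
    events for the mixture to be identifiable in practice.
    """
    from sklearn.mixture import GaussianMixture

    if channel not in events.channel_map:
        raise ChannelError(f"channel {channel!r} absent")
    if events.n_events < 200:
        raise SampleSizeError(
            f"subpopulation fit needs >=200 events, got {events.n_events}"
        )
    x = log_display(events.channel(channel)).reshape(-1, 1)

    best = None
    scores: dict[int, float] = {}
    any_converged = False
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="diag",
            n_init=10,
            tol=1e-6,
            max_iter=500,
            random_state=seed,
        ).fit(x)
        scores[k] = float(gm.bic(x))
        any_converged = any_converged or bool(gm.converged_)
        if best is None or scores[k] < scores[best[0]]:
            best = (k, gm)
    if not any_converged:
        raise FitError(f"EM failed to converge for all k<= {k_max}: scores={scores}")

    k, gm = best
    order = np.argsort(gm.means_.ravel())
    return MixtureFit(
        k=k,
        weights=tuple(float(w) for w in gm.weights_.ravel()[order]),
        means=tuple(float(m) for m in gm.means_.ravel()[order]),
        sds=tuple(float(np.sqrt(v)) for v in gm.covariances_.ravel()[order]),
        scores=scores,
        converged=bool(gm.converged_),
    )


def iron_index(
    sample: FluorescenceSummary,
    reference: FluorescenceSummary,
    model: QuenchModel | None = None,
) -> IronIndex:
    """Relative chelatable-iron readout from PG-SK quenching.

    ``fold_quench = reference.mfi / sample.mfi`` — the reference is the
    iron-free (unquenched) condition, so fold-quench grows monotonically
    with intracellular iron. With a Stern–Volmer model the estimate is
    ``iron = (fold_quench − 1) / K_sv``.
    """
    if sample.mfi <= 0:
        raise ValidationError("sample MFI must be > 0 to compute a fold-quench")
    if reference.mfi <= 0:
        raise ValidationError("reference MFI must be > 0")
    fold = reference.mfi / sample.mfi
    iron = None
    if model is not None and model.K_sv > 0:
        iron = (fold - 1.0) / model.K_sv
    return IronIndex(fold_quench=fold, iron_uM=iron)


def fit_count_calibration(pairs, mode: str = "FCM") -> CountCalibration:
    """Fit the proportional calibration ``concentration = slope · OD₅₆₅``.

    Least squares through the origin; R² is ``1 − SS_res/SS_tot`` with
    SS_tot about the mean concentration. Requires ≥3 pairs with ≥2
    distinct OD values, all positive.
    """
    pairs = [(float(a), float(b)) for a, b in pairs]
    if len(pairs) < 3:
        raise FitError(f"calibration needs >=3 pairs, got {len(pairs)}")
    od = np.array([p[0] for p in pairs])
    conc = np.array([p[1] for p in pairs])
    if (od <= 0).any() or (conc <= 0).any():
        raise ValidationError("calibration pairs must be positive")
    if len(np.unique(od)) < 2:
        raise FitError("degenerate design: need >=2 distinct OD values")
    slope = float(np.dot(od, conc) / np.dot(od, od))
    ss_res = float(np.sum((conc - slope * od) ** 2))
    ss_tot = float(np.sum((conc - conc.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    r2 = min(max(r2, 0.0), 1.0)
    return CountCalibration(mode=mode, slope=slope, r2=r2, n_points=len(pairs))


def od_to_concentration(od: float, cal: CountCalibration) -> float:
    """Convert an OD₅₆₅ reading to cells·mL⁻¹ (or CFU·mL⁻¹, per ``cal.mode``)."""
    if od < 0:
        raise ValidationError("OD must be >= 0")
    return cal.slope * od


def events_to_concentration(meta: AcquisitionMeta) -> float:
    """Volumetric event concentration from acquisition metadata.

    ``n_events · dilution_factor / analysed volume``, where the analysed
    volume is ``flow_rate (µL·min⁻¹) · duration (s) / 60``, converted to
    mL. Refuses sentinel or assumed metadata.
    """
    meta.require("flow_rate", "duration", "dilution_factor")
    volume_ml = meta.flow_rate * meta.duration / 60.0 / 1000.0
    if volume_ml <= 0:
        raise ParameterError("analysed volume must be > 0")
    return meta.n_events * meta.dilution_factor / volume_ml
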