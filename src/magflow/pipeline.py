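"""Per-sample orchestration and multi-condition comparison.

:func:`run_sample` composes the whole battery for one culture condition:
noise gating, quadrant thresholds from a dye-negative control, viability
classification, fluorescence summaries (Pyr-546 for PHA, PG-SK for iron),
scatter morphology, OD-calibrated cell concentration and the C_mag
statistic — all into one serialisable :class:`ConditionReport`.

Because BOX, Pyr-546 and PG-SK are all read on the green FL1 detector, a
single stained sample cannot carry the viability, PHA and iron signals at
once; a condition is therefore measured as up to three separately stained
aliquots, and the configuration may name separate event files for the PHA
(``pha_events``) and iron (``iron_events``) stains alongside the BOX/PI
co-stained main file.

Configuration is a plain mapping (or a YAML file path) with keys::

    condition_id        name of the condition
    control_events      path to the unstained control (threshold source)
    threshold_percentile  default 99.5
    noise_gate          optional {mode: syto62|scatter, cut: <linear units>}
    pha_events          optional path (Pyr-546 stained aliquot)
    iron_events         optional path (PG-SK stained aliquot)
    pgsk_reference_mfi  optional MFI of the iron-free reference condition
    quench              optional {f0: ..., K_sv: ...} Stern-Volmer model
    calibration         packaged name (fcm_unstained|fcm_syto62|cfu)
    od565               optional scalar OD of the condition
    format              event-file format, fcs or csv (default csv)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from statistics import mean, stdev

import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .cmag import compute_cmag, read_od_pairs
from .errors import ConfigurationError, ValidationError
from .events_io import read_events
from .gating import (
    ViabilityFractions,
    classify_viability,
    estimate_thresholds,
    noise_gate,
    scatter_summary,
)
from .quantify import (
    FluorescenceSummary,
    iron_index,
    od_to_concentration,
    summarize_fluorescence,
)
from .registry import packaged_calibration
from .synthetic import QuenchModel

REPORT_SCHEMA_VERSION = 1

#: Metrics emitted per condition by :func:`compare_conditions`.
_COMPARE_METRICS = (
    "od565",
    "cmag",
    "healthy",
    "injured",
    "dead",
    "anomalous",
    "pyr546_mfi",
    "pgsk_mfi",
    "iron_fold_quench",
    "fsc_mean",
    "ssc_mean",
)


@dataclass
class ConditionReport:
    """All physiology readouts of one culture condition, with provenance."""

    condition_id: str
    schema_version: int = REPORT_SCHEMA_VERSION
    od565: float | None = None
    concentration: float | None = None
    calibration: dict | None = None
    cmag: float | None = None
    cmag_sd: float | None = None
    viability: dict | None = None
    pha: dict | None = None
    iron: dict | None = None
    iron_idx: dict | None = None
    scatter: dict | None = None
    thresholds: dict | None = None
    warnings: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "condition_id": self.condition_id,
            "schema_version": self.schema_version,
            "od565": self.od565,
            "concentration": self.concentration,
            "calibration": self.calibration,
            "cmag": self.cmag,
            "cmag_sd": self.cmag_sd,
            "viability": self.viability,
            "pha": self.pha,
            "iron": self.iron,
            "iron_index": self.iron_idx,
            "scatter": self.scatter,
            "thresholds": self.thresholds,
            "warnings": self.warnings,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        """Canonical serialisation: sorted keys, so identical runs are byte-identical."""
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return dict(config)
    with open(config, "r", encoding="utf-8") as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise ConfigurationError(f"config file {config} did not parse to a mapping")
    return loaded


def _stage(name: str):
    """Annotate module errors with the pipeline stage they occurred in."""
    import contextlib

    @contextlib.contextmanager
    def ctx():
        try:
            yield
        except Exception as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    return ctx()


def run_sample(events_path: str, od_pairs_path: str | None, config) -> ConditionReport:
    """Run the full analysis battery on one condition.

    ``events_path`` is the BOX/PI co-stained sample; ``od_pairs_path`` an
    optional CSV of paired parallel/perpendicular OD₅₆₅ readings. The run
    is fully deterministic given inputs and configuration.
    """
    cfg = _load_config(config)
    if "control_events" not in cfg:
        raise ConfigurationError("config must name control_events for threshold placement")
    fmt = cfg.get("format", "csv")
    condition_id = cfg.get("condition_id", "unnamed")

    report = ConditionReport(condition_id=condition_id)
    report.provenance = {
        "events": str(events_path),
        "od_pairs": str(od_pairs_path) if od_pairs_path else None,
        "control_events": str(cfg["control_events"]),
        "pha_events": str(cfg["pha_events"]) if cfg.get("pha_events") else None,
        "iron_events": str(cfg["iron_events"]) if cfg.get("iron_events") else None,
        "threshold_percentile": cfg.get("threshold_percentile", 99.5),
        "noise_gate": cfg.get("noise_gate"),
        "calibration": cfg.get("calibration"),
        "magflow_version": _pkg_version,
    }

    with _stage("read_events"):
        events = read_events(str(events_path), format=fmt)
        control = read_events(str(cfg["control_events"]), format=fmt)

    gate_cfg = cfg.get("noise_gate")
    if gate_cfg:
        with _stage("noise_gate"):
            events = noise_gate(events, mode=gate_cfg["mode"], cut=float(gate_cfg["cut"]))
            report.provenance["retained_fraction"] = events.meta.retained_fraction

    with _stage("estimate_thresholds"):
        thr = estimate_thresholds(
            control,
            percentile=float(cfg.get("threshold_percentile", 99.5)),
            control_id=str(cfg["control_events"]),
        )
        report.thresholds = thr.to_dict()

    with _stage("classify_viability"):
        _, fractions = classify_viability(events, thr)
        report.viability = fractions.to_dict()
        if fractions.warning:
            report.warnings.append(fractions.warning)

    if events.n_events > 0:
        with _stage("scatter_summary"):
            report.scatter = scatter_summary(events).to_dict()
    else:
        report.warnings.append("no events for scatter summary")

    pha_summary = _optional_fl1_summary(cfg.get("pha_events"), fmt, "pha", report)
    if pha_summary is not None:
        report.pha = pha_summary.to_dict()

    iron_summary = _optional_fl1_summary(cfg.get("iron_events"), fmt, "iron", report)
    if iron_summary is not None:
        report.iron = iron_summary.to_dict()
        ref_mfi = cfg.get("pgsk_reference_mfi")
        if ref_mfi is not None:
            with _stage("iron_index"):
                reference = FluorescenceSummary(
                    channel="FL1_A", mfi=float(ref_mfi), cv=0.0, n_events=1
                )
                model = None
                if cfg.get("quench"):
                    q = cfg["quench"]
                    model = QuenchModel(f0=float(q["f0"]), K_sv=float(q["K_sv"]))
                report.iron_idx = iron_index(iron_summary, reference, model).to_dict()

    od = cfg.get("od565")
    if od is not None:
        report.od565 = float(od)
        if cfg.get("calibration"):
            with _stage("od_to_concentration"):
                cal = packaged_calibration(cfg["calibration"])
                report.concentration = od_to_concentration(float(od), cal)
                report.calibration = cal.to_dict()

    if od_pairs_path:
        with _stage("cmag"):
            readings = read_od_pairs(str(od_pairs_path))
            values = [compute_cmag(r) for r in readings]
            report.cmag = mean(values)
            report.cmag_sd = stdev(values) if len(values) > 1 else 0.0

    return report


def _optional_fl1_summary(path, fmt, stage, report) -> FluorescenceSummary | None:
    if not path:
        return None
    with _stage(f"summarize_{stage}"):
        table = read_events(str(path), format=fmt)
        if table.n_events == 0:
            report.warnings.append(f"no events in {stage} sample")
            return None
        return summarize_fluorescence(table, "FL1_A")


def run_synthetic_condition(
    cond: dict,
    workdir: str,
    control_events: str,
    format: str = "csv",
    calibration: str | None = "fcm_unstained",
    pgsk_reference_mfi: float | None = None,
    n_od_pairs: int = 3,
    od_seed: int = 0,
) -> ConditionReport:
    """Materialise one synthetic condition to files and run the battery on it.

    ``cond`` is a condition dict from
    :func:`magflow.registry.headspace_conditions` or
    :func:`magflow.registry.medium_shift_conditions`; ``control_events``
    is a path to an already-written unstained control. Event tables and
    paired OD readings are written under ``workdir`` so the run exercises
    the same I/O path as instrument data.
    """
    import os

    from .cmag import write_od_pairs
    from .events_io import write_events
    from .synthetic import generate_od_pairs, generate_scenario

    cid = cond["condition_id"]
    ext = format
    paths = {}
    for key, scenario in (
        ("events", cond["viability_scenario"]),
        ("pha_events", cond["pha_scenario"]),
        ("iron_events", cond["iron_scenario"]),
    ):
        path = os.path.join(workdir, f"{cid}_{key}.{ext}")
        write_events(generate_scenario(scenario), path, format=format)
        paths[key] = path
    od_path = os.path.join(workdir, f"{cid}_od_pairs.csv")
    write_od_pairs(generate_od_pairs(cond["cmag_generator"], n_od_pairs, od_seed), od_path)

    cfg = {
        "condition_id": cid,
        "control_events": control_events,
        "pha_events": paths["pha_events"],
        "iron_events": paths["iron_events"],
        "od565": cond["od565"],
        "format": format,
    }
    if calibration:
        cfg["calibration"] = calibration
    if pgsk_reference_mfi is not None:
        cfg["pgsk_reference_mfi"] = pgsk_reference_mfi
    return run_sample(paths["events"], od_path, cfg)


def compare_conditions(reports: list[ConditionReport]) -> pd.DataFrame:
    """Long-format comparison table across conditions.

    Columns ``(condition, metric, value, dispersion)``; conditions keep
    their input order, metrics cover OD₅₆₅, C_mag, the four viability
    fractions, Pyr-546 and PG-SK MFI, the iron fold-quench and the scatter
    means. Metrics absent from a report are emitted as NA so the table
    shape is stable.
    """
    if len(reports) < 2:
        raise ValidationError("comparison needs at least two condition reports")
    ids = [r.condition_id for r in reports]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate condition ids: {ids}")

    rows = []
    for r in reports:
        values: dict[str, tuple] = {
            "od565": (r.od565, None),
            "cmag": (r.cmag, r.cmag_sd),
            "iron_fold_quench": (
                r.iron_idx.get("fold_quench") if r.iron_idx else None, None
            ),
        }
        for q in ("healthy", "injured", "dead", "anomalous"):
            values[q] = (r.viability.get(q) if r.viability else None, None)
        values["pyr546_mfi"] = (
            r.pha.get("mfi") if r.pha else None,
            r.pha.get("cv") if r.pha else None,
        )
        values["pgsk_mfi"] = (
            r.iron.get("mfi") if r.iron else None,
            r.iron.get("cv") if r.iron else None,
        )
        values["fsc_mean"] = (
            r.scatter.get("fsc_mean") if r.scatter else None,
            r.scatter.get("fsc_cv") if r.scatter else None,
        )
        values["ssc_mean"] = (
            r.scatter.get("ssc_mean") if r.scatter else None,
            r.scatter.get("ssc_cv") if r.scatter else None,
        )
        for metric in _COMPARE_METRICS:
            v, disp = values[metric]
            rows.append(
                {
                    "condition": r.condition_id,
                    "metric": metric,
                    "value": v,
                    "dispersion": disp,
                }
            )
    return pd.DataFrame(rows, columns=["condition", "metric", "value", "dispersion"])
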