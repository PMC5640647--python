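"""Packaged scenarios, calibration constants and multi-condition series.

The scenario registry ships human-editable YAML files describing the
synthetic-cytometer fixtures used throughout the package: viability
panels (growing/starving × magnetic/non-magnetic, an ethanol-killed
positive control, an unstained control), the liquid-vs-plate morphology
pair, the one- and two-population PHA staining fixtures, and a
cells-plus-debris mixture for the Syto62 noise gate.

Two experiment series are built programmatically on top of the registry:

* :func:`headspace_conditions` — sealed-tube cultures at 20/40/60/80 %
  headspace volume (an O₂-availability gradient). Less O₂ means stronger
  magnetosome formation (higher C_mag), more PHA (higher Pyr-546 MFI) and
  better viability; more O₂ means more biomass but more intracellular
  iron (lower PG-SK fluorescence, minimal at 80 %).
* :func:`medium_shift_conditions` — an O₂-limited bioreactor culture
  shifted to aerobic flasks with (FSM) or without (FSM-Fe−) iron. In FSM
  the cells grow, burn their PHA (>3-fold Pyr-546 drop by 24 h) and
  slowly lose magnetism; without iron growth stalls, PHA drops only to
  ~65 % of the pre-shift value and C_mag decays to ~1.2 by 48 h.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import replace

import yaml

from .errors import ConfigurationError
from .quantify import CountCalibration
from .synthetic import (
    CmagGenerator,
    KineticsParams,
    PopulationSpec,
    ScenarioSpec,
    StainSpec,
)

__all__ = [
    "available_scenarios",
    "load_scenario",
    "scenario_from_dict",
    "available_calibrations",
    "packaged_calibration",
    "headspace_conditions",
    "medium_shift_conditions",
]


def _data_dir():
    return resources.files("magflow") / "data"


def available_scenarios() -> list[str]:
    """Names of the packaged scenario files."""
    return sorted(
        p.name[: -len(".yaml")]
        for p in (_data_dir() / "scenarios").iterdir()
        if p.name.endswith(".yaml")
    )


def scenario_from_dict(d: dict) -> ScenarioSpec:
    """Build a :class:`ScenarioSpec` from a parsed scenario config mapping."""
    try:
        populations = tuple(
            PopulationSpec(
                label=p["label"],
                fraction=float(p["fraction"]),
                mu={k: float(v) for k, v in p["mu"].items()},
                sigma={k: float(v) for k, v in p["sigma"].items()},
            )
            for p in d["populations"]
        )
        stain = StainSpec(**d.get("stain", {}))
        kinetics = KineticsParams(**d["kinetics"]) if "kinetics" in d else None
        return ScenarioSpec(
            scenario_id=d["scenario_id"],
            populations=populations,
            stain=stain,
            n_events=int(d.get("n_events", 25_000)),
            seed=int(d.get("seed", 0)),
            kinetics=kinetics,
            iron_uM=float(d.get("iron_uM", 0.0)),
            description=d.get("description", ""),
        )
    except KeyError as exc:
        raise ConfigurationError(f"scenario config missing key {exc}") from exc


def load_scenario(
    name: str, n_events: int | None = None, seed: int | None = None
) -> ScenarioSpec:
    """Load a packaged scenario, optionally overriding event count and seed."""
    path = _data_dir() / "scenarios" / f"{name}.yaml"
    try:
        text = path.read_text(encoding="utf-8")
    except FileNotFoundError:
        raise ConfigurationError(
            f"unknown scenario {name!r}; available: {available_scenarios()}"
        ) from None
    spec = scenario_from_dict(yaml.safe_load(text))
    if n_events is not None:
        spec = replace(spec, n_events=n_events)
    if seed is not None:
        spec = replace(spec, seed=seed)
    return spec


def available_calibrations() -> list[str]:
    return sorted(_load_calibrations())


def _load_calibrations() -> dict:
    text = (_data_dir() / "calibrations.yaml").read_text(encoding="utf-8")
    return yaml.safe_load(text)


def packaged_calibration(name: str) -> CountCalibration:
    """One of the shipped OD₅₆₅→concentration constants.

    ``fcm_unstained`` (1 OD₅₆₅ = 1.16×10⁹ cells·mL⁻¹), ``fcm_syto62``
    (1.03×10⁹ cells·mL⁻¹) and ``cfu`` (3.3×10⁸ CFU·mL⁻¹).
    """
    cals = _load_calibrations()
    if name not in cals:
        raise ConfigurationError(
            f"unknown calibration {name!r}; available: {sorted(cals)}"
        )
    c = cals[name]
    return CountCalibration(
        mode=c["mode"],
        slope=float(c["slope"]),
        r2=float(c["r2"]),
        n_points=int(c["n_points"]),
        provenance=c.get("provenance", "").strip(),
    )


# ---------------------------------------------------------------------------
# Condition series
# ---------------------------------------------------------------------------

_LIQ_SCATTER = {"FSC_A": 2.3, "SSC_A": 2.0}
_FL_NEG = 1.5
_SIGMA = {"FSC_A": 0.15, "SSC_A": 0.15, "FL1_A": 0.25, "FL3_A": 0.25, "FL4_A": 0.25}


def _viability_scenario(
    condition_id: str, healthy: float, injured: float, dead: float, seed: int,
    n_events: int,
) -> ScenarioSpec:
    anomalous = 1.0 - healthy - injured - dead
    fl = {"healthy": (1.5, 1.5), "injured": (3.5, 1.5), "dead": (3.5, 3.5),
          "anomalous": (1.5, 3.5)}
    fracs = {"healthy": healthy, "injured": injured, "dead": dead, "anomalous": anomalous}
    pops = tuple(
        PopulationSpec(
            label=label,
            fraction=fracs[label],
            mu={**_LIQ_SCATTER, "FL1_A": fl[label][0], "FL3_A": fl[label][1], "FL4_A": _FL_NEG},
            sigma=dict(_SIGMA),
        )
        for label in ("healthy", "injured", "dead", "anomalous")
    )
    return ScenarioSpec(
        scenario_id=f"{condition_id}_viability",
        populations=pops,
        stain=StainSpec(dye="BOX", concentration=10.0, staining_time=600.0),
        n_events=n_events,
        seed=seed,
    )


def _single_stain_scenario(
    condition_id: str, dye: str, fl1_mu: float, seed: int, n_events: int
) -> ScenarioSpec:
    pop = PopulationSpec(
        label="stained",
        fraction=1.0,
        mu={**_LIQ_SCATTER, "FL1_A": fl1_mu, "FL3_A": _FL_NEG, "FL4_A": _FL_NEG},
        sigma=dict(_SIGMA),
    )
    stain = (
        StainSpec(dye="PYR546", concentration=0.5, staining_time=300.0)
        if dye == "PYR546"
        else StainSpec(dye="PGSK", concentration=5.0, unit="uM", staining_time=600.0)
    )
    return ScenarioSpec(
        scenario_id=f"{condition_id}_{dye.lower()}",
        populations=(pop,),
        stain=stain,
        n_events=n_events,
        seed=seed,
    )


def _condition(
    condition_id: str, od: float, cmag: float, viability: tuple[float, float, float],
    pyr_mu: float, pgsk_mu: float, seed: int, n_events: int, noise_cv: float,
) -> dict:
    h, i, d = viability
    return {
        "condition_id": condition_id,
        "od565": od,
        "cmag_generator": CmagGenerator(
            od_base=od,
            magnetic_fraction=cmag - 1.0,
            alignment_contrast=1.0,
            noise_cv=noise_cv,
        ),
        "viability_scenario": _viability_scenario(condition_id, h, i, d, seed, n_events),
        "pha_scenario": _single_stain_scenario(condition_id, "PYR546", pyr_mu, seed + 1, n_events),
        "iron_scenario": _single_stain_scenario(condition_id, "PGSK", pgsk_mu, seed + 2, n_events),
    }


def headspace_conditions(
    n_events: int = 25_000, base_seed: int = 100, noise_cv: float = 0.01
) -> list[dict]:
    """The sealed-tube O₂-limitation series (20/40/60/80 % headspace).

    Each condition dict holds the terminal OD₅₆₅, a C_mag generator and
    three scenario specs (BOX/PI viability, Pyr-546 PHA, PG-SK iron).
    C_mag and PHA fall, and biomass and intracellular iron rise, with
    increasing O₂ availability.
    """
    rows = [
        # id,            od,   cmag, (healthy, injured, dead), pyr_mu, pgsk_mu
        ("headspace_20", 0.45, 2.00, (0.90, 0.06, 0.03), 3.4, 3.10),
        ("headspace_40", 0.90, 1.55, (0.85, 0.09, 0.05), 3.1, 3.20),
        ("headspace_60", 1.30, 1.10, (0.75, 0.15, 0.09), 2.8, 3.30),
        ("headspace_80", 1.60, 1.02, (0.60, 0.22, 0.17), 2.5, 2.60),
    ]
    return [
        _condition(cid, od, cm, viab, pyr, pgsk, base_seed + 10 * i, n_events, noise_cv)
        for i, (cid, od, cm, viab, pyr, pgsk) in enumerate(rows)
    ]


def medium_shift_conditions(
    n_events: int = 25_000, base_seed: int = 500, noise_cv: float = 0.01
) -> list[dict]:
    """The O₂-limited → aerobic medium-shift series.

    ``t0`` is the pre-transfer bioreactor culture; FSM and FSM-Fe−
    conditions follow it 24 h and 48 h after transfer to aerobic flasks
    with and without iron citrate. Pyr-546 MFI in FSM at 24 h is below a
    third of the pre-transfer value (PHA consumed as substrate); without
    iron it only falls to ~65 %.
    """
    rows = [
        ("t0",          1.00, 1.71, (0.88, 0.07, 0.04), 3.50, 3.20),
        ("FSM_24h",     1.50, 1.84, (0.90, 0.06, 0.03), 2.956, 3.00),
        ("FSM_48h",     2.00, 1.46, (0.88, 0.07, 0.04), 2.93, 2.80),
        ("FSM-Fe-_24h", 0.25, 1.50, (0.80, 0.12, 0.07), 3.43, 3.20),
        ("FSM-Fe-_48h", 0.30, 1.20, (0.75, 0.15, 0.09), 3.313, 3.20),
    ]
    return [
        _condition(cid, od, cm, viab, pyr, pgsk, base_seed + 10 * i, n_events, noise_cv)
        for i, (cid, od, cm, viab, pyr, pgsk) in enumerate(rows)
    ]
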