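"""What-if land-cover scenarios and model-based richness change.

Two built-in scenario families:

* urban expansion (A-D): peri-/extra-urban quadrats are fully converted to
  continuous urban fabric plus road networks, in fractions
  A = (100%, 0%), B = (90%, 10%), C = (80%, 20%), D = (70%, 30%);
* urban greening (E-H): in urban quadrats, k = 1..4 hectares are moved from
  continuous urban fabric into green urban areas.

Applying a scenario rewrites land cover (conserving the quadrat area
exactly); a fitted model then predicts the per-quadrat change in expected
richness (or any other fitted response).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .gam import FittedAdditiveModel
from .survey import (
    LANDCOVER_CATEGORIES,
    QuadratRecord,
    Zone,
)

logger = logging.getLogger(__name__)

_IDX = {name: i for i, name in enumerate(LANDCOVER_CATEGORIES)}
_CONT = _IDX["continuous_urban_fabric"]
_ROADS = _IDX["road_networks"]
_GREEN = _IDX["green_urban_areas"]

EXPANSION_FRACTIONS = {
    "A": (1.0, 0.0),
    "B": (0.9, 0.1),
    "C": (0.8, 0.2),
    "D": (0.7, 0.3),
}

GREENING_HECTARES = {"E": 1.0, "F": 2.0, "G": 3.0, "H": 4.0}


@dataclass(frozen=True)
class Scenario:
    """A per-quadrat land-cover rewrite restricted to target zones.

    Exactly one of ``replacement`` (8 fractions summing to 1, applied to the
    whole quadrat area) or ``delta`` (signed hectares per category, summing
    to 0, with donor clipping) is set.
    """

    name: str
    target_zones: frozenset[Zone]
    replacement: tuple[float, ...] | None = None
    delta: tuple[float, ...] | None = None

    def __post_init__(self):
        if (self.replacement is None) == (self.delta is None):
            raise ValueError("give exactly one of replacement or delta")
        if self.replacement is not None:
            frac = np.asarray(self.replacement, dtype=float)
            if frac.shape != (len(LANDCOVER_CATEGORIES),):
                raise ValueError("replacement needs 8 fractions")
            if np.any(frac < 0) or abs(frac.sum() - 1.0) > 1e-9:
                raise ValueError("replacement fractions must be >= 0 and sum to 1")
        if self.delta is not None:
            d = np.asarray(self.delta, dtype=float)
            if d.shape != (len(LANDCOVER_CATEGORIES),):
                raise ValueError("delta needs 8 components")
            if abs(d.sum()) > 1e-9:
                raise ValueError("delta must conserve total area (sum to 0)")


@dataclass(frozen=True)
class ScenarioResult:
    scenario: str
    per_quadrat: tuple[tuple[str, float, float, float], ...]
    # (quadrat_id, baseline_pred, scenario_pred, delta)
    mean_delta: float
    sd_delta: float
    extreme: tuple[str, float]


def make_expansion_scenario(variant: str) -> Scenario:
    """Urban-sprawl scenario A-D on peri- and extra-urban quadrats."""
    try:
        cont, roads = EXPANSION_FRACTIONS[variant.upper()]
    except KeyError:
        raise ValueError(f"expansion variant must be A-D, got {variant!r}")
    frac = [0.0] * len(LANDCOVER_CATEGORIES)
    frac[_CONT] = cont
    frac[_ROADS] = roads
    return Scenario(
        name=f"expansion_{variant.upper()}",
        target_zones=frozenset({Zone.PERI_URBAN, Zone.EXTRA_URBAN}),
        replacement=tuple(frac),
    )


def make_greening_scenario(variant: str) -> Scenario:
    """Urban-greening scenario E-H: +k ha green taken from continuous fabric."""
    try:
        k = GREENING_HECTARES[variant.upper()]
    except KeyError:
        raise ValueError(f"greening variant must be E-H, got {variant!r}")
    d = [0.0] * len(LANDCOVER_CATEGORIES)
    d[_GREEN] = k
    d[_CONT] = -k
    return Scenario(
        name=f"greening_{variant.upper()}",
        target_zones=frozenset({Zone.URBAN}),
        delta=tuple(d),
    )


def _rewrite(record: QuadratRecord, s: Scenario) -> QuadratRecord:
    lc = record.landcover
    if s.replacement is not None:
        new_lc = np.asarray(s.replacement) * record.quadrat_area
    else:
        d = np.asarray(s.delta, dtype=float)
        if not d.any():  # identity rewrite: bit-exact pass-through
            return record
        gains = np.clip(d, 0, None)
        losses = np.clip(-d, 0, None)
        avail = lc.copy()
        # clip each donation to what the donor class actually holds
        short = losses > avail + 1e-12
        if short.any():
            scale = float(
                min(
                    (avail[k] / losses[k]) for k in np.flatnonzero(short)
                )
            )
            warnings.warn(
                f"quadrat {record.quadrat_id}: donor class has only "
                f"{avail[short][0]:.3f} ha; transfer clipped",
                stacklevel=2,
            )
            logger.warning(
                "scenario %s: clipped transfer on quadrat %s (scale %.3f)",
                s.name,
                record.quadrat_id,
                scale,
            )
            gains = gains * scale
            losses = losses * scale
        new_lc = lc + gains - losses
    if np.any(new_lc < -1e-9):
        raise ValueError(
            f"scenario {s.name} drives quadrat {record.quadrat_id} negative"
        )
    new_lc = np.clip(new_lc, 0.0, None)
    if abs(new_lc.sum() - record.quadrat_area) > 1e-6:
        raise ValueError(
            f"scenario {s.name} does not conserve area on quadrat "
            f"{record.quadrat_id}"
        )
    # pin the sum exactly: adjust the largest component by the float residue
    residue = record.quadrat_area - new_lc.sum()
    new_lc[int(np.argmax(new_lc))] += residue
    return QuadratRecord(
        quadrat_id=record.quadrat_id,
        zone=record.zone,
        landcover=new_lc,
        quadrat_area=record.quadrat_area,
    )


def apply_scenario(
    quadrats: Sequence[QuadratRecord], s: Scenario
) -> list[QuadratRecord]:
    """Rewrite target-zone quadrats; non-target quadrats pass through as-is."""
    return [
        _rewrite(q, s) if q.zone in s.target_zones else q for q in quadrats
    ]


def predict_scenario(
    model: FittedAdditiveModel,
    baseline: Sequence[QuadratRecord],
    s: Scenario,
) -> ScenarioResult:
    """Per-quadrat change in the model's expected count under a scenario.

    Only target-zone quadrats are reported.  mean/sd are the arithmetic mean
    and sample (n-1) standard deviation of the deltas; ``extreme`` is the
    largest-magnitude delta.
    """
    rows = []
    for q in baseline:
        if q.zone not in s.target_zones:
            continue
        base_pred = float(model.predict(q.landcover[None, :])[0])
        new_q = _rewrite(q, s)
        scen_pred = float(model.predict(new_q.landcover[None, :])[0])
        rows.append((q.quadrat_id, base_pred, scen_pred, scen_pred - base_pred))
    if not rows:
        return ScenarioResult(s.name, (), float("nan"), float("nan"), ("", 0.0))
    deltas = np.array([r[3] for r in rows])
    i_ext = int(np.argmax(np.abs(deltas)))
    return ScenarioResult(
        scenario=s.name,
        per_quadrat=tuple(rows),
        mean_delta=float(deltas.mean()),
        sd_delta=float(deltas.std(ddof=1)) if len(deltas) > 1 else 0.0,
        extreme=(rows[i_ext][0], float(deltas[i_ext])),
    )


def scenario_from_config(d: dict) -> Scenario:
    """Build a scenario from a configuration mapping.

    Keys: name; zones (list of zone labels); and either ``replacement``
    (mapping category -> fraction) or ``delta`` (mapping category -> signed
    hectares).  Omitted categories default to zero.
    """
    zones = frozenset(Zone(z) for z in d["zones"])

    def vec(mapping):
        v = [0.0] * len(LANDCOVER_CATEGORIES)
        for cat, val in mapping.items():
            if cat not in _IDX:
                raise ValueError(f"unknown land-cover category {cat!r}")
            v[_IDX[cat]] = float(val)
        return tuple(v)

    if "replacement" in d:
        return Scenario(name=d["name"], target_zones=zones,
                        replacement=vec(d["replacement"]))
    if "delta" in d:
        return Scenario(name=d["name"], target_zones=zones,
                        delta=vec(d["delta"]))
    raise ValueError("scenario config needs 'replacement' or 'delta'")


def builtin_scenario(name: str) -> Scenario:
    """Scenario A-H by letter."""
    u = name.upper()
    if u in EXPANSION_FRACTIONS:
        return make_expansion_scenario(u)
    if u in GREENING_HECTARES:
        return make_greening_scenario(u)
    raise ValueError(f"no built-in scenario named {name!r}")
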