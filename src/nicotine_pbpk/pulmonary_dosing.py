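"""Regional respiratory-tract dosing: deposition, absorption, mucociliary transit.

Smoking, e-cigarette and nasal-spray use patterns are converted into
deposition events on anatomically distinct regions of the respiratory tract:

* buccal cavity (BC),
* extra-thoracic airways (ET2: posterior nasal passages, larynx, pharynx,
  mouth),
* thoracic airways (BB: trachea and bronchi),
* bronchiolar airways (bb: down to the terminal bronchioles),
* alveolar-interstitial region (AI: respiratory bronchioles to alveoli),
* a nasal region for sprays,

plus an explicitly tracked exhaled (lost) fraction.  Published coarse
deposition data for inhaled nicotine give ~20% buccal, 25% upper respiratory
tract, 50% lower respiratory tract and 5% exhaled; :func:`map_coarse_to_pcat`
maps that coarse split onto the regional compartments (URT → ET2; LRT split
10/15/75% among BB/bb/AI, alveolar-dominant consistent with the rapid
absorption seen during smoking).

Each region absorbs drug into the systemic circulation with a first-order
rate constant: alveolar/bronchiolar/thoracic mass enters the lung (venous
side) compartment, while ET2/buccal/nasal mass enters venous blood directly.
A slow mucociliary ladder carries mass upward (bb → BB → ET2 → swallowed);
swallowed drug lands in the gut lumen, is absorbed with a single first-order
constant ka = 2·Peff/r (intestinal radius 1.75 cm), and undergoes hepatic
first pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .compound_physiology import CompoundProperties

__all__ = [
    "DepositionFractions",
    "PuffRegimen",
    "RegionalAbsorptionRates",
    "DoseEvent",
    "allocate_deposition",
    "map_coarse_to_pcat",
    "puff_events",
    "per_puff_dose_from_eliquid",
    "respiratory_transfer_rates",
    "nasal_spray_events",
    "smoking_fractions",
    "ecigarette_fractions",
    "default_absorption_rates",
    "gut_absorption_rate_constant",
    "DEPOT_ORDER",
    "LUNG_REGIONS",
    "LRT_SPLIT",
]

#: Ordering of the extravascular depot compartments in the ODE state vector.
DEPOT_ORDER = (
    "buccal",
    "nasal",
    "et2",
    "bb_thoracic",
    "bb_bronchiolar",
    "ai_alveolar",
    "gut_lumen",
)
#: Regions addressable by lung_region_deposit dose events.
LUNG_REGIONS = ("et2", "bb_thoracic", "bb_bronchiolar", "ai_alveolar")
#: Fixed split of the lower-respiratory-tract mass among BB / bb / AI.
LRT_SPLIT = (0.10, 0.15, 0.75)

#: Intestinal radius (cm) used for the single-constant gut absorption model.
INTESTINAL_RADIUS_CM = 1.75


@dataclass(frozen=True)
class DoseEvent:
    """A single dosing event handled by the ODE engine.

    ``route`` is one of iv_bolus, iv_infusion, lung_region_deposit,
    nasal_deposit, buccal_deposit, gut_lumen, or exhaled (an explicit loss
    sink so the mass-balance audit sees every milligram).  ``duration`` is 0
    for instantaneous events; iv_infusion delivers ``amount`` at a constant
    rate over [start, start + duration].
    """

    route: str
    amount: float  # mg
    start: float = 0.0  # h
    duration: float = 0.0  # h
    target_region: str | None = None

    ROUTES = (
        "iv_bolus",
        "iv_infusion",
        "lung_region_deposit",
        "nasal_deposit",
        "buccal_deposit",
        "gut_lumen",
        "exhaled",
    )

    def __post_init__(self) -> None:
        if self.route not in self.ROUTES:
            raise ValueError(f"unknown route {self.route!r}")
        if self.amount < 0:
            raise ValueError("amount must be >= 0")
        if self.start < 0 or self.duration < 0:
            raise ValueError("start and duration must be >= 0")
        if self.route == "lung_region_deposit":
            if self.target_region not in LUNG_REGIONS:
                raise ValueError(
                    f"lung_region_deposit requires target_region in {LUNG_REGIONS}"
                )
        if self.route == "iv_infusion" and self.duration <= 0:
            raise ValueError("iv_infusion requires duration > 0")


@dataclass(frozen=True)
class DepositionFractions:
    """Fraction of an inhaled dose landing in each region (sums to 1)."""

    buccal: float
    et2: float
    bb_thoracic: float
    bb_bronchiolar: float
    ai_alveolar: float
    exhaled: float

    def __post_init__(self) -> None:
        vals = self.as_dict()
        for name, v in vals.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"fraction {name} must lie in [0, 1]")
        if abs(sum(vals.values()) - 1.0) > 1e-9:
            raise ValueError("deposition fractions must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "buccal": self.buccal,
            "et2": self.et2,
            "bb_thoracic": self.bb_thoracic,
            "bb_bronchiolar": self.bb_bronchiolar,
            "ai_alveolar": self.ai_alveolar,
            "exhaled": self.exhaled,
        }


@dataclass(frozen=True)
class PuffRegimen:
    """Puffing topography for smoking or e-cigarette use."""

    puffs_per_session: int
    puff_interval: float  # seconds
    dose_per_puff: float  # mg
    sessions: int = 1
    session_gap: float = 1.0  # hours between session starts
    eliquid_concentration: float | None = None  # mg/mL, e-cigarette metadata

    def __post_init__(self) -> None:
        if self.puffs_per_session < 1 or self.sessions < 1:
            raise ValueError("puff and session counts must be >= 1")
        if self.puff_interval <= 0:
            raise ValueError("puff_interval must be > 0")
        if self.dose_per_puff < 0:
            raise ValueError("dose_per_puff must be >= 0")

    @property
    def total_dose(self) -> float:
        return self.puffs_per_session * self.sessions * self.dose_per_puff


def _halflife_to_rate(t_half_min: float) -> float:
    """First-order rate constant (1/h) from a half-life in minutes."""
    return math.log(2.0) / (t_half_min / 60.0)


@dataclass(frozen=True)
class RegionalAbsorptionRates:
    """First-order absorption and mucociliary-transit constants (1/h).

    Defaults correspond to absorption half-lives of 0.5 min (AI), 5 min
    (bb and BB), 15 min (ET2), 20 min (buccal) and 10 min (nasal), with slow
    mucociliary transfers (0.1/h) up the airway ladder, and a gut absorption
    constant derived from the compound's effective permeability.  The fast
    alveolar constant puts the smoking plasma peak at the end of the puffing
    period; all constants are exposed in scenario configs.
    """

    buccal: float = field(default_factory=lambda: _halflife_to_rate(20.0))
    nasal: float = field(default_factory=lambda: _halflife_to_rate(10.0))
    et2: float = field(default_factory=lambda: _halflife_to_rate(15.0))
    bb_thoracic: float = field(default_factory=lambda: _halflife_to_rate(5.0))
    bb_bronchiolar: float = field(default_factory=lambda: _halflife_to_rate(5.0))
    ai_alveolar: float = field(default_factory=lambda: _halflife_to_rate(0.5))
    gut_lumen: float = 1.76  # overridden from Peff via default_absorption_rates
    mc_bb_to_thoracic: float = 0.1
    mc_thoracic_to_et2: float = 0.1
    mc_et2_to_swallowed: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "buccal",
            "nasal",
            "et2",
            "bb_thoracic",
            "bb_bronchiolar",
            "ai_alveolar",
            "gut_lumen",
            "mc_bb_to_thoracic",
            "mc_thoracic_to_et2",
            "mc_et2_to_swallowed",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be >= 0")

    def absorption_rate(self, region: str) -> float:
        return getattr(self, region)


def gut_absorption_rate_constant(compound: CompoundProperties) -> float:
    """ka = 2·Peff / r for a cylindrical intestine, converted to 1/h."""
    peff_cm_h = compound.effective_permeability * 3600.0
    return 2.0 * peff_cm_h / INTESTINAL_RADIUS_CM


def default_absorption_rates(
    compound: CompoundProperties | None = None,
) -> RegionalAbsorptionRates:
    """Default regional kinetics; the gut constant is derived from Peff."""
    if compound is None:
        return RegionalAbsorptionRates()
    return RegionalAbsorptionRates(gut_lumen=gut_absorption_rate_constant(compound))


def map_coarse_to_pcat(
    buccal_pct: float,
    urt_pct: float,
    lrt_pct: float,
    exhaled_pct: float,
    lrt_split: tuple[float, float, float] = LRT_SPLIT,
) -> DepositionFractions:
    """Map a coarse buccal/URT/LRT/exhaled percentage split onto regions.

    URT maps to ET2; LRT splits among BB/bb/AI with the fixed ``lrt_split``
    ratio; buccal and exhaled pass through.  The four percentages must sum
    to 100.
    """
    total = buccal_pct + urt_pct + lrt_pct + exhaled_pct
    if abs(total - 100.0) > 1e-9:
        raise ValueError(f"coarse percentages must sum to 100 (got {total})")
    if abs(sum(lrt_split) - 1.0) > 1e-9:
        raise ValueError("lrt_split must sum to 1")
    bb, bbr, ai = lrt_split
    return DepositionFractions(
        buccal=buccal_pct / 100.0,
        et2=urt_pct / 100.0,
        bb_thoracic=lrt_pct / 100.0 * bb,
        bb_bronchiolar=lrt_pct / 100.0 * bbr,
        ai_alveolar=lrt_pct / 100.0 * ai,
        exhaled=exhaled_pct / 100.0,
    )


def smoking_fractions() -> DepositionFractions:
    """The coarse 20/25/50/5 smoking split mapped onto the regional model."""
    return map_coarse_to_pcat(20.0, 25.0, 50.0, 5.0)


def ecigarette_fractions() -> DepositionFractions:
    """E-cigarette deposition: no exhalation loss (complete absorption).

    The smoking split is renormalized over the retained 95% so the regional
    proportions are preserved while the whole delivered dose is absorbed.
    """
    base = smoking_fractions()
    keep = 1.0 - base.exhaled
    return DepositionFractions(
        buccal=base.buccal / keep,
        et2=base.et2 / keep,
        bb_thoracic=base.bb_thoracic / keep,
        bb_bronchiolar=base.bb_bronchiolar / keep,
        ai_alveolar=base.ai_alveolar / keep,
        exhaled=0.0,
    )


def allocate_deposition(
    dose: float, fractions: DepositionFractions
) -> dict[str, float]:
    """Per-region deposited amounts (mg); the exhaled share is recorded lost."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    return {name: dose * frac for name, frac in fractions.as_dict().items()}


def _deposition_events(
    dose: float, fractions: DepositionFractions, start: float
) -> list[DoseEvent]:
    amounts = allocate_deposition(dose, fractions)
    events: list[DoseEvent] = []
    if amounts["buccal"] > 0:
        events.append(DoseEvent("buccal_deposit", amounts["buccal"], start))
    for region in LUNG_REGIONS:
        if amounts[region] > 0:
            events.append(
                DoseEvent("lung_region_deposit", amounts[region], start,
                          target_region=region)
            )
    if amounts["exhaled"] > 0:
        events.append(DoseEvent("exhaled", amounts["exhaled"], start))
    return events


def puff_events(
    regimen: PuffRegimen,
    fractions: DepositionFractions,
    start: float = 0.0,
) -> list[DoseEvent]:
    """One deposition event set per puff.

    Puff k of session j fires at start + j·session_gap + k·puff_interval.
    The total scheduled amount equals puffs × sessions × dose_per_puff
    (including any exhaled share, which is emitted as explicit loss events).
    """
    events: list[DoseEvent] = []
    interval_h = regimen.puff_interval / 3600.0
    for session in range(regimen.sessions):
        session_start = start + session * regimen.session_gap
        for k in range(regimen.puffs_per_session):
            t = session_start + k * interval_h
            events.extend(_deposition_events(regimen.dose_per_puff, fractions, t))
    return events


def per_puff_dose_from_eliquid(
    concentration: float, puff_liquid_volume: float
) -> float:
    """Nicotine per puff (mg) = e-liquid concentration × aerosolized volume."""
    if concentration <= 0 or puff_liquid_volume < 0:
        raise ValueError("concentration must be > 0 and volume >= 0")
    return concentration * puff_liquid_volume


def nasal_spray_events(dose: float, start: float = 0.0) -> list[DoseEvent]:
    """Nasal spray: 95% deposits in the nasal region, 5% is exhaled/lost."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if dose == 0:
        return []
    return [
        DoseEvent("nasal_deposit", 0.95 * dose, start),
        DoseEvent("exhaled", 0.05 * dose, start),
    ]


def depot_rate_matrix(
    rates: RegionalAbsorptionRates,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Linear depot kinetics as matrices over :data:`DEPOT_ORDER`.

    Returns (M, w_lung, w_venous, w_liver): dA/dt = M·A for the depot block,
    with absorbed mass routed to the lung compartment (w_lung·A), venous
    blood (w_venous·A) or the liver (w_liver·A, the swallowed/gut pathway).
    """
    idx = {name: i for i, name in enumerate(DEPOT_ORDER)}
    n = len(DEPOT_ORDER)
    M = np.zeros((n, n))
    w_lung = np.zeros(n)
    w_venous = np.zeros(n)
    w_liver = np.zeros(n)

    for region, w in (
        ("ai_alveolar", w_lung),
        ("bb_bronchiolar", w_lung),
        ("bb_thoracic", w_lung),
        ("et2", w_venous),
        ("buccal", w_venous),
        ("nasal", w_venous),
        ("gut_lumen", w_liver),
    ):
        ka = rates.absorption_rate(region)
        w[idx[region]] = ka
        M[idx[region], idx[region]] -= ka

    # mucociliary ladder: bb -> BB -> ET2 -> swallowed (gut lumen)
    for src, dst, k in (
        ("bb_bronchiolar", "bb_thoracic", rates.mc_bb_to_thoracic),
        ("bb_thoracic", "et2", rates.mc_thoracic_to_et2),
        ("et2", "gut_lumen", rates.mc_et2_to_swallowed),
    ):
        M[idx[src], idx[src]] -= k
        M[idx[dst], idx[src]] += k
    return M, w_lung, w_venous, w_liver


def respiratory_transfer_rates(
    state: Mapping[str, float], rates: RegionalAbsorptionRates
) -> dict[str, dict[str, float] | float]:
    """Instantaneous depot flows (mg/h) for a regional amount state.

    Returns per-region net rates of change plus the aggregate absorption
    flows into the lung, venous blood and liver (swallowed pathway).  This is
    the same linear system the ODE engine integrates.
    """
    a = np.array([max(float(state.get(name, 0.0)), 0.0) for name in DEPOT_ORDER])
    if any(float(state.get(name, 0.0)) < 0 for name in DEPOT_ORDER):
        raise ValueError("regional amounts must be non-negative")
    M, w_lung, w_venous, w_liver = depot_rate_matrix(rates)
    da = M @ a
    return {
        "region_rates": dict(zip(DEPOT_ORDER, da.tolist())),
        "to_lung": float(w_lung @ a),
        "to_venous": float(w_venous @ a),
        "to_liver": float(w_liver @ a),
    }
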