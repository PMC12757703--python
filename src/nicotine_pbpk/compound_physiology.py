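"""Drug constants and the reference-human physiology.

This module houses three things:

* :class:`CompoundProperties` — nicotine's physicochemical / ADME constants
  (molecular weight, LogD, solubility, plasma protein binding, blood:plasma
  ratio, permeability).
* :class:`PhysiologyModel` — an ordered set of perfused tissue compartments
  (volumes in L, blood flows in L/h) for a 70-kg reference human, scaled
  linearly with body weight, plus the hepatic IVIVE scaling factors
  (liver mass, MPPGL, CYP2A6 abundance).
* :class:`PartitionCoefficients` — the tissue:plasma Kp set.  Individual
  per-tissue values for nicotine are not published, but their ranking is
  (highest in lung, liver, kidney, heart and spleen; low in adipose) and so
  is the aggregate steady-state volume of distribution, 2.70 L/kg.  We ship
  a ranked base template and rescale it by a single scalar so that the
  plasma-referenced Vss hits the target exactly
  (:func:`calibrate_partition_coefficients`).

Units are fixed throughout: volumes L, flows L/h, body weight kg, liver
mass g, MPPGL mg microsomal protein per g liver, CYP2A6 abundance pmol per
mg microsomal protein, concentrations derived downstream in mg/L (≡ µg/mL)
and reported in ng/mL.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import yaml

__all__ = [
    "CompoundProperties",
    "TissueCompartment",
    "PhysiologyModel",
    "PartitionCoefficients",
    "nicotine",
    "build_reference_human",
    "fraction_unbound_blood",
    "plasma_volume",
    "compute_vss",
    "calibrate_partition_coefficients",
    "default_partition_coefficients",
    "TARGET_VSS_L_PER_KG",
    "REFERENCE_BODY_WEIGHT_KG",
    "KP_TEMPLATE",
]

REFERENCE_BODY_WEIGHT_KG = 70.0
#: Reference cardiac output, 6.5 L/min for a resting 70-kg adult.
REFERENCE_CARDIAC_OUTPUT_L_H = 390.0
#: Default hematocrit (exposed for sensitivity analysis).
DEFAULT_HEMATOCRIT = 0.44
#: Target plasma-referenced steady-state volume of distribution for nicotine.
TARGET_VSS_L_PER_KG = 2.70

# 70-kg reference tissue volumes (L) and blood-flow fractions of cardiac
# output.  ICRP-style reference values, simplified to a parallel circulation:
# every tissue receives arterial blood and drains to venous blood; the lung
# sits in series and carries the whole cardiac output.  The liver fraction is
# total hepatic (arterial + portal) flow because the splanchnic organs are
# plumbed in parallel here, not chained through the portal vein.
# name: (volume_L, flow_fraction_of_CO, eliminating)
REFERENCE_TISSUES: dict[str, tuple[float, float, bool]] = {
    "lung": (0.53, 1.00, False),
    "liver": (1.80, 0.25, True),
    "kidney": (0.31, 0.19, True),
    "heart": (0.33, 0.04, False),
    "spleen": (0.18, 0.01, False),
    "adipose": (14.5, 0.05, False),
    "muscle": (29.0, 0.17, False),
    "skin": (3.30, 0.05, False),
    "gut": (1.65, 0.04, False),
    "brain": (1.45, 0.12, False),
    "rest_of_body": (9.00, 0.08, False),
}
REFERENCE_BLOOD_VOLUMES: dict[str, float] = {
    "arterial_blood": 1.8,
    "venous_blood": 3.5,
}
BLOOD_COMPARTMENTS = ("arterial_blood", "venous_blood")

REFERENCE_LIVER_MASS_G = 1800.0
DEFAULT_MPPGL = 40.0  # mg microsomal protein per g liver

#: Ranked Kp base template.  Only the ranking is physiologically constrained
#: (lung/liver/kidney/heart/spleen ≥ muscle > adipose); the absolute scale is
#: set by calibration against the target Vss.
KP_TEMPLATE: dict[str, float] = {
    "lung": 3.0,
    "liver": 3.5,
    "kidney": 3.5,
    "heart": 2.5,
    "spleen": 2.5,
    "brain": 2.0,
    "gut": 2.0,
    "muscle": 1.5,
    "skin": 1.5,
    "rest_of_body": 1.5,
    "adipose": 0.4,
}

_HIGH_KP_TISSUES = ("lung", "liver", "kidney", "heart", "spleen")


@dataclass(frozen=True)
class CompoundProperties:
    """Physicochemical and ADME constants of the simulated compound.

    ``diffusion_coefficient`` and ``particle_density`` are carried as
    metadata only — particle-resolved aerosol deposition is out of scope and
    regional deposition fractions are model inputs.
    """

    molecular_weight: float  # g/mol
    log_d: float  # dimensionless, pH 7.4
    solubility: float  # mg/mL at pH 7.4
    fu_plasma: float  # unbound fraction in plasma, (0, 1]
    blood_plasma_ratio: float  # whole blood : plasma concentration ratio
    effective_permeability: float  # cm/s
    diffusion_coefficient: float  # cm^2/s
    particle_density: float  # g/mL

    def __post_init__(self) -> None:
        for name in (
            "molecular_weight",
            "solubility",
            "fu_plasma",
            "blood_plasma_ratio",
            "effective_permeability",
            "diffusion_coefficient",
            "particle_density",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.fu_plasma > 1:
            raise ValueError("fu_plasma must be <= 1")


def nicotine() -> CompoundProperties:
    """Nicotine's compound constants (MW 162.24, LogD 1.1, fu,p 0.95, B/P 1.2)."""
    return CompoundProperties(
        molecular_weight=162.24,
        log_d=1.1,
        solubility=93.3,
        fu_plasma=0.95,
        blood_plasma_ratio=1.2,
        effective_permeability=4.28e-4,
        diffusion_coefficient=0.0846e-5,
        particle_density=1.2,
    )


@dataclass(frozen=True)
class TissueCompartment:
    name: str
    volume: float  # L
    blood_flow: float  # L/h
    eliminating: bool = False

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"tissue {self.name!r}: volume must be > 0")
        if self.blood_flow < 0:
            raise ValueError(f"tissue {self.name!r}: blood_flow must be >= 0")


@dataclass(frozen=True)
class PhysiologyModel:
    """Whole-body physiology: perfused tissues plus arterial/venous blood.

    Invariants (checked on construction): the non-lung tissue blood flows sum
    to the cardiac output within 0.1%, and the lung carries the full cardiac
    output (series circulation).
    """

    body_weight: float  # kg
    hematocrit: float  # fraction
    cardiac_output: float  # L/h
    tissues: tuple[TissueCompartment, ...]
    liver_mass: float  # g
    mppgl: float = DEFAULT_MPPGL  # mg microsomal protein / g liver
    cyp2a6_abundance: float | None = None  # pmol/mg; None -> calibrated downstream

    def __post_init__(self) -> None:
        if not 0 < self.hematocrit < 1:
            raise ValueError("hematocrit must be in (0, 1)")
        names = [t.name for t in self.tissues]
        if len(set(names)) != len(names):
            raise ValueError("duplicate tissue names")
        required = set(REFERENCE_TISSUES) | set(BLOOD_COMPARTMENTS)
        missing = required - set(names)
        if missing:
            raise ValueError(f"missing tissue compartments: {sorted(missing)}")
        lung = self.tissue("lung")
        if abs(lung.blood_flow - self.cardiac_output) > 1e-9 * self.cardiac_output:
            raise ValueError("lung blood flow must equal cardiac output")
        flow_sum = sum(
            t.blood_flow
            for t in self.tissues
            if t.name != "lung" and t.name not in BLOOD_COMPARTMENTS
        )
        if abs(flow_sum - self.cardiac_output) > 1e-3 * self.cardiac_output:
            raise ValueError(
                "non-lung tissue blood flows must sum to cardiac output "
                f"(got {flow_sum:.4g} vs {self.cardiac_output:.4g})"
            )

    def tissue(self, name: str) -> TissueCompartment:
        for t in self.tissues:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def perfused_tissue_names(self) -> tuple[str, ...]:
        """Non-blood compartments, in declaration order (lung first-class)."""
        return tuple(
            t.name for t in self.tissues if t.name not in BLOOD_COMPARTMENTS
        )

    @property
    def blood_volume(self) -> float:
        return sum(self.tissue(n).volume for n in BLOOD_COMPARTMENTS)

    def to_dict(self) -> dict:
        return {
            "body_weight": self.body_weight,
            "hematocrit": self.hematocrit,
            "cardiac_output": self.cardiac_output,
            "liver_mass": self.liver_mass,
            "mppgl": self.mppgl,
            "cyp2a6_abundance": self.cyp2a6_abundance,
            "tissues": [
                {
                    "name": t.name,
                    "volume": t.volume,
                    "blood_flow": t.blood_flow,
                    "eliminating": t.eliminating,
                }
                for t in self.tissues
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhysiologyModel":
        tissues = tuple(
            TissueCompartment(
                name=t["name"],
                volume=t["volume"],
                blood_flow=t["blood_flow"],
                eliminating=bool(t.get("eliminating", False)),
            )
            for t in d["tissues"]
        )
        return cls(
            body_weight=d["body_weight"],
            hematocrit=d["hematocrit"],
            cardiac_output=d["cardiac_output"],
            tissues=tissues,
            liver_mass=d["liver_mass"],
            mppgl=d.get("mppgl", DEFAULT_MPPGL),
            cyp2a6_abundance=d.get("cyp2a6_abundance"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhysiologyModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class PartitionCoefficients:
    """Tissue-name → Kp (tissue:plasma, dimensionless) mapping.

    Enforces the ranking constraint: each of lung, liver, kidney, heart and
    spleen has Kp ≥ muscle, and muscle Kp > adipose Kp.
    """

    values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = dict(self.values)
        object.__setattr__(self, "values", vals)
        for name, kp in vals.items():
            if kp <= 0:
                raise ValueError(f"Kp for {name!r} must be > 0")
        if "muscle" in vals and "adipose" in vals:
            # uniform (flat) sets are tolerated; an inverted ranking is not
            if vals["muscle"] < vals["adipose"]:
                raise ValueError("ranking violated: muscle Kp must exceed adipose Kp")
            for name in _HIGH_KP_TISSUES:
                if name in vals and vals[name] < vals["muscle"]:
                    raise ValueError(
                        f"ranking violated: {name} Kp must be >= muscle Kp"
                    )

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def scaled(self, s: float) -> "PartitionCoefficients":
        return PartitionCoefficients({k: s * v for k, v in self.values.items()})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dict(self.values), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PartitionCoefficients":
        with open(path) as fh:
            return cls(json.load(fh))


def build_reference_human(body_weight: float = REFERENCE_BODY_WEIGHT_KG) -> PhysiologyModel:
    """Reference-human physiology, scaled linearly from 70 kg.

    All volumes and flows (and liver mass) scale proportionally with body
    weight; body weight must lie in [30, 150] kg.
    """
    if not 30.0 <= body_weight <= 150.0:
        raise ValueError(
            f"body weight {body_weight} kg outside supported range 30-150 kg"
        )
    s = body_weight / REFERENCE_BODY_WEIGHT_KG
    co = s * REFERENCE_CARDIAC_OUTPUT_L_H
    tissues = [
        TissueCompartment(
            name=name,
            volume=s * vol,
            blood_flow=frac * co,
            eliminating=elim,
        )
        for name, (vol, frac, elim) in REFERENCE_TISSUES.items()
    ]
    tissues += [
        TissueCompartment(name=name, volume=s * vol, blood_flow=0.0)
        for name, vol in REFERENCE_BLOOD_VOLUMES.items()
    ]
    return PhysiologyModel(
        body_weight=body_weight,
        hematocrit=DEFAULT_HEMATOCRIT,
        cardiac_output=co,
        tissues=tuple(tissues),
        liver_mass=s * REFERENCE_LIVER_MASS_G,
    )


def fraction_unbound_blood(compound: CompoundProperties) -> float:
    """Unbound fraction referenced to whole blood: fu,B = fu,p / (B:P)."""
    return compound.fu_plasma / compound.blood_plasma_ratio


def plasma_volume(physiology: PhysiologyModel) -> float:
    """Plasma volume in L: total blood volume × (1 − hematocrit)."""
    return physiology.blood_volume * (1.0 - physiology.hematocrit)


def compute_vss(
    physiology: PhysiologyModel,
    kps: PartitionCoefficients,
    compound: CompoundProperties,
) -> float:
    """Plasma-referenced steady-state volume of distribution, L/kg.

    Vss·BW = V_plasma + Σ_i Kp_i·V_i over every non-blood tissue.  The
    blood:plasma ratio enters the flow equations of the ODE core, not this
    static volume term.
    """
    del compound  # B:P deliberately absent from the plasma-referenced formula
    total = plasma_volume(physiology)
    for name in physiology.perfused_tissue_names:
        if name not in kps:
            raise ValueError(f"partition coefficient set is missing tissue {name!r}")
        total += kps[name] * physiology.tissue(name).volume
    return total / physiology.body_weight


def calibrate_partition_coefficients(
    physiology: PhysiologyModel,
    compound: CompoundProperties,
    target_vss: float = TARGET_VSS_L_PER_KG,
    template: Mapping[str, float] | None = None,
) -> PartitionCoefficients:
    """Rescale the ranked Kp template so compute_vss hits ``target_vss``.

    Closed form: s = (target·BW − V_plasma) / Σ_i template_i·V_i.  Uniform
    scaling preserves the ranking invariant; the round trip through
    :func:`compute_vss` is exact to floating-point precision.
    """
    template = dict(KP_TEMPLATE if template is None else template)
    v_pl = plasma_volume(physiology)
    tissue_term = 0.0
    for name in physiology.perfused_tissue_names:
        if name not in template:
            raise ValueError(f"Kp template is missing tissue {name!r}")
        tissue_term += template[name] * physiology.tissue(name).volume
    numerator = target_vss * physiology.body_weight - v_pl
    if numerator <= 0:
        raise ValueError(
            f"target Vss {target_vss} L/kg unachievable: target volume "
            f"{target_vss * physiology.body_weight:.3g} L does not exceed the "
            f"plasma volume {v_pl:.3g} L"
        )
    s = numerator / tissue_term
    kps = PartitionCoefficients({k: s * v for k, v in template.items()})
    achieved = compute_vss(physiology, kps, compound)
    if abs(achieved - target_vss) > 1e-6:
        raise RuntimeError("Kp calibration failed to reach the target Vss")
    return kps


def default_partition_coefficients(
    physiology: PhysiologyModel | None = None,
    compound: CompoundProperties | None = None,
) -> PartitionCoefficients:
    """The shipped calibrated Kp set (Vss = 2.70 L/kg on the reference human)."""
    physiology = physiology or build_reference_human()
    compound = compound or nicotine()
    return calibrate_partition_coefficients(physiology, compound, TARGET_VSS_L_PER_KG)
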