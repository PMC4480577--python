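"""Species physiology and gas partition-coefficient library.

Ships reference parameter sets for mouse, rat, pig and a 70-kg adult male
human, and Ostwald-type partition coefficients for xenon and argon, as
human-readable YAML files under ``gaspbpk/data``.  Fractional perfusion and
volume entries are resolved into absolute flows (L/min) and volumes (L) by
:func:`build_subject`; :func:`scale_subject` adapts the human base model to
other body weights and fat fractions.

The parser is strict: unknown keys, unknown compartments and missing
required fields are errors, so a typo in a user-supplied parameter file
cannot silently change the model.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping

import yaml

from .core import GasExchangeConfig

__all__ = [
    "SpeciesPhysiology",
    "GasSpec",
    "Compartment",
    "SubjectModel",
    "ParameterError",
    "KNOWN_SPECIES",
    "KNOWN_GASES",
    "KNOWN_COMPARTMENTS",
    "COMPARTMENT_LABELS",
    "load_species",
    "load_gas",
    "list_species",
    "list_gases",
    "build_subject",
    "scale_subject",
    "allometric_hook",
    "identity_hook",
]

KNOWN_SPECIES = ("mouse", "rat", "pig", "human")
KNOWN_GASES = ("xenon", "argon")

#: Valid tissue-compartment identifiers.  Species with no richly/poorly
#: fat split use the single ``fat`` compartment.
KNOWN_COMPARTMENTS = (
    "fat",
    "fat_rich",
    "fat_poor",
    "liver",
    "richly_perfused",
    "poorly_perfused",
    "muscle",
    "brain",
)

COMPARTMENT_LABELS = {
    "blood_venous": "Blood (venous)",
    "blood_arterial": "Blood (arterial)",
    "fat": "Fat",
    "fat_rich": "Fat (Richly perfused)",
    "fat_poor": "Fat (Poorly perfused)",
    "liver": "Liver",
    "richly_perfused": "Richly perfused tissue",
    "poorly_perfused": "Poorly perfused tissue",
    "muscle": "Muscle",
    "brain": "Brain",
}

#: Declared tolerance on Σ perfusion fractions.  The human reference column
#: sums to 0.9833 as printed; the residual cardiac output is carried as an
#: arteriovenous bypass rather than renormalised away.
PERFUSION_SUM_TOL = 0.02


class ParameterError(ValueError):
    """Invalid, unknown or inconsistent model parameters."""


@dataclass(frozen=True)
class SpeciesPhysiology:
    """One species column of the physiology table.

    Flows are L/min, body weight kg, all per-compartment entries are
    dimensionless fractions (of cardiac output or of body weight).
    ``tissue_density`` (kg/L) converts weight fractions to litres; it
    defaults to 1.0 for every compartment and may be overridden per
    compartment.
    """

    species_name: str
    body_weight: float
    minute_ventilation: float
    alveolar_ventilation: float
    cardiac_output: float
    perfusion_fraction: dict[str, float]
    volume_fraction: dict[str, float]
    blood_volume_fraction: dict[str, float]
    tissue_density: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("body_weight", "minute_ventilation", "alveolar_ventilation",
                     "cardiac_output"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.alveolar_ventilation > self.minute_ventilation:
            raise ParameterError(
                "alveolar ventilation cannot exceed minute ventilation"
            )
        if set(self.perfusion_fraction) != set(self.volume_fraction):
            raise ParameterError(
                "perfusion and volume fractions must cover the same compartments"
            )
        for mapping, what in (
            (self.perfusion_fraction, "perfusion fraction"),
            (self.volume_fraction, "volume fraction"),
            (self.blood_volume_fraction, "blood volume fraction"),
        ):
            for comp, f in mapping.items():
                if not 0.0 < f <= 1.0 and not (what.startswith("blood") and f == 0.0):
                    raise ParameterError(
                        f"{what} for {comp!r} must be in (0, 1], got {f}"
                    )
        total = sum(self.perfusion_fraction.values())
        if abs(total - 1.0) > PERFUSION_SUM_TOL:
            raise ParameterError(
                f"perfusion fractions sum to {total:.4f}, outside "
                f"1 ± {PERFUSION_SUM_TOL}"
            )
        for comp in self.perfusion_fraction:
            if comp not in KNOWN_COMPARTMENTS:
                raise ParameterError(f"unknown compartment {comp!r}")
        for key in self.blood_volume_fraction:
            if key not in ("arterial", "venous", "lung"):
                raise ParameterError(f"unknown blood pool {key!r}")
        for key in ("arterial", "venous"):
            if key not in self.blood_volume_fraction:
                raise ParameterError(f"missing blood pool {key!r}")

    @property
    def compartments(self) -> list[str]:
        return list(self.perfusion_fraction)

    def density(self, compartment: str) -> float:
        return self.tissue_density.get(compartment, 1.0)


@dataclass(frozen=True)
class GasSpec:
    """Partition coefficients for one gas, keyed by species.

    ``blood_gas_pc`` is the Ostwald-type blood:gas coefficient;
    ``tissue_blood_pc[species][compartment]`` the tissue:blood coefficient.
    Blood pools have an implicit tissue:blood coefficient of 1.
    ``atmospheric_percent`` is the ambient atmospheric abundance in % by
    volume (8.7e-6 % for xenon, 1 % for argon).
    """

    gas_name: str
    blood_gas_pc: dict[str, float]
    tissue_blood_pc: dict[str, dict[str, float]]
    atmospheric_percent: float

    def __post_init__(self) -> None:
        for sp, pc in self.blood_gas_pc.items():
            if pc <= 0:
                raise ParameterError(f"blood:gas PC for {sp} must be > 0")
        for sp, table in self.tissue_blood_pc.items():
            for comp, pc in table.items():
                if pc <= 0:
                    raise ParameterError(
                        f"tissue:blood PC for {sp}/{comp} must be > 0"
                    )
        if self.atmospheric_percent < 0:
            raise ParameterError("atmospheric percent must be >= 0")


@dataclass(frozen=True)
class Compartment:
    """One resolved tissue compartment: absolute flow, volume and PC."""

    name: str
    perfusion: float  # L/min
    volume: float  # L
    pc_tissue_blood: float

    def __post_init__(self) -> None:
        if self.perfusion <= 0 or self.volume <= 0 or self.pc_tissue_blood <= 0:
            raise ParameterError(
                f"compartment {self.name!r}: flow, volume and PC must be > 0"
            )


@dataclass(frozen=True)
class SubjectModel:
    """Fully resolved subject: physiology × gas, ready to simulate.

    ``arterial_volume`` includes the lung blood pool, which sits downstream
    of gas exchange and is given no separate dynamics.
    """

    physiology: SpeciesPhysiology
    gas: GasSpec
    compartments: tuple[Compartment, ...]
    arterial_volume: float
    venous_volume: float
    exchange: GasExchangeConfig = field(default_factory=GasExchangeConfig)

    def __post_init__(self) -> None:
        if self.arterial_volume <= 0 or self.venous_volume <= 0:
            raise ParameterError("blood volumes must be > 0")
        q_total = sum(c.perfusion for c in self.compartments)
        if q_total > self.physiology.cardiac_output * (1 + 1e-9):
            raise ParameterError(
                "compartment perfusion exceeds cardiac output"
            )

    @property
    def blood_gas_pc(self) -> float:
        return self.gas.blood_gas_pc[self.physiology.species_name]

    @property
    def bypass_flow(self) -> float:
        """Cardiac output not assigned to any tissue (arteriovenous bypass)."""
        return self.physiology.cardiac_output - sum(
            c.perfusion for c in self.compartments
        )

    def compartment(self, name: str) -> Compartment:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(f"no compartment {name!r}")


# ---------------------------------------------------------------------------
# Library loading
# ---------------------------------------------------------------------------


def _data_dir() -> Path:
    return Path(str(importlib.resources.files("gaspbpk"))) / "data"


def _load_yaml(path: Path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ParameterError(f"{path}: expected a mapping at top level")
    return doc


def _require(doc: dict, keys: set[str], optional: set[str], where: str) -> None:
    missing = keys - set(doc)
    unknown = set(doc) - keys - optional
    if missing:
        raise ParameterError(f"{where}: missing keys {sorted(missing)}")
    if unknown:
        raise ParameterError(f"{where}: unknown keys {sorted(unknown)}")


def load_species(species_name: str, path: Path | None = None) -> SpeciesPhysiology:
    """Load one species' physiology from the built-in library (or a file).

    Compartments absent for a species are simply not present in the
    returned mappings (they are never zero-filled).
    """
    if path is None:
        if species_name not in KNOWN_SPECIES:
            raise ParameterError(
                f"unknown species {species_name!r}; "
                f"available: {', '.join(KNOWN_SPECIES)}"
            )
        path = _data_dir() / "species" / f"{species_name}.yaml"
    doc = _load_yaml(path)
    _require(
        doc,
        {
            "species",
            "body_weight_kg",
            "minute_ventilation_l_min",
            "alveolar_ventilation_l_min",
            "cardiac_output_l_min",
            "perfusion_fraction",
            "volume_fraction",
            "blood_volume_fraction",
        },
        {"tissue_density_kg_per_l"},
        str(path),
    )
    return SpeciesPhysiology(
        species_name=doc["species"],
        body_weight=float(doc["body_weight_kg"]),
        minute_ventilation=float(doc["minute_ventilation_l_min"]),
        alveolar_ventilation=float(doc["alveolar_ventilation_l_min"]),
        cardiac_output=float(doc["cardiac_output_l_min"]),
        perfusion_fraction={k: float(v) for k, v in doc["perfusion_fraction"].items()},
        volume_fraction={k: float(v) for k, v in doc["volume_fraction"].items()},
        blood_volume_fraction={
            k: float(v) for k, v in doc["blood_volume_fraction"].items()
        },
        tissue_density={
            k: float(v)
            for k, v in doc.get("tissue_density_kg_per_l", {}).items()
        },
    )


def load_gas(gas_name: str, path: Path | None = None) -> GasSpec:
    """Load one gas' partition coefficients from the built-in library."""
    if path is None:
        if gas_name not in KNOWN_GASES:
            raise ParameterError(
                f"unknown gas {gas_name!r}; available: {', '.join(KNOWN_GASES)}"
            )
        path = _data_dir() / "gases" / f"{gas_name}.yaml"
    doc = _load_yaml(path)
    _require(
        doc, {"gas", "atmospheric_percent", "blood_gas", "tissue_blood"}, set(),
        str(path),
    )
    return GasSpec(
        gas_name=doc["gas"],
        blood_gas_pc={k: float(v) for k, v in doc["blood_gas"].items()},
        tissue_blood_pc={
            sp: {k: float(v) for k, v in table.items()}
            for sp, table in doc["tissue_blood"].items()
        },
        atmospheric_percent=float(doc["atmospheric_percent"]),
    )


def list_species() -> list[str]:
    return list(KNOWN_SPECIES)


def list_gases() -> list[str]:
    return list(KNOWN_GASES)


# ---------------------------------------------------------------------------
# Subject resolution
# ---------------------------------------------------------------------------


def _apply_overrides(
    physiology: SpeciesPhysiology, overrides: Mapping[str, float]
) -> SpeciesPhysiology:
    """Apply dotted-path overrides, e.g. ``cardiac_output`` or
    ``volume_fraction.muscle``."""
    scalar_fields = {
        "body_weight",
        "minute_ventilation",
        "alveolar_ventilation",
        "cardiac_output",
    }
    mapping_fields = {
        "perfusion_fraction",
        "volume_fraction",
        "blood_volume_fraction",
        "tissue_density",
    }
    updates: dict = {}
    for dotted, value in overrides.items():
        head, _, tail = dotted.partition(".")
        if head in scalar_fields and not tail:
            updates[head] = float(value)
        elif head in mapping_fields and tail:
            current = dict(updates.get(head, getattr(physiology, head)))
            current[tail] = float(value)
            updates[head] = current
        else:
            raise ParameterError(
                f"cannot override {dotted!r}: expected one of "
                f"{sorted(scalar_fields)} or <mapping>.<compartment> with "
                f"mapping in {sorted(mapping_fields)}"
            )
    return replace(physiology, **updates)


def build_subject(
    physiology: SpeciesPhysiology,
    gas: GasSpec,
    overrides: Mapping[str, float] | None = None,
    exchange: GasExchangeConfig | None = None,
) -> SubjectModel:
    """Resolve fractions into absolute flows/volumes and pair with a gas.

    Q_i = perfusion_fraction_i × CO; V_i = volume_fraction_i × BW / ρ_i;
    blood-pool volumes likewise (density 1 kg/L).  Overrides (dotted paths
    into the physiology) are applied before resolution, so e.g. overriding
    ``cardiac_output`` rescales every compartment flow proportionally.
    """
    if overrides:
        physiology = _apply_overrides(physiology, overrides)
    sp = physiology.species_name
    try:
        pc_table = gas.tissue_blood_pc[sp]
    except KeyError:
        raise ParameterError(
            f"gas {gas.gas_name!r} has no partition coefficients for "
            f"species {sp!r}"
        ) from None
    if sp not in gas.blood_gas_pc:
        raise ParameterError(
            f"gas {gas.gas_name!r} has no blood:gas PC for species {sp!r}"
        )
    comps = []
    bw = physiology.body_weight
    co = physiology.cardiac_output
    for name in physiology.compartments:
        if name not in pc_table:
            raise ParameterError(
                f"missing tissue:blood partition coefficient for "
                f"compartment {name!r} ({gas.gas_name}/{sp})"
            )
        comps.append(
            Compartment(
                name=name,
                perfusion=physiology.perfusion_fraction[name] * co,
                volume=physiology.volume_fraction[name] * bw / physiology.density(name),
                pc_tissue_blood=pc_table[name],
            )
        )
    bvf = physiology.blood_volume_fraction
    arterial = (bvf["arterial"] + bvf.get("lung", 0.0)) * bw
    venous = bvf["venous"] * bw
    return SubjectModel(
        physiology=physiology,
        gas=gas,
        compartments=tuple(comps),
        arterial_volume=arterial,
        venous_volume=venous,
        exchange=exchange or GasExchangeConfig(),
    )


# ---------------------------------------------------------------------------
# Intersubject scaling
# ---------------------------------------------------------------------------

#: Mean whole-body fat fraction by gender (fraction of body weight).
FAT_FRACTION = {"male": 0.135, "female": 0.265}

ScalingHook = Callable[[float, float, float], float]


def identity_hook(base_value: float, weight: float, base_weight: float) -> float:
    """Leave the base value unchanged (useful for isolating fat effects)."""
    return base_value


def allometric_hook(exponent: float) -> ScalingHook:
    """Power-law scaling: value × (weight / base_weight) ** exponent."""

    def hook(base_value: float, weight: float, base_weight: float) -> float:
        return base_value * (weight / base_weight) ** exponent

    return hook


#: Default scaling of flows with body weight: the classic 3/4-power
#: allometric exponent for cardiac output and ventilation.  Blood and
#: tissue volumes scale with weight through the (unchanged) fractions.
DEFAULT_FLOW_HOOK = allometric_hook(0.75)


def scale_subject(
    base: SpeciesPhysiology,
    weight: float,
    gender: str,
    fat_fraction: float | None = None,
    cardiac_output_hook: ScalingHook | None = None,
    ventilation_hook: ScalingHook | None = None,
    blood_volume_hook: ScalingHook | None = None,
) -> SpeciesPhysiology:
    """Scale the base physiology to a new body weight and fat fraction.

    The total fat volume fraction is set to the gender mean (13.5 % male,
    26.5 % female) unless ``fat_fraction`` is given, split among the base
    model's fat compartments in their base ratio with perfusion fractions
    untouched.  Non-fat tissue fractions are rescaled by a common factor so
    their mutual ratios and the total tissue fraction are preserved.
    Cardiac output and ventilation scale allometrically (exponent 0.75) by
    default; blood-volume *fractions* are kept, so absolute blood volumes
    scale linearly with weight.  Any hook can be replaced, e.g. with
    :func:`identity_hook`.
    """
    if weight <= 0:
        raise ParameterError(f"weight must be > 0, got {weight}")
    if gender not in FAT_FRACTION:
        raise ParameterError(
            f"gender must be one of {sorted(FAT_FRACTION)}, got {gender!r}"
        )
    target_fat = FAT_FRACTION[gender] if fat_fraction is None else fat_fraction
    if not 0.0 < target_fat < 1.0:
        raise ParameterError("fat fraction must be in (0, 1)")

    fat_comps = [c for c in base.volume_fraction if c.startswith("fat")]
    if not fat_comps:
        raise ParameterError("base physiology has no fat compartment to scale")
    base_fat = sum(base.volume_fraction[c] for c in fat_comps)
    other = [c for c in base.volume_fraction if c not in fat_comps]
    base_other = sum(base.volume_fraction[c] for c in other)
    # preserve the total tissue fraction while moving fat to its target;
    # both factors are exactly 1.0 when the target equals the base fat,
    # making the base physiology a fixed point
    fat_scale = target_fat / base_fat
    other_scale = 1.0 + (base_fat - target_fat) / base_other
    if other_scale <= 0:
        raise ParameterError("fat fraction too large for this physiology")

    volume_fraction = {}
    for c in base.volume_fraction:
        scale = fat_scale if c in fat_comps else other_scale
        volume_fraction[c] = scale * base.volume_fraction[c]

    co_hook = cardiac_output_hook or DEFAULT_FLOW_HOOK
    vent_hook = ventilation_hook or DEFAULT_FLOW_HOOK
    bv_hook = blood_volume_hook or identity_hook
    w0 = base.body_weight
    return replace(
        base,
        body_weight=weight,
        cardiac_output=co_hook(base.cardiac_output, weight, w0),
        minute_ventilation=vent_hook(base.minute_ventilation, weight, w0),
        alveolar_ventilation=vent_hook(base.alveolar_ventilation, weight, w0),
        blood_volume_fraction={
            k: bv_hook(v, weight, w0) for k, v in base.blood_volume_fraction.items()
        },
        volume_fraction=volume_fraction,
    )
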