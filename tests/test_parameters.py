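"""Parameter library: transcription fidelity, resolution, scaling."""

import dataclasses

import pytest

from gaspbpk.core import GasExchangeConfig
from gaspbpk.parameters import (
    ParameterError,
    build_subject,
    identity_hook,
    load_gas,
    load_species,
    scale_subject,
)

# Independent transcription of the published physiology/partition table,
# typed in separately from the YAML library so that a copy error in either
# place fails this test.
PHYSIOLOGY = {
    "mouse": dict(bw=0.025, mv=0.385, av=0.025, co=0.017),
    "rat": dict(bw=0.25, mv=0.18, av=0.117, co=0.083),
    "pig": dict(bw=25.0, mv=3.6, av=2.34, co=2.060),
    "human": dict(bw=70.0, mv=7.5, av=4.875, co=6.0),
}
PERFUSION = {
    "mouse": {"fat": 0.09, "liver": 0.25, "richly_perfused": 0.415,
              "muscle": 0.15, "brain": 0.095},
    "rat": {"fat": 0.09, "liver": 0.25, "richly_perfused": 0.484,
            "muscle": 0.15, "brain": 0.026},
    "pig": {"fat": 0.1747, "liver": 0.3052, "richly_perfused": 0.1829,
            "poorly_perfused": 0.0553, "muscle": 0.2523, "brain": 0.0296},
    "human": {"fat_rich": 0.04, "fat_poor": 0.01, "liver": 0.26,
              "richly_perfused": 0.3303, "poorly_perfused": 0.01,
              "muscle": 0.24, "brain": 0.093},
}
VOLUME = {
    "mouse": {"fat": 0.10, "liver": 0.055, "richly_perfused": 0.0454,
              "muscle": 0.66, "brain": 0.0046},
    "rat": {"fat": 0.07, "liver": 0.04, "richly_perfused": 0.0497,
            "muscle": 0.676, "brain": 0.0003},
    "pig": {"fat": 0.3, "liver": 0.0294, "richly_perfused": 0.0697,
            "poorly_perfused": 0.1269, "muscle": 0.4, "brain": 0.004},
    "human": {"fat_rich": 0.09, "fat_poor": 0.09, "liver": 0.06,
              "richly_perfused": 0.0624, "poorly_perfused": 0.24,
              "muscle": 0.44, "brain": 0.0176},
}
BLOOD = {
    "mouse": {"arterial": 0.0110, "venous": 0.0331, "lung": 0.0049},
    "rat": {"arterial": 0.0167, "venous": 0.050, "lung": 0.0074},
    "pig": {"arterial": 0.018, "venous": 0.042},
    "human": {"arterial": 0.0209, "venous": 0.0545, "lung": 0.00245},
}
BLOOD_GAS = {
    "xenon": {"mouse": 0.207, "rat": 0.207, "pig": 0.11, "human": 0.14},
    "argon": {"mouse": 0.037, "rat": 0.037, "pig": 0.037, "human": 0.037},
}
TISSUE_BLOOD = {
    ("xenon", "mouse"): {"fat": 6.2802, "liver": 0.7246,
                         "richly_perfused": 0.6951, "poorly_perfused": 0.7246,
                         "muscle": 0.7246, "brain": 1.1233},
    ("xenon", "rat"): {"fat": 6.2802, "liver": 0.7246,
                       "richly_perfused": 0.7229, "poorly_perfused": 0.7246,
                       "muscle": 0.7246, "brain": 1.015},
    ("xenon", "pig"): {"fat": 11.8182, "liver": 1.3636,
                       "richly_perfused": 1.3774, "poorly_perfused": 1.3636,
                       "muscle": 1.3636, "brain": 1.1233},
    ("xenon", "human"): {"fat_rich": 9.287, "fat_poor": 9.287, "liver": 1.071,
                         "richly_perfused": 1.071, "poorly_perfused": 1.071,
                         "muscle": 1.071, "brain": 1.123},
    ("argon", "mouse"): {"fat": 4.1622, "liver": 0.7539,
                         "richly_perfused": 1.0663, "poorly_perfused": 0.9987,
                         "muscle": 0.7205, "brain": 0.6747},
    ("argon", "rat"): {"fat": 4.1622, "liver": 0.7539,
                       "richly_perfused": 1.0323, "poorly_perfused": 0.9987,
                       "muscle": 0.7205, "brain": 0.6747},
    ("argon", "pig"): {"fat": 4.1622, "liver": 0.7539,
                       "richly_perfused": 1.0506, "poorly_perfused": 0.9987,
                       "muscle": 0.7205, "brain": 0.6747},
    ("argon", "human"): {"fat_rich": 4.162, "fat_poor": 4.162, "liver": 0.754,
                         "richly_perfused": 1.028, "poorly_perfused": 0.999,
                         "muscle": 0.720, "brain": 0.6751},
}


@pytest.mark.parametrize("species", list(PHYSIOLOGY))
def test_species_library_matches_reference_transcription(species):
    phys = load_species(species)
    ref = PHYSIOLOGY[species]
    assert phys.body_weight == ref["bw"]
    assert phys.minute_ventilation == ref["mv"]
    assert phys.alveolar_ventilation == ref["av"]
    assert phys.cardiac_output == ref["co"]
    assert phys.perfusion_fraction == PERFUSION[species]
    assert phys.volume_fraction == VOLUME[species]
    assert phys.blood_volume_fraction == BLOOD[species]


@pytest.mark.parametrize("gas", list(BLOOD_GAS))
def test_gas_library_matches_reference_transcription(gas):
    spec = load_gas(gas)
    assert spec.blood_gas_pc == BLOOD_GAS[gas]
    for species in PHYSIOLOGY:
        assert spec.tissue_blood_pc[species] == TISSUE_BLOOD[(gas, species)]
    assert load_gas("xenon").atmospheric_percent == 8.7e-6
    assert load_gas("argon").atmospheric_percent == 1.0


def test_absent_compartments_are_omitted_not_zero_filled():
    pig = load_species("pig")
    assert "fat_poor" not in pig.perfusion_fraction
    assert "fat" in pig.perfusion_fraction
    rat = load_species("rat")
    assert "poorly_perfused" not in rat.perfusion_fraction
    # pig lung blood is unavailable and defaults to zero volume
    assert "lung" not in pig.blood_volume_fraction


def test_unknown_species_and_gas_errors_list_options():
    with pytest.raises(ParameterError, match="mouse, rat, pig, human"):
        load_species("dog")
    with pytest.raises(ParameterError, match="xenon, argon"):
        load_gas("helium")


def test_strict_parse_rejects_unknown_keys(tmp_path):
    path = tmp_path / "bad.yaml"
    base = (
        "species: test\nbody_weight_kg: 1\nminute_ventilation_l_min: 1\n"
        "alveolar_ventilation_l_min: 0.5\ncardiac_output_l_min: 1\n"
        "perfusion_fraction: {liver: 1.0}\nvolume_fraction: {liver: 0.5}\n"
        "blood_volume_fraction: {arterial: 0.02, venous: 0.05}\n"
    )
    path.write_text(base + "typo_key: 3\n")
    with pytest.raises(ParameterError, match="typo_key"):
        load_species("test", path=path)
    path.write_text(base)
    assert load_species("test", path=path).cardiac_output == 1.0


class TestBuildSubject:
    def test_resolves_fractions_to_absolute_quantities(self):
        subject = build_subject(load_species("human"), load_gas("xenon"))
        # arterial pool = arterial fraction x BW plus the lung blood pool
        assert subject.arterial_volume == pytest.approx(
            0.0209 * 70 + 0.00245 * 70, rel=1e-12
        )
        liver = subject.compartment("liver")
        assert liver.perfusion == pytest.approx(0.26 * 6.0, rel=1e-12)
        assert liver.volume == pytest.approx(0.06 * 70 / 1.0, rel=1e-12)
        assert liver.pc_tissue_blood == 1.071

    @pytest.mark.parametrize("species", list(PHYSIOLOGY))
    @pytest.mark.parametrize("gas", list(BLOOD_GAS))
    def test_flow_conservation(self, species, gas):
        subject = build_subject(load_species(species), load_gas(gas))
        q_total = sum(c.perfusion for c in subject.compartments)
        assert q_total + subject.bypass_flow == pytest.approx(
            subject.physiology.cardiac_output, rel=1e-12
        )
        assert subject.bypass_flow >= -1e-12
        assert all(c.volume > 0 for c in subject.compartments)

    def test_cardiac_output_override_rescales_all_flows(self):
        base = build_subject(load_species("human"), load_gas("xenon"))
        halved = build_subject(
            load_species("human"), load_gas("xenon"),
            overrides={"cardiac_output": 3.0},
        )
        for c_base, c_half in zip(base.compartments, halved.compartments):
            assert c_half.perfusion == pytest.approx(c_base.perfusion / 2)

    def test_dotted_override_and_bad_path(self):
        subject = build_subject(
            load_species("human"), load_gas("xenon"),
            overrides={"volume_fraction.muscle": 0.5},
        )
        assert subject.compartment("muscle").volume == pytest.approx(0.5 * 70)
        with pytest.raises(ParameterError, match="cannot override"):
            build_subject(
                load_species("human"), load_gas("xenon"),
                overrides={"nonsense.path": 1.0},
            )

    def test_missing_partition_coefficient_names_compartment(self):
        gas = load_gas("xenon")
        stripped = dataclasses.replace(
            gas,
            tissue_blood_pc={
                "human": {
                    k: v for k, v in gas.tissue_blood_pc["human"].items()
                    if k != "brain"
                }
            },
        )
        with pytest.raises(ParameterError, match="brain"):
            build_subject(load_species("human"), stripped)


class TestScaleSubject:
    def test_male_70kg_identity_hooks_splits_fat_evenly(self):
        base = load_species("human")
        scaled = scale_subject(
            base, 70.0, "male",
            cardiac_output_hook=identity_hook,
            ventilation_hook=identity_hook,
            blood_volume_hook=identity_hook,
        )
        # base split 0.09/0.09 -> 1:1 ratio of the 13.5 % target
        assert scaled.volume_fraction["fat_rich"] == pytest.approx(0.0675)
        assert scaled.volume_fraction["fat_poor"] == pytest.approx(0.0675)
        assert scaled.cardiac_output == base.cardiac_output

    def test_female_target_fat_fraction(self):
        scaled = scale_subject(load_species("human"), 70.0, "female")
        total_fat = (
            scaled.volume_fraction["fat_rich"] + scaled.volume_fraction["fat_poor"]
        )
        assert total_fat == pytest.approx(0.265)

    def test_fixed_point_on_base_subject(self):
        base = load_species("human")
        base_fat = (
            base.volume_fraction["fat_rich"] + base.volume_fraction["fat_poor"]
        )
        scaled = scale_subject(
            base, base.body_weight, "male", fat_fraction=base_fat,
            cardiac_output_hook=identity_hook,
            ventilation_hook=identity_hook,
            blood_volume_hook=identity_hook,
        )
        assert scaled == base

    def test_nonfat_mutual_ratios_and_total_preserved(self):
        base = load_species("human")
        scaled = scale_subject(base, 60.0, "male")
        ratio = (
            scaled.volume_fraction["muscle"] / scaled.volume_fraction["brain"]
        )
        assert ratio == pytest.approx(
            base.volume_fraction["muscle"] / base.volume_fraction["brain"]
        )
        assert sum(scaled.volume_fraction.values()) == pytest.approx(
            sum(base.volume_fraction.values())
        )

    def test_allometric_flow_scaling(self):
        base = load_species("human")
        scaled = scale_subject(base, 100.0, "male")
        assert scaled.cardiac_output == pytest.approx(
            base.cardiac_output * (100.0 / 70.0) ** 0.75
        )

    def test_rejects_nonpositive_weight(self):
        with pytest.raises(ParameterError, match="weight"):
            scale_subject(load_species("human"), 0.0, "male")


def test_invalid_physiology_is_rejected():
    phys = load_species("human")
    with pytest.raises(ParameterError, match="alveolar"):
        dataclasses.replace(phys, alveolar_ventilation=10.0)
    with pytest.raises(ParameterError, match="cardiac_output"):
        dataclasses.replace(phys, cardiac_output=-1.0)


def test_exchange_config_validation():
    with pytest.raises(ValueError, match="shunt_fraction"):
        GasExchangeConfig(shunt_fraction=1.2)
    with pytest.raises(ValueError, match="temperature"):
        GasExchangeConfig(temperature_k=-3.0)
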