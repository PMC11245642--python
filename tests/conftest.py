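"""Shared fixtures: the bundled key, reference specimens and evidence.

Reference rows pair raw measurements (µm) with the indices printed for the
same specimens in the source morphometric tables; recomputed indices must
agree within the tolerance appropriate to rounded raw inputs (±0.1 for
ratios, ±1 for integer percents).
"""

from __future__ import annotations

import pytest

from monotax.key import CharacterValue, load_bundled_key
from monotax.morphometrics import SpecimenMeasurements


@pytest.fixture(scope="session")
def mononchus_key():
    return load_bundled_key("mononchus")


def holotype_measurements() -> SpecimenMeasurements:
    """The M. pseudoaquaticus holotype female (raw measurements, µm)."""
    return SpecimenMeasurements(
        specimen_id="holotype",
        taxon_label="M. pseudoaquaticus sp. nov.",
        body_length=1450,
        tail_length=195,
        pharynx_length=365,
        max_body_diameter=72,
        body_diameter_at_anus=39,
        anterior_gonad_length=187,
        posterior_gonad_length=194,
        buccal_capsule_length=29,
        buccal_capsule_width=16,
        tooth_apex_distance=6,
        lip_region_width=25,
        rectum_length=26,
    )


@pytest.fixture
def holotype():
    return holotype_measurements()


@pytest.fixture
def holotype_evidence() -> list[CharacterValue]:
    """Character evidence for the holotype as the key engine consumes it."""
    return [
        CharacterValue("body_length", 1.45),
        CharacterValue("gonads", "didelphic"),
        CharacterValue("c_prime", 5.0),
        CharacterValue("spinneret", "terminal"),
        CharacterValue("pars_refringens", "rhomb"),
        CharacterValue("subventral_ribs", "at_level_or_posterior"),
        CharacterValue("amphid_position", "anterior"),
        CharacterValue("buccal_capsule_length", 29.0),
        CharacterValue("buccal_vs_labial", 29 / 25),
        CharacterValue("tooth_position", 21.0),
        CharacterValue("vagina", "not_spotted"),
        CharacterValue("bc_ratio", 29 / 16),
        CharacterValue("tail_length", 195.0),
    ]


# (description, raw measurements, printed indices)
REFERENCE_ROWS: list[tuple[str, dict, dict]] = [
    (
        "M. pseudoaquaticus holotype",
        dict(body_length=1450, tail_length=195, pharynx_length=365,
             max_body_diameter=72, body_diameter_at_anus=39,
             anterior_gonad_length=187, posterior_gonad_length=194,
             buccal_capsule_length=29, tooth_apex_distance=6),
        dict(a=20.2, b=4.0, c=7.5, c_prime=5.0, G1=12.9, G2=13.3, tooth_position=21),
    ),
    (
        "C. parvus, Kaleytsa",
        dict(body_length=1050, tail_length=71, pharynx_length=294,
             max_body_diameter=56, body_diameter_at_anus=31,
             buccal_capsule_length=24, tooth_apex_distance=9),
        dict(a=18.7, b=3.6, c=14.8, c_prime=2.3, tooth_position=38),
    ),
    (
        "C. parvus, Dyavolski Most",
        dict(body_length=700, tail_length=60, pharynx_length=189,
             max_body_diameter=54, body_diameter_at_anus=28),
        dict(a=12.9, b=3.7, c=11.7, c_prime=2.1),
    ),
    (
        "M. truncatus, Teshel",
        dict(body_length=1890, tail_length=218, pharynx_length=468,
             body_diameter_at_anus=40,
             buccal_capsule_length=44, tooth_apex_distance=11),
        dict(b=4.0, c=8.6, c_prime=5.5, tooth_position=25),
    ),
    (
        "Mononchus sp., female 1",
        dict(body_length=1310, tail_length=230, pharynx_length=370,
             max_body_diameter=47, body_diameter_at_anus=29,
             buccal_capsule_length=45, tooth_apex_distance=10),
        dict(a=27.9, b=3.5, c=5.7, c_prime=7.9, tooth_position=22),
    ),
]

RATIO_TOL = 0.1  # printed ratios carry one decimal, raws are rounded µm
PERCENT_TOL = 1.0  # tooth position prints as an integer
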