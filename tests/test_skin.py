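"""Series-parallel epidermal resistance network and permeability analysis.

Published resistances are printed to three significant figures, so
recomputed intermediates can differ from the printed ones by up to one
unit of the last printed digit (rounded inputs propagate); the assertions
below use exactly that tolerance.
"""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from safperm.skin import (
    COMPARTMENTS,
    CompartmentResistance,
    ResistanceProfile,
    analyze,
    combine_pathways,
    corrected_log_permeability,
    deviation_vs_reference,
    log_permeability,
    skin_resistance,
    stratified_resistance,
)

resistances = st.floats(1e3, 1e15)


class TestCombinePathways:
    def test_published_granulosum_combination(self):
        # caffeic acid SG arms, printed as 1.22e7 after rounding
        assert combine_pathways(1.26e8, 1.34e7) == pytest.approx(1.22e7, abs=0.01e7)

    def test_equal_arms_halve(self):
        assert combine_pathways(4.0, 4.0) == pytest.approx(2.0)

    def test_blocked_pathway(self):
        assert combine_pathways(math.inf, 7.5) == 7.5
        assert combine_pathways(7.5, math.inf) == 7.5
        assert combine_pathways(math.inf, math.inf) == math.inf

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            combine_pathways(0.0, 1.0)
        with pytest.raises(ValueError):
            combine_pathways(1.0, -2.0)

    @given(a=resistances, b=resistances)
    def test_parallel_bound(self, a, b):
        assert combine_pathways(a, b) <= min(a, b)


class TestStratifiedResistance:
    def test_published_serial_sums(self):
        # chlorogenic acid: 1.93e9; caffeic acid: 7.75e7
        assert stratified_resistance(1.76e8, 5.13e8, 1.16e9, 8.06e7) == pytest.approx(
            1.93e9, abs=0.01e9
        )
        assert stratified_resistance(4.07e7, 1.22e7, 2.09e7, 3.72e6) == pytest.approx(
            7.75e7, abs=0.01e7
        )

    def test_unit_sum(self):
        assert stratified_resistance(1, 1, 1, 1) == 4

    @given(rs=st.tuples(resistances, resistances, resistances, resistances))
    def test_serial_bound(self, rs):
        assert stratified_resistance(*rs) >= max(rs)


class TestSkinResistance:
    def test_published_shunt_parallel(self):
        assert skin_resistance(7.75e7, 2e-11) == pytest.approx(7.74e7, abs=0.01e7)
        assert skin_resistance(1.93e9, 2e-11) == pytest.approx(1.86e9, abs=0.01e9)

    def test_no_shunt_is_identity(self):
        assert skin_resistance(123.0, 0.0) == 123.0

    @given(r=resistances, g=st.floats(0, 1e-9))
    def test_shunt_never_increases_resistance(self, r, g):
        assert skin_resistance(r, g) <= r * (1 + 1e-12)


class TestLogPermeability:
    def test_published_conversions(self):
        assert log_permeability(7.74e7) == pytest.approx(-5.89, abs=0.005)
        assert log_permeability(3.74e7) == pytest.approx(-5.57, abs=0.005)

    def test_one_cm_per_s(self):
        assert log_permeability(100.0) == 0.0

    @given(r=resistances)
    def test_round_trip_with_zero_shunt(self, r):
        assert log_permeability(skin_resistance(r, 0.0)) == pytest.approx(
            -math.log10(r / 100.0), rel=1e-12
        )


def test_offset_correction():
    assert corrected_log_permeability(-7.27, -1.12) == pytest.approx(-8.39)
    assert corrected_log_permeability(-5.57, -1.12) == pytest.approx(-6.69)
    assert corrected_log_permeability(-4.2, 0.0) == -4.2


def test_deviation_sign_convention():
    # reference minus corrected prediction
    assert deviation_vs_reference(-8.39, -5.60) == pytest.approx(2.79)
    assert deviation_vs_reference(-7.01, -6.85) == pytest.approx(0.16)
    assert deviation_vs_reference(-3.0, -3.0) == 0.0


# Published per-compound values: combined compartment resistances, network
# totals, permeability logs and the rate-limiting/pathway calls.
PUBLISHED = {
    "CAF": {
        "combined": {"SC": (4.07e7, 0.01e7), "SG": (1.22e7, 0.01e7), "SS": (2.09e7, 0.01e7), "SB": (3.72e6, 0.01e6)},
        "r_cells": (7.75e7, 0.01e7),
        "r_skin": (7.74e7, 0.01e7),
        "logkp_pred": (-5.89, 0.01),
        "logkp_corrected": (-7.01, 0.01),
        "rate_limiting": "SC",
        "pathway_at_limit": "trans",
        "classification": "retained in SC",
        "deviations": {"caco2": 1.17, "epidermis_calc": 0.16},
    },
    "CHA": {
        "combined": {"SC": (1.76e8, 0.01e8), "SG": (5.13e8, 0.01e8), "SS": (1.16e9, 0.01e9), "SB": (8.06e7, 0.01e7)},
        "r_cells": (1.93e9, 0.01e9),
        "r_skin": (1.86e9, 0.01e9),
        "logkp_pred": (-7.27, 0.01),
        "logkp_corrected": (-8.39, 0.01),
        "rate_limiting": "SS",
        "pathway_at_limit": "inter",
        "classification": "safe — below desquamation",
        "deviations": {"caco2": 2.79},
    },
    "FA": {
        "combined": {"SC": (3.23e7, 0.01e7), "SG": (1.61e6, 0.01e6), "SS": (2.88e6, 0.01e6), "SB": (6.29e5, 0.01e5)},
        "r_cells": (3.74e7, 0.01e7),
        "r_skin": (3.74e7, 0.01e7),
        "logkp_pred": (-5.57, 0.01),
        "logkp_corrected": (-6.69, 0.01),
        "rate_limiting": "SC",
        "pathway_at_limit": "trans",
        "classification": "retained in SC",
        "deviations": {"caco2": 1.71, "epidermis_calc": -0.46},
    },
}

REFERENCES = {
    "CAF": {"caco2": -5.84, "epidermis_calc": -6.85},
    "CHA": {"caco2": -5.60},
    "FA": {"caco2": -4.98, "epidermis_calc": -7.15},
}


@pytest.mark.parametrize("compound", sorted(PUBLISHED))
def test_full_profile_reproduces_published_network(profiles, compound):
    """Every published intermediate (four combined compartment
    resistances, the serial total, the shunt-parallel total, predicted and
    corrected log Kp) is reproduced from the raw pathway resistances."""
    result = analyze(profiles[compound], REFERENCES[compound])
    expect = PUBLISHED[compound]
    for name, (value, tol) in expect["combined"].items():
        assert result.compartment_resistance[name] == pytest.approx(value, abs=tol)
    assert result.r_stratified_cells == pytest.approx(*expect["r_cells"])
    assert result.r_skin == pytest.approx(*expect["r_skin"])
    assert result.logkp_pred == pytest.approx(*expect["logkp_pred"])
    assert result.logkp_corrected == pytest.approx(*expect["logkp_corrected"])
    assert result.rate_limiting_compartment == expect["rate_limiting"]
    assert result.preferred_pathway[expect["rate_limiting"]] == expect["pathway_at_limit"]
    assert result.classification == expect["classification"]
    for label, dev in expect["deviations"].items():
        assert result.deviations[label] == pytest.approx(dev, abs=0.01)


def test_layer_log_permeability_matches_reported_barrier_values(profiles):
    """The per-layer log permeability (cm/s) reproduces the reported
    barrier strengths: -5.61 (CAF SC), -5.51 (FA SC), -7.06 (CHA SS)."""
    caf = analyze(profiles["CAF"])
    fa = analyze(profiles["FA"])
    cha = analyze(profiles["CHA"])
    assert caf.layer_log_permeability["SC"] == pytest.approx(-5.61, abs=0.01)
    assert fa.layer_log_permeability["SC"] == pytest.approx(-5.51, abs=0.01)
    assert cha.layer_log_permeability["SS"] == pytest.approx(-7.06, abs=0.01)


def test_shunt_dominated_limit():
    """With a huge shunt conductance the skin resistance collapses to the
    shunt, regardless of the stratified-cell stack."""
    comp = {name: CompartmentResistance(name, 1e8, 1e8) for name in COMPARTMENTS}
    profile = ResistanceProfile("toy", comp, shunt_conductance=1e-3)
    result = analyze(profile)
    assert result.r_skin == pytest.approx(1e3, rel=1e-3)


def test_monotonicity_in_pathway_resistance():
    """Increasing any single pathway resistance never decreases R_skin."""
    base = {name: CompartmentResistance(name, 1e8, 1e7) for name in COMPARTMENTS}
    r0 = analyze(ResistanceProfile("toy", base)).r_skin
    for name in COMPARTMENTS:
        bumped = dict(base)
        bumped[name] = CompartmentResistance(name, 1e9, 1e7)
        r1 = analyze(ResistanceProfile("toy", bumped)).r_skin
        assert r1 >= r0


def test_vehicle_partition_shifts_prediction_additively(profiles):
    base = analyze(profiles["CAF"])
    shifted_profile = ResistanceProfile(
        compound="CAF",
        compartments=profiles["CAF"].compartments,
        vehicle="ethanol",
        log_k_vehicle_water=0.7,
        shunt_conductance=profiles["CAF"].shunt_conductance,
        offset=profiles["CAF"].offset,
    )
    shifted = analyze(shifted_profile)
    assert shifted.logkp_pred == pytest.approx(base.logkp_pred + 0.7)
    assert shifted.logkp_corrected == pytest.approx(base.logkp_corrected + 0.7)


def test_profile_requires_all_compartments():
    comp = {name: CompartmentResistance(name, 1.0, 1.0) for name in ("SC", "SG")}
    with pytest.raises(ValueError, match="compartments"):
        ResistanceProfile("toy", comp)


def test_rate_limiting_tie_breaks_outermost():
    comp = {name: CompartmentResistance(name, 2e8, 2e8) for name in COMPARTMENTS}
    result = analyze(ResistanceProfile("toy", comp))
    assert result.rate_limiting_compartment == "SC"
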