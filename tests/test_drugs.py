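"""Closed-form drug-property calculators."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depotsim import (
    DrugProperties,
    blend_missed_injection,
    compute_logd,
    estimate_aqueous_diffusivity,
    prodrug_dose,
    solubility_at_ph,
)
from depotsim.fixtures import aripiprazole, aripiprazole_lauroxil


@pytest.mark.parametrize(
    "logp, pka, ph, expected",
    [
        (9.8, 7.47, 7.4, 9.4626),  # prodrug at plasma pH
        (9.8, 7.47, 7.47 + 6.0, 9.8),  # fully un-ionized limit
        (5.2, 7.6, 7.6, 5.2 - math.log10(2)),  # pH = pKa halves neutral fraction
    ],
)
def test_logd_monoprotic_base(logp, pka, ph, expected):
    assert compute_logd(logp, pka, ph) == pytest.approx(expected, abs=5e-5)


@given(
    logp=st.floats(-2, 12),
    pka=st.floats(2, 12),
    ph1=st.floats(1, 13),
    dph=st.floats(0.01, 5),
)
@settings(max_examples=200, derandomize=True)
def test_logd_increasing_in_ph_and_bounded(logp, pka, ph1, dph):
    lo, hi = compute_logd(logp, pka, ph1), compute_logd(logp, pka, ph1 + dph)
    assert lo < hi <= logp


class TestSolubility:
    def test_reference_point_returned_unchanged(self):
        assert solubility_at_ph(aripiprazole_lauroxil(), 7.0) == pytest.approx(
            3e-4, rel=1e-12
        )

    def test_plasma_ph_value(self):
        # 3e-4 * (1 + 10^0.07) / (1 + 10^0.47), independently evaluated
        assert solubility_at_ph(aripiprazole_lauroxil(), 7.4) == pytest.approx(
            1.6513e-4, rel=1e-3
        )

    def test_bounded_between_intrinsic_and_cap(self):
        drug = aripiprazole_lauroxil()
        s_int = drug.s_ref / (1 + 10 ** (drug.pka - drug.ph_ref))
        values = [solubility_at_ph(drug, ph) for ph in (1.0, 4.0, 7.0, 7.4, 10.0, 14.0)]
        assert all(
            s_int * (1 - 1e-12) <= s <= s_int * drug.solubility_factor for s in values
        )
        # monotone non-increasing in pH for a base
        assert values == sorted(values, reverse=True)

    def test_high_ph_limit_is_intrinsic(self):
        drug = aripiprazole()
        s_int = drug.s_ref / (1 + 10 ** (drug.pka - drug.ph_ref))
        assert solubility_at_ph(drug, 14.0) == pytest.approx(s_int, rel=1e-4)


@pytest.mark.parametrize(
    "mw, expected",
    [(660.73, 5.226e-6), (448.38, 6.229e-6)],
)
def test_aqueous_diffusivity_correlation(mw, expected):
    assert estimate_aqueous_diffusivity(mw) == pytest.approx(expected, rel=1e-3)


def test_aqueous_diffusivity_power_law():
    mw = 300.0
    assert estimate_aqueous_diffusivity(mw * 2 ** (1 / 0.453)) == pytest.approx(
        estimate_aqueous_diffusivity(mw) / 2, rel=1e-12
    )


def test_d_aq_override_takes_precedence():
    drug = DrugProperties(
        name="x", mw=400.0, logp=3.0, pka=8.0, rbp=1.0, fup=0.1,
        s_ref=0.01, d_aq_override=1.5e-6,
    )
    assert drug.d_aq == 1.5e-6


class TestMissedInjectionBlending:
    def test_reference_medians(self):
        kp, fut = blend_missed_injection(1.84, 9.84, 1.20e-3, 2.24e-4)
        assert kp == pytest.approx(5.84, abs=1e-12)
        assert fut == pytest.approx(7.12e-4, abs=1e-15)

    def test_symmetric_and_identity(self):
        assert blend_missed_injection(2.0, 3.0, 0.1, 0.2) == blend_missed_injection(
            3.0, 2.0, 0.2, 0.1
        )
        assert blend_missed_injection(4.0, 4.0, 0.3, 0.3) == (4.0, 0.3)

    @given(
        kp1=st.floats(0.1, 50), kp2=st.floats(0.1, 50),
        f1=st.floats(1e-6, 1), f2=st.floats(1e-6, 1),
    )
    @settings(max_examples=100, derandomize=True)
    def test_midpoint_between_inputs(self, kp1, kp2, f1, f2):
        kp, fut = blend_missed_injection(kp1, kp2, f1, f2)
        assert min(kp1, kp2) <= kp <= max(kp1, kp2)
        assert min(f1, f2) <= fut <= max(f1, f2)


class TestProdrugDose:
    def test_marketed_strength(self):
        # 300 mg parent-equivalent corresponds to the 441 mg prodrug strength
        assert prodrug_dose(300, 660.73, 448.38) == pytest.approx(442.1, abs=0.05)

    def test_400_equivalent(self):
        assert prodrug_dose(400, 660.73, 448.38) == pytest.approx(589.4, abs=0.05)

    def test_identity_and_round_trip(self):
        assert prodrug_dose(123.4, 500.0, 500.0) == pytest.approx(123.4, rel=1e-15)
        forward = prodrug_dose(150.0, 660.73, 448.38)
        assert prodrug_dose(forward, 448.38, 660.73) == pytest.approx(150.0, rel=1e-14)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(mw=-1.0),
        dict(fup=0.0),
        dict(fup=1.5),
        dict(rbp=0.0),
        dict(s_ref=0.0),
        dict(solubility_factor=0.5),
    ],
)
def test_drug_properties_invariants(kwargs):
    base = dict(
        name="x", mw=400.0, logp=3.0, pka=8.0, rbp=1.0, fup=0.1, s_ref=0.01
    )
    base.update(kwargs)
    with pytest.raises(ValueError):
        DrugProperties(**base)
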