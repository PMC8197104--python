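"""Thermal-comfort kernel tests: closed-form pieces against direct
evaluation, the implicit clothing-temperature solver against a brute-force
bisection oracle, PMV against an independent straight-line transcription of
the heat-balance terms, and the defining self-equivalence and monotonicity
properties of PET."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comfortrisk.comfort import (
    EnvironmentState,
    PersonState,
    PETConfig,
    REFERENCE_PERSON,
    SolverError,
    ValidationError,
    clothing_area_factor,
    convective_coeff,
    pet,
    pet_batch,
    pet_from_values,
    pmv,
    solve_clothing_temperature,
    vapor_pressure,
)

from _oracles import oracle_pmv, oracle_tcl

ONE_MET_ONE_CLO = PersonState(met=58.15, clo=1.0)


# -------------------------------------------------------- closed-form ops

def test_vapor_pressure_examples():
    assert vapor_pressure(25.0, 0.0) == 0.0
    magnus = 611.2 * np.exp(17.62 * 20.0 / (243.12 + 20.0))
    assert vapor_pressure(20.0, 100.0) == pytest.approx(magnus, rel=1e-12)
    assert vapor_pressure(20.0, 50.0) == pytest.approx(magnus / 2.0, rel=1e-12)
    with pytest.raises(ValidationError):
        vapor_pressure(20.0, 101.0)
    with pytest.raises(ValidationError):
        vapor_pressure(20.0, -1.0)


def test_clothing_area_factor_branches():
    assert clothing_area_factor(0.0) == 1.0
    assert clothing_area_factor(0.155) == pytest.approx(1.05 + 0.645 * 0.155)
    # the boundary belongs to the lower branch
    assert clothing_area_factor(0.078) == pytest.approx(1.00 + 1.290 * 0.078)
    with pytest.raises(ValidationError):
        clothing_area_factor(-0.01)


@given(st.floats(0.0, 0.6))
@settings(max_examples=50, deadline=None)
def test_clothing_area_factor_non_decreasing(icl):
    assert clothing_area_factor(icl + 1e-3) >= clothing_area_factor(icl)


def test_convective_coeff_examples():
    assert convective_coeff(20.0, 20.0, 1.0) == pytest.approx(12.1)
    assert convective_coeff(30.0, 20.0, 0.01) == pytest.approx(2.38 * 10**0.25)
    assert convective_coeff(20.0001, 20.0, 4.0) == pytest.approx(24.2)


@given(
    st.floats(-30.0, 60.0), st.floats(-30.0, 60.0), st.floats(0.0, 15.0)
)
@settings(max_examples=100, deadline=None)
def test_convective_coeff_is_branch_max(tcl, ta, var):
    expected = max(2.38 * abs(tcl - ta) ** 0.25, 12.1 * np.sqrt(var))
    assert convective_coeff(tcl, ta, var) == pytest.approx(expected, rel=1e-12)


# ------------------------------------------------- clothing temperature

def test_tcl_zero_gradient_fixed_point():
    person = PersonState(met=58.15, clo=0.0)
    tsk = 35.7 - 0.028 * person.met
    env = EnvironmentState(ta=tsk, tmrt=tsk, v=0.0, rh=50.0)
    tcl, _, _ = solve_clothing_temperature(env, person)
    assert tcl == pytest.approx(tsk, abs=1e-6)


@pytest.mark.parametrize(
    "ta,tmrt,v,rh,person",
    [
        (22.0, 22.0, 0.1, 60.0, ONE_MET_ONE_CLO),
        (0.0, 10.0, 3.0, 50.0, REFERENCE_PERSON),
    ],
)
def test_tcl_matches_bisection_oracle(ta, tmrt, v, rh, person):
    env = EnvironmentState(ta=ta, tmrt=tmrt, v=v, rh=rh)
    tcl, hc, _ = solve_clothing_temperature(env, person)
    expected = oracle_tcl(ta, tmrt, v, person)
    assert tcl == pytest.approx(expected, abs=2e-4)
    assert hc == pytest.approx(
        max(2.38 * abs(expected - ta) ** 0.25, 12.1 * np.sqrt(v)), abs=1e-3
    )


def test_tcl_bracket_bounds(rng):
    for _ in range(20):
        ta = rng.uniform(-20, 40)
        tmrt = ta + rng.uniform(-20, 30)
        v = rng.uniform(0, 10)
        env = EnvironmentState(ta=ta, tmrt=tmrt, v=v, rh=50.0)
        tcl, _, _ = solve_clothing_temperature(env, REFERENCE_PERSON)
        tsk = 35.7 - 0.028 * REFERENCE_PERSON.met
        assert min(ta, tmrt) - 5 - 80 < tcl < tsk + 5 + 40


# ----------------------------------------------------------------- PMV

def test_pmv_zero_load_is_zero_vote():
    res = pmv(EnvironmentState(ta=26.0, tmrt=26.0, v=0.1, rh=50.0),
              ONE_MET_ONE_CLO)
    # vote is load times a positive constant: they vanish together
    assert (res.pmv == 0) == (res.load == 0)
    assert res.pmv == pytest.approx(
        (0.303 * np.exp(-0.036 * 58.15) + 0.028) * res.load, rel=1e-12
    )
    assert res.fcl >= 1.0
    assert res.hc > 0


def test_pmv_matches_independent_oracle_small_grid(rng):
    for _ in range(40):
        ta = rng.uniform(-20, 40)
        tmrt = ta + rng.uniform(-20, 30)
        v = rng.uniform(0, 10)
        rh = rng.uniform(0, 100)
        env = EnvironmentState(ta=ta, tmrt=tmrt, v=v, rh=rh)
        res = pmv(env, REFERENCE_PERSON)
        assert res.pmv == pytest.approx(
            oracle_pmv(ta, tmrt, v, rh, REFERENCE_PERSON), abs=1e-3
        )


def test_pmv_increases_with_air_temperature():
    base = pmv(EnvironmentState(ta=22.0, tmrt=22.0, v=0.1, rh=60.0),
               ONE_MET_ONE_CLO)
    warmer = pmv(EnvironmentState(ta=27.0, tmrt=22.0, v=0.1, rh=60.0),
                 ONE_MET_ONE_CLO)
    assert warmer.pmv > base.pmv


# ----------------------------------------------------------------- PET

def test_pet_reference_environment_self_equivalence():
    for ta in np.linspace(-20.0, 40.0, 13):
        env = EnvironmentState(ta=ta, tmrt=ta, v=0.1, pa=1200.0)
        value = pet(env)
        assert value.converged
        assert value.pet == pytest.approx(ta, abs=0.02)


def test_pet_monotone_in_air_temperature(rng):
    tas = np.sort(rng.uniform(-15.0, 35.0, size=8))
    pets = pet_from_values(tas, tas + 5.0, np.full_like(tas, 1.0),
                           np.full_like(tas, 60.0))
    assert np.all(np.diff(pets) > 0)


def test_pet_decreases_with_wind_below_skin_temperature():
    calm = pet(EnvironmentState(ta=0.0, tmrt=0.0, v=0.5, rh=50.0))
    windy = pet(EnvironmentState(ta=0.0, tmrt=0.0, v=5.0, rh=50.0))
    assert windy.pet < calm.pet


def test_pet_scalar_and_vector_agree():
    scalar = pet(EnvironmentState(ta=5.0, tmrt=15.0, v=2.0, rh=70.0)).pet
    vector = pet_from_values(np.array([5.0]), np.array([15.0]),
                             np.array([2.0]), np.array([70.0]))
    assert scalar == pytest.approx(vector[0], abs=2e-3)


def test_pet_bracket_failure_raises():
    env = EnvironmentState(ta=200.0, tmrt=200.0, v=0.0, rh=0.0)
    with pytest.raises(SolverError):
        pet(env, config=PETConfig(lo=-10.0, hi=10.0))


def test_pet_batch_adds_columns():
    import pandas as pd

    frame = pd.DataFrame(
        {"ta": [20.0, 0.0], "tmrt": [25.0, 5.0], "v": [0.5, 3.0],
         "rh": [50.0, 80.0]}
    )
    out = pet_batch(frame)
    assert {"pa", "pmv", "tcl", "pet"} <= set(out.columns)
    assert len(out) == 2
    with pytest.raises(ValidationError):
        pet_batch(frame.drop(columns=["rh"]))
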