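"""Thermal comfort indices: Fanger's PMV and the physiological equivalent
temperature (PET).

The PMV model is the steady-state human heat-balance model of ISO 7730: the
thermal load L (W/m^2) on the body is the metabolic heat production minus six
heat-loss pathways (diffusive skin evaporation, sweat evaporation, latent and
sensible respiration, radiation, convection), and

    PMV = (0.303 * exp(-0.036 M) + 0.028) * L.

The clothing surface temperature t_cl appears implicitly (it feeds both the
radiative and convective losses and the convective coefficient h_c), so it is
solved iteratively.

PET is defined as the air temperature of a standardized reference environment
(t_mrt = t_a, v = 0.1 m/s, vapour pressure 1200 Pa) in which a reference
subject (0.9 clo, 80 W total metabolic rate) experiences the same thermal
load as in the actual outdoor environment.  Here the load is evaluated with
the PMV body model and the reference air temperature is found by bisection;
this reproduces the defining load-equivalence of PET without the full
two-node physiology, and is documented as an approximation to the reference
simulation tools (agreement within a couple of degrees, see docs/methods.md).

All numerical kernels broadcast over numpy arrays; the dataclass API accepts
scalars or arrays alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

ArrayLike = Union[float, np.ndarray]

#: Stefan-Boltzmann constant folded with body emissivity, W/m^2/K^4.
RADIATIVE_COEFF = 3.96e-8
#: Thermal resistance of one clo unit, m^2*K/W.
CLO_TO_ICL = 0.155
#: DuBois body surface area of the reference subject, m^2.
DEFAULT_BODY_AREA = 1.80
#: Total metabolic rate of the reference subject, W.
DEFAULT_MET_WATTS = 80.0
#: Clothing insulation of the reference subject, clo.
DEFAULT_CLO = 0.9


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class SolverError(RuntimeError):
    """An iterative solver failed; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


def saturation_vapor_pressure(ta: ArrayLike) -> ArrayLike:
    """Magnus saturation vapour pressure over water, Pa.

    A single continuous form (constants 611.2 / 17.62 / 243.12) is used for
    all temperatures, including below 0 degC, to avoid a freezing-point
    discontinuity in downstream solvers.
    """
    ta = np.asarray(ta, dtype=float)
    out = 611.2 * np.exp(17.62 * ta / (243.12 + ta))
    return out if out.ndim else float(out)


def vapor_pressure(ta: ArrayLike, rh: ArrayLike) -> ArrayLike:
    """Water vapour partial pressure (Pa) from air temperature and RH (%)."""
    ta = np.asarray(ta, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValidationError("relative humidity must lie in [0, 100] %")
    out = rh / 100.0 * 611.2 * np.exp(17.62 * ta / (243.12 + ta))
    return out if out.ndim else float(out)


def clothing_area_factor(icl: ArrayLike) -> ArrayLike:
    """Clothed-to-nude body surface area ratio f_cl from I_cl (m^2*K/W)."""
    icl = np.asarray(icl, dtype=float)
    if np.any(icl < 0):
        raise ValidationError("clothing insulation must be non-negative")
    out = np.where(icl <= 0.078, 1.00 + 1.290 * icl, 1.05 + 0.645 * icl)
    return out if out.ndim else float(out)


def convective_coeff(tcl: ArrayLike, ta: ArrayLike, var: ArrayLike) -> ArrayLike:
    """Convective heat transfer coefficient h_c, W/m^2/K.

    The larger of natural convection 2.38*|t_cl - t_a|^0.25 and forced
    convection 12.1*sqrt(v_ar).
    """
    tcl = np.asarray(tcl, dtype=float)
    ta = np.asarray(ta, dtype=float)
    var = np.asarray(var, dtype=float)
    if np.any(var < 0):
        raise ValidationError("air velocity must be non-negative")
    out = np.maximum(2.38 * np.abs(tcl - ta) ** 0.25, 12.1 * np.sqrt(var))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class EnvironmentState:
    """One environmental exposure state.

    Exactly one of ``rh`` (relative humidity, %) or ``pa`` (vapour partial
    pressure, Pa) must be supplied; ``pa`` derived from ``rh`` never exceeds
    saturation.  An explicit ``pa`` is accepted as-is: the PET reference
    environment fixes pa = 1200 Pa by convention even where that exceeds
    saturation at the reference air temperature.
    """

    ta: ArrayLike
    tmrt: ArrayLike
    v: ArrayLike
    rh: ArrayLike | None = None
    pa: ArrayLike = field(default=None)  # derived unless supplied

    def __post_init__(self):
        if np.any(np.asarray(self.v, dtype=float) < 0):
            raise ValidationError("wind speed must be non-negative")
        if self.pa is None:
            if self.rh is None:
                raise ValidationError("either rh or pa must be given")
            object.__setattr__(self, "pa", vapor_pressure(self.ta, self.rh))
        elif np.any(np.asarray(self.pa, dtype=float) < 0):
            raise ValidationError("vapour pressure must be non-negative")


@dataclass(frozen=True)
class PersonState:
    """Personal factors: metabolic rate (W/m^2), mechanical work (W/m^2),
    clothing (clo).  I_cl is derived as clo * 0.155 m^2*K/W."""

    met: float
    clo: float
    work: float = 0.0

    def __post_init__(self):
        if self.met <= 0:
            raise ValidationError("metabolic rate must be positive")
        if self.work < 0:
            raise ValidationError("mechanical work must be non-negative")
        if self.clo < 0:
            raise ValidationError("clothing insulation must be non-negative")

    @property
    def icl(self) -> float:
        return self.clo * CLO_TO_ICL

    @classmethod
    def from_total_watts(
        cls,
        watts: float = DEFAULT_MET_WATTS,
        body_area_m2: float = DEFAULT_BODY_AREA,
        clo: float = DEFAULT_CLO,
        work: float = 0.0,
    ) -> "PersonState":
        """Convert a total metabolic rate in W to W/m^2 of body surface."""
        return cls(met=watts / body_area_m2, clo=clo, work=work)


#: The fixed reference subject of the PET analysis: 80 W, 0.9 clo.
REFERENCE_PERSON = PersonState.from_total_watts()


@dataclass(frozen=True)
class PMVResult:
    pmv: ArrayLike
    load: ArrayLike
    tcl: ArrayLike
    hc: ArrayLike
    fcl: ArrayLike
    iterations: int


@dataclass(frozen=True)
class PETValue:
    pet: ArrayLike
    converged: ArrayLike
    reference_load: ArrayLike


@dataclass(frozen=True)
class PETConfig:
    """Reference environment and solver settings of the PET equivalence."""

    v: float = 0.1          # m/s, reference air speed
    pa: float = 1200.0      # Pa, reference vapour pressure
    lo: float = -60.0       # degC, bisection bracket
    hi: float = 70.0
    tol: float = 1e-3       # degC, bisection half-width


def _tcl_residual(tcl, ta, tmrt, v, person: PersonState, fcl):
    """rhs(tcl) of the clothing-temperature balance and h_c at tcl."""
    hc = np.maximum(2.38 * np.abs(tcl - ta) ** 0.25, 12.1 * np.sqrt(v))
    rhs = (
        35.7
        - 0.028 * (person.met - person.work)
        - person.icl
        * (
            RADIATIVE_COEFF * fcl * ((tcl + 273.0) ** 4 - (tmrt + 273.0) ** 4)
            + fcl * hc * (tcl - ta)
        )
    )
    return rhs, hc


def solve_clothing_temperature(
    env: EnvironmentState,
    person: PersonState,
    tol: float = 1e-4,
    max_iter: int = 500,
    damping: float = 0.5,
):
    """Solve the implicit clothing-surface-temperature balance.

    Damped fixed-point iteration (classic ISO scheme) started midway between
    the skin-temperature term and the air temperature; elements that fail to
    contract (strong wind makes the map expansive) fall back to bisection on
    the monotone residual, which guarantees termination.

    Returns ``(tcl, hc, iterations)``; scalar in, scalar out.
    """
    ta, tmrt, v = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (env.ta, env.tmrt, env.v))
    )
    scalar = ta.ndim == 0
    ta, tmrt, v = np.atleast_1d(ta), np.atleast_1d(tmrt), np.atleast_1d(v)
    fcl = clothing_area_factor(person.icl)
    tsk = 35.7 - 0.028 * (person.met - person.work)

    tcl = (tsk + ta) / 2.0
    iterations = 0
    resid = np.full_like(ta, np.inf)
    with np.errstate(over="ignore", invalid="ignore"):
        for iterations in range(1, max_iter + 1):
            rhs, _ = _tcl_residual(tcl, ta, tmrt, v, person, fcl)
            resid = np.abs(rhs - tcl)
            if np.all(resid < tol):
                break
            tcl = tcl + damping * (rhs - tcl)
            # keep divergent iterates finite; they are re-solved by bisection
            tcl = np.clip(tcl, -250.0, 300.0)

    stuck = ~(resid < tol) | ~np.isfinite(tcl)
    if np.any(stuck):
        tcl = np.where(np.isfinite(tcl), tcl, (tsk + ta) / 2.0)
        lo = np.minimum(np.minimum(ta, tmrt), tsk) - 80.0
        hi = np.maximum(np.maximum(ta, tmrt), tsk) + 40.0
        f_lo = lo - _tcl_residual(lo, ta, tmrt, v, person, fcl)[0]
        f_hi = hi - _tcl_residual(hi, ta, tmrt, v, person, fcl)[0]
        if np.any(stuck & ((f_lo > 0) | (f_hi < 0))):
            raise SolverError(
                "clothing-temperature bracket failure", last_iterate=tcl
            )
        # residual t - rhs(t) is strictly increasing: plain bisection
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            f_mid = mid - _tcl_residual(mid, ta, tmrt, v, person, fcl)[0]
            hi = np.where(f_mid >= 0, mid, hi)
            lo = np.where(f_mid < 0, mid, lo)
            iterations += 1
        tcl = np.where(stuck, 0.5 * (lo + hi), tcl)

    _, hc = _tcl_residual(tcl, ta, tmrt, v, person, fcl)
    if scalar:
        return float(tcl[0]), float(hc[0]), iterations
    return tcl, hc, iterations


def pmv(env: EnvironmentState, person: PersonState) -> PMVResult:
    """Predicted mean vote and the thermal load it scales.

    The load is metabolic heat minus the six ISO heat-loss terms; the sweat
    term 0.42*((M-W) - 58.15) is clamped at zero below the resting rate.
    """
    tcl, hc, iterations = solve_clothing_temperature(env, person)
    ta = np.asarray(env.ta, dtype=float)
    tmrt = np.asarray(env.tmrt, dtype=float)
    pa = np.asarray(env.pa, dtype=float)
    m, w = person.met, person.work
    mw = m - w
    fcl = clothing_area_factor(person.icl)

    skin_diffusion = 3.05e-3 * (5733.0 - 6.99 * mw - pa)
    sweat = np.maximum(0.0, 0.42 * (mw - 58.15))
    latent_resp = 1.7e-5 * m * (5867.0 - pa)
    dry_resp = 0.0014 * m * (34.0 - ta)
    radiation = RADIATIVE_COEFF * fcl * ((tcl + 273.0) ** 4 - (tmrt + 273.0) ** 4)
    convection = fcl * hc * (tcl - ta)

    load = mw - skin_diffusion - sweat - latent_resp - dry_resp - radiation - convection
    vote = (0.303 * np.exp(-0.036 * m) + 0.028) * load
    if np.ndim(vote) == 0 or (isinstance(vote, np.ndarray) and vote.ndim == 0):
        vote, load, tcl, hc = (float(x) for x in (vote, load, tcl, hc))
    return PMVResult(pmv=vote, load=load, tcl=tcl, hc=hc, fcl=float(fcl),
                     iterations=iterations)


def thermal_load(ta, tmrt, v, pa, person: PersonState):
    """Body thermal load (W/m^2) for array inputs; kernel behind PET."""
    env = EnvironmentState(ta=ta, tmrt=tmrt, v=v, pa=pa)
    return pmv(env, person).load


def pet(
    env: EnvironmentState,
    person: PersonState = REFERENCE_PERSON,
    config: PETConfig = PETConfig(),
) -> PETValue:
    """Physiological equivalent temperature by load equivalence.

    Bisects the reference-environment air temperature until the reference
    thermal load matches the actual one; the load is strictly increasing in
    the reference air temperature, so the bracket is valid whenever the
    actual load lies between the bracket-end loads.
    """
    actual = np.atleast_1d(
        np.asarray(thermal_load(env.ta, env.tmrt, env.v, env.pa, person),
                   dtype=float)
    )
    scalar = np.ndim(env.ta) == 0

    lo = np.full_like(actual, config.lo)
    hi = np.full_like(actual, config.hi)

    def ref_load(t):
        return np.asarray(
            thermal_load(t, t, config.v, config.pa, person), dtype=float
        )

    f_lo = ref_load(lo) - actual
    f_hi = ref_load(hi) - actual
    ok = (f_lo <= 0) & (f_hi >= 0)
    if not np.all(ok):
        raise SolverError("PET bracket failure: load outside reference range",
                          last_iterate=actual)

    n_steps = int(np.ceil(np.log2((config.hi - config.lo) / config.tol)))
    for _ in range(n_steps):
        mid = 0.5 * (lo + hi)
        f_mid = ref_load(mid) - actual
        hi = np.where(f_mid >= 0, mid, hi)
        lo = np.where(f_mid < 0, mid, lo)
    result = 0.5 * (lo + hi)
    converged = (hi - lo) <= 2 * config.tol

    if scalar:
        return PETValue(pet=float(result[0]), converged=bool(converged[0]),
                        reference_load=float(actual[0]))
    return PETValue(pet=result, converged=converged, reference_load=actual)


def pet_from_values(ta, tmrt, v, rh,
                    person: PersonState = REFERENCE_PERSON,
                    config: PETConfig = PETConfig()):
    """PET for array inputs given RH in percent; returns the PET array."""
    env = EnvironmentState(ta=ta, tmrt=tmrt, v=v, rh=rh)
    return pet(env, person, config).pet


def pet_batch(frame, person: PersonState = REFERENCE_PERSON,
              config: PETConfig = PETConfig()):
    """Batch mode over a DataFrame with columns ta, tmrt, v, rh.

    Returns a copy with added columns pa, pmv, tcl, pet.
    """
    required = {"ta", "tmrt", "v", "rh"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    out = frame.copy()
    env = EnvironmentState(
        ta=out["ta"].to_numpy(float),
        tmrt=out["tmrt"].to_numpy(float),
        v=out["v"].to_numpy(float),
        rh=out["rh"].to_numpy(float),
    )
    res = pmv(env, person)
    out["pa"] = env.pa
    out["pmv"] = res.pmv
    out["tcl"] = res.tcl
    out["pet"] = pet(env, person, config).pet
    return out
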