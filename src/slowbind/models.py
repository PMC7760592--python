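"""Closed-form kinetic models for slow-binding enzyme inhibition.

This module collects the algebraic layer of the analysis: the integrated
slow-onset progress curve, the general linear reversible-inhibition rate
law, the hyperbolic dependence of the observed onset rate constant on
inhibitor concentration that diagnoses a two-step (induced-fit) binding
mechanism, the chain of constants derived from the elementary rates
(steady-state inhibition constant, overall off-rate, residence time,
dissociation half-time), target fractional occupancy, and the
two-exponential residual-activity law for hysteretic (two-conformer)
covalent inactivation.

All rates are in min^-1 (second-order rates in M^-1 min^-1) and all
concentrations in molar. Functions are pure and perform no fitting.

Mechanistic background
----------------------
The two-step ("type B") slow-binding scheme is

    E + I  <==[k+3, k-3]==>  EI  <==[k+4, k-4]==>  EI*

with a fast initial binding equilibrium (K_i = k-3/k+3) followed by a slow
isomerization to a tightened complex EI*. At steady state the apparent
inhibition constant tightens to K_i* = K_i k-4/(k-4 + k+4), and the overall
dissociation rate of inhibitor from the target sets the residence time
tau = 1/k_off.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, model_validator

__all__ = [
    "RateConstants",
    "AssayConditions",
    "BiphasicParams",
    "progress_curve",
    "linear_progress",
    "reversible_rate",
    "kobs_type_b",
    "derive_constants",
    "fractional_occupancy",
    "biphasic_activity",
]

LN2 = math.log(2.0)


def _require_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.all(np.isfinite(value)):
            raise ValueError(f"{name} must be finite, got {value!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class RateConstants(BaseModel):
    """Elementary and derived constants of the two-step binding scheme.

    Attributes
    ----------
    k_plus3:
        Second-order association rate of the initial encounter complex EI,
        M^-1 min^-1.
    k_minus3:
        First-order dissociation rate of EI, min^-1.
    k_plus4, k_minus4:
        Forward / reverse isomerization rates EI <-> EI*, min^-1.
    Ki:
        Initial inhibition constant k_minus3/k_plus3, molar.
    Ki_star:
        Steady-state inhibition constant of the tightened complex, molar.
    koff_overall:
        Overall dissociation rate of inhibitor from the target, min^-1.
    tau:
        Residence time 1/koff_overall, minutes.
    t_half_diss:
        Dissociation half-time ln2 * tau, minutes.
    """

    model_config = {"frozen": True}

    k_plus3: float
    k_minus3: float
    k_plus4: float
    k_minus4: float
    Ki: float
    Ki_star: float
    koff_overall: float
    tau: float
    t_half_diss: float

    @model_validator(mode="after")
    def _check_invariants(self) -> "RateConstants":
        for name in (
            "k_plus3",
            "k_minus3",
            "k_plus4",
            "k_minus4",
            "Ki",
            "Ki_star",
            "koff_overall",
            "tau",
            "t_half_diss",
        ):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if abs(self.Ki * self.k_plus3 - self.k_minus3) > 1e-9 * self.k_minus3:
            raise ValueError("Ki * k_plus3 must equal k_minus3")
        expected_star = self.Ki * self.k_minus4 / (self.k_minus4 + self.k_plus4)
        if abs(self.Ki_star - expected_star) > 1e-9 * expected_star:
            raise ValueError("Ki_star inconsistent with Ki * k-4/(k-4 + k+4)")
        if self.Ki_star > self.Ki * (1 + 1e-12):
            raise ValueError("Ki_star must not exceed Ki")
        if abs(self.tau * self.koff_overall - 1.0) > 1e-9:
            raise ValueError("tau must equal 1/koff_overall")
        if abs(self.t_half_diss - LN2 * self.tau) > 1e-9 * self.t_half_diss:
            raise ValueError("t_half_diss must equal ln2 * tau")
        return self


class AssayConditions(BaseModel):
    """One assay condition: substrate/inhibitor levels and signal constants.

    Concentrations are molar; ``Vmax`` is molar product per minute;
    ``extinction_coeff`` (M^-1 cm^-1) and ``path_length`` (cm) convert
    product concentration to absorbance.
    """

    model_config = {"frozen": True}

    S: float
    Km: float
    I: float = 0.0
    E0: float = 1e-10
    Vmax: Optional[float] = None
    extinction_coeff: float = 13_600.0
    path_length: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "AssayConditions":
        for name in ("S", "Km", "E0", "extinction_coeff", "path_length"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if self.Vmax is not None and not (np.isfinite(self.Vmax) and self.Vmax > 0):
            raise ValueError("Vmax must be strictly positive when given")
        if not (np.isfinite(self.I) and self.I >= 0):
            raise ValueError("inhibitor concentration I must be >= 0")
        return self


class BiphasicParams(BaseModel):
    """Parameters of the two-conformer (hysteretic) inactivation model.

    The enzyme exists as two slowly interconverting forms E and E' present
    at t=0 in amounts ``E0_fast`` and ``E0_slow`` (E_tot = E0_fast +
    E0_slow). Each form is inactivated by the covalent agent with a
    saturable pseudo-first-order rate k_obs = k_p [I]/(K_I + [I]).
    """

    model_config = {"frozen": True}

    E0_fast: float
    E0_slow: float
    kp_fast: float
    kp_slow: float
    KI_fast: float
    KI_slow: float

    @model_validator(mode="after")
    def _check(self) -> "BiphasicParams":
        for name in ("kp_fast", "kp_slow", "KI_fast", "KI_slow"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if self.E0_fast < 0 or self.E0_slow < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.E0_fast + self.E0_slow <= 0:
            raise ValueError("total enzyme must be positive")
        return self

    @property
    def E_tot(self) -> float:
        return self.E0_fast + self.E0_slow


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def progress_curve(t, v_i: float, v_ss: float, k_obs: float):
    """Integrated slow-onset progress curve.

    P(t) = v_ss t + (v_i - v_ss)(1 - exp(-k_obs t))/k_obs

    describes product accumulation when the instantaneous velocity relaxes
    exponentially from an initial value ``v_i`` to a steady-state value
    ``v_ss`` with first-order rate constant ``k_obs`` (the reciprocal of
    the lag time).

    Parameters are in signal units per minute (``v_i``, ``v_ss``), min^-1
    (``k_obs``) and minutes (``t``, scalar or array, >= 0).
    """
    t = np.asarray(t, dtype=float)
    _require_finite(t=t, v_i=v_i, v_ss=v_ss, k_obs=k_obs)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if k_obs <= 0:
        raise ValueError(
            "k_obs must be > 0; for the uninhibited (no-lag) case use linear_progress"
        )
    out = v_ss * t + (v_i - v_ss) * (-np.expm1(-k_obs * t)) / k_obs
    return out if out.ndim else float(out)


def linear_progress(t, v: float):
    """Lag-free progress curve P(t) = v t (the v_i = v_ss special case)."""
    t = np.asarray(t, dtype=float)
    _require_finite(t=t, v=v)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = v * t
    return out if out.ndim else float(out)


def reversible_rate(
    cond: AssayConditions,
    K_ci: Optional[float] = None,
    K_ui: Optional[float] = None,
) -> float:
    """Initial velocity under general linear reversible inhibition.

    v = Vmax [S] / ( Km (1 + [I]/K_ci) + [S] (1 + [I]/K_ui) )

    ``K_ci`` and ``K_ui`` are the competitive and uncompetitive inhibition
    constants. An absent constant (``None``) encodes the corresponding pure
    limit: ``K_ui=None`` gives pure competitive inhibition, ``K_ci=None``
    pure uncompetitive, both absent the uninhibited Michaelis-Menten rate.
    """
    if cond.Vmax is None:
        raise ValueError("AssayConditions.Vmax is required for reversible_rate")
    for name, K in (("K_ci", K_ci), ("K_ui", K_ui)):
        if K is not None and not (np.isfinite(K) and K > 0):
            raise ValueError(f"{name} must be strictly positive or None, got {K!r}")
    comp = 1.0 + (cond.I / K_ci if K_ci is not None else 0.0)
    uncomp = 1.0 + (cond.I / K_ui if K_ui is not None else 0.0)
    return cond.Vmax * cond.S / (cond.Km * comp + cond.S * uncomp)


def kobs_type_b(
    I,
    Ki: float,
    k_plus4: float,
    k_minus4: float,
    S: float = 0.0,
    Km: Optional[float] = None,
):
    """Observed onset rate for two-step (type B) slow-binding inhibition.

    k_obs = k-4 + k+4 [I] / ( K_i (1 + [S]/Km) + [I] )

    The intercept at [I]=0 is k-4 and the asymptote as [I] -> inf is
    k-4 + k+4; a competitive substrate at concentration ``S`` shifts the
    apparent half-saturation inhibitor level by the factor (1 + S/Km).

    Raises if ``S > 0`` without a ``Km`` — the substrate-competition factor
    cannot be silently dropped.
    """
    I = np.asarray(I, dtype=float)
    _require_finite(I=I, Ki=Ki, k_plus4=k_plus4, k_minus4=k_minus4, S=S)
    if np.any(I < 0):
        raise ValueError("inhibitor concentration must be >= 0")
    for name, v in (("Ki", Ki), ("k_plus4", k_plus4), ("k_minus4", k_minus4)):
        if v <= 0:
            raise ValueError(f"{name} must be strictly positive")
    if S < 0:
        raise ValueError("substrate concentration must be >= 0")
    if S > 0:
        if Km is None:
            raise ValueError("Km is required when S > 0")
        if not (np.isfinite(Km) and Km > 0):
            raise ValueError("Km must be strictly positive")
        K_app = Ki * (1.0 + S / Km)
    else:
        K_app = Ki
    out = k_minus4 + k_plus4 * I / (K_app + I)
    return out if out.ndim else float(out)


def derive_constants(
    Ki: float,
    k_plus4: float,
    k_minus4: float,
    k_plus3: float,
) -> RateConstants:
    """Derive the full constant chain from the fitted type-B elementaries.

    From the initial inhibition constant ``Ki``, the isomerization rates
    ``k_plus4``/``k_minus4`` and an assumed (or measured) association rate
    ``k_plus3``:

    - k-3      = Ki k+3
    - K_i*     = Ki k-4 / (k-4 + k+4)
    - tau      = (k-3 + k+4 + k-4) / (k-3 k-4)   [residence time, min]
    - k_off    = 1/tau
    - t_1/2    = ln2 / k_off
    """
    for name, v in (
        ("Ki", Ki),
        ("k_plus4", k_plus4),
        ("k_minus4", k_minus4),
        ("k_plus3", k_plus3),
    ):
        if not (np.isfinite(v) and v > 0):
            raise ValueError(f"{name} must be strictly positive, got {v!r}")
    k_minus3 = Ki * k_plus3
    Ki_star = Ki * k_minus4 / (k_minus4 + k_plus4)
    tau = (k_minus3 + k_plus4 + k_minus4) / (k_minus3 * k_minus4)
    koff = 1.0 / tau
    return RateConstants(
        k_plus3=k_plus3,
        k_minus3=k_minus3,
        k_plus4=k_plus4,
        k_minus4=k_minus4,
        Ki=Ki,
        Ki_star=Ki_star,
        koff_overall=koff,
        tau=tau,
        t_half_diss=LN2 * tau,
    )


def fractional_occupancy(I, Ki_star: float):
    """Fractional occupancy of the target at free inhibitor level ``I``.

    FO = [I] / ([I] + K_i*), a rectangular hyperbola rising from 0 through
    0.5 at [I] = K_i* toward 1. Uses the steady-state constant of the
    tightened complex, so it describes occupancy once binding has fully
    equilibrated.
    """
    I = np.asarray(I, dtype=float)
    _require_finite(I=I, Ki_star=Ki_star)
    if np.any(I < 0):
        raise ValueError("inhibitor concentration must be >= 0")
    if Ki_star <= 0:
        raise ValueError("Ki_star must be strictly positive")
    out = I / (I + Ki_star)
    return out if out.ndim else float(out)


def biphasic_activity(t, p: BiphasicParams, I: float):
    """Residual active enzyme under two-conformer covalent inactivation.

    E(t) = E0_fast exp(-k_obs t) + E0_slow exp(-k'_obs t)

    with each phase's pseudo-first-order rate saturating in the inactivator
    concentration, k_obs = k_p [I]/(K_I + [I]). With ``E0_slow = 0`` the
    decay is a single exponential (the classical first-order inactivation
    limit).
    """
    t = np.asarray(t, dtype=float)
    _require_finite(t=t, I=I)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if I < 0:
        raise ValueError("inactivator concentration must be >= 0")
    k_fast = p.kp_fast * I / (p.KI_fast + I)
    k_slow = p.kp_slow * I / (p.KI_slow + I)
    out = p.E0_fast * np.exp(-k_fast * t) + p.E0_slow * np.exp(-k_slow * t)
    return out if out.ndim else float(out)
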