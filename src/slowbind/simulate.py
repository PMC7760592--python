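"""Mechanistic simulator for slow-binding inhibition assays.

Generates synthetic assay data by deterministic integration of the
mass-action scheme underlying two-step slow-binding inhibition,

    E + I <==[k+3, k-3]==> EI <==[k+4, k-4]==> EI* --[k_acyl]--> acyl-E
                                                acyl-E --[k_react]--> E + I

with substrate turnover carried as a Michaelis-Menten flux: the
inhibitor-free enzyme pool is partitioned between free enzyme and the
Michaelis complex in rapid equilibrium (fraction 1/(1+S/Km) available for
inhibitor binding), so a competitive substrate protects against inhibitor
binding by exactly the (1+S/Km) factor that appears in the closed-form
onset rate law.

Enzyme and inhibitor mass balances are enforced by construction: only the
bound enzyme species and the substrate are integrated, and the free pools
are recovered from the conserved totals, so the sum over enzyme states is
conserved to floating-point roundoff at every output time.

Two-conformer (hysteretic) covalent inactivation time courses are produced
directly from the closed-form two-exponential law, since no additional
states are involved at the residual-activity level.

Gaussian noise is added to the final signal, reproducibly from an explicit
seed.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator
from scipy.integrate import solve_ivp

from .models import AssayConditions, BiphasicParams, biphasic_activity

__all__ = [
    "MechanismSpec",
    "ProgressTrace",
    "ActivityTimeCourse",
    "IntegrationError",
    "integrate_states",
    "simulate_progress",
    "simulate_reactivation",
    "simulate_biphasic_inactivation",
    "signal_convert",
    "signal_invert",
]


class IntegrationError(RuntimeError):
    """ODE integration failed or produced unphysical concentrations."""


class MechanismSpec(BaseModel):
    """Rate constants of the simulated mechanism.

    ``k_plus3``/``k_minus3`` are the fast binding step (M^-1 min^-1 and
    min^-1), ``k_plus4``/``k_minus4`` the slow isomerization (min^-1),
    ``kcat`` the turnover number (min^-1). ``k_acyl`` (EI* -> acyl-enzyme)
    and ``k_react`` (deacylation regenerating free enzyme and releasing
    intact inhibitor) extend the scheme with a transient covalent step;
    both default to 0 (purely reversible scheme). An optional
    ``hysteresis`` block carries the two-conformer phosphylation constants.
    """

    model_config = {"frozen": True}

    k_plus3: float
    k_minus3: float
    k_plus4: float = 0.0
    k_minus4: float = 0.0
    kcat: float = 2.0e2
    k_acyl: float = 0.0
    k_react: float = 0.0
    hysteresis: Optional[BiphasicParams] = None

    @model_validator(mode="after")
    def _check(self) -> "MechanismSpec":
        for name in ("k_plus3", "k_minus3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("k_plus4", "k_minus4", "kcat", "k_acyl", "k_react"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        # isomerization must be reversible or absent
        if (self.k_plus4 > 0) != (self.k_minus4 > 0):
            raise ValueError("k_plus4 and k_minus4 must both be zero or both positive")
        if self.k_acyl > 0 and self.k_plus4 == 0:
            raise ValueError("acylation proceeds from EI*; it requires k_plus4 > 0")
        return self

    @property
    def Ki(self) -> float:
        return self.k_minus3 / self.k_plus3


class ProgressTrace(BaseModel):
    """One simulated (or loaded) product time course at fixed [S], [I]."""

    model_config = {"frozen": True, "arbitrary_types_allowed": True}

    times: np.ndarray
    signal: np.ndarray
    condition: AssayConditions
    signal_units: str = "absorbance"
    noise_sd: float = 0.0
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "ProgressTrace":
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and signal must be 1-D arrays of equal length")
        if t.size and (t[0] < 0 or np.any(np.diff(t) <= 0)):
            raise ValueError("times must be strictly increasing and start at >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", y)
        return self


class ActivityTimeCourse(BaseModel):
    """Residual enzymatic activity (fraction of uninhibited control) vs time."""

    model_config = {"frozen": True, "arbitrary_types_allowed": True}

    times: np.ndarray
    residual_activity: np.ndarray
    metadata: dict = {}
    noise_sd: float = 0.0
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "ActivityTimeCourse":
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.residual_activity, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("times and residual_activity must match in length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "residual_activity", a)
        return self


# ---------------------------------------------------------------------------
# Core integration
# ---------------------------------------------------------------------------

# state vector: [EI, EI*, acyl-E, S]; free pools recovered from totals


def _rhs(t, y, spec: MechanismSpec, Km: float, E_tot: float, I_tot: float):
    EI, EIs, EA, S = y
    bound = EI + EIs + EA
    Ef = E_tot - bound
    I_free = I_tot - bound
    ff = 1.0 / (1.0 + S / Km) if S > 0 else 1.0
    bind = spec.k_plus3 * I_free * Ef * ff
    dEI = bind - (spec.k_minus3 + spec.k_plus4) * EI + spec.k_minus4 * EIs
    dEIs = spec.k_plus4 * EI - (spec.k_minus4 + spec.k_acyl) * EIs
    dEA = spec.k_acyl * EIs - spec.k_react * EA
    dS = -spec.kcat * Ef * S / (Km + S) if S > 0 else 0.0
    return (dEI, dEIs, dEA, dS)


def _integrate(
    spec: MechanismSpec,
    times: np.ndarray,
    y0: np.ndarray,
    Km: float,
    E_tot: float,
    I_tot: float,
    rtol: float = 1e-9,
) -> np.ndarray:
    t0, t1 = float(times[0]), float(times[-1])
    atol = 1e-12 * E_tot
    sol = solve_ivp(
        _rhs,
        (t0, t1),
        y0,
        t_eval=times,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        args=(spec, Km, E_tot, I_tot),
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed ({sol.message}) for spec={spec.model_dump()}, "
            f"E_tot={E_tot:g}, I_tot={I_tot:g}"
        )
    y = sol.y
    # unphysical states are a hard failure, not something to clip silently
    slack = 1e3 * atol
    if np.any(y[:3] < -slack) or np.any(y[3] < -1e-9 * max(y0[3], 1.0)):
        raise IntegrationError("negative concentration encountered during integration")
    bound = y[0] + y[1] + y[2]
    if np.any(bound > E_tot * (1 + 1e-9) + slack):
        raise IntegrationError("bound enzyme exceeds total enzyme")
    return np.clip(y, 0.0, None)


def integrate_states(
    spec: MechanismSpec,
    cond: AssayConditions,
    times,
) -> pd.DataFrame:
    """Integrate the full scheme and return every species trajectory.

    Returns a DataFrame with columns ``t_min, E_free, EI, EI_star, acyl_E,
    S, P, I_free`` (all molar except time). ``E_free`` is the
    inhibitor-free enzyme pool (free enzyme plus Michaelis complex).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1-D array")
    y0 = np.array([0.0, 0.0, 0.0, cond.S])
    y = _integrate(spec, times, y0, cond.Km, cond.E0, cond.I)
    bound = y[0] + y[1] + y[2]
    return pd.DataFrame(
        {
            "t_min": times,
            "E_free": cond.E0 - bound,
            "EI": y[0],
            "EI_star": y[1],
            "acyl_E": y[2],
            "S": y[3],
            "P": cond.S - y[3],
            "I_free": cond.I - bound,
        }
    )


# ---------------------------------------------------------------------------
# Signal conversion
# ---------------------------------------------------------------------------


def signal_convert(product, cond: AssayConditions):
    """Product concentration (M) -> absorbance via Beer-Lambert."""
    return np.asarray(product, dtype=float) * cond.extinction_coeff * cond.path_length


def signal_invert(absorbance, cond: AssayConditions):
    """Absorbance -> product concentration (M); exact inverse of signal_convert."""
    return np.asarray(absorbance, dtype=float) / (
        cond.extinction_coeff * cond.path_length
    )


# ---------------------------------------------------------------------------
# Public simulators
# ---------------------------------------------------------------------------


def simulate_progress(
    spec: MechanismSpec,
    cond: AssayConditions,
    times,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    signal_units: str = "absorbance",
) -> ProgressTrace:
    """Simulate one product progress curve under fixed [S] and [I].

    The full system is integrated (no pseudo-first-order assumption), the
    product trace is converted to the requested signal units
    (``"absorbance"`` or ``"product"``), and Gaussian noise of standard
    deviation ``noise_sd`` (signal units) is added reproducibly from
    ``seed``.
    """
    if signal_units not in ("absorbance", "product"):
        raise ValueError("signal_units must be 'absorbance' or 'product'")
    states = integrate_states(spec, cond, times)
    product = states["P"].to_numpy()
    signal = signal_convert(product, cond) if signal_units == "absorbance" else product
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, signal.shape)
    return ProgressTrace(
        times=np.asarray(times, dtype=float),
        signal=signal,
        condition=cond,
        signal_units=signal_units,
        noise_sd=noise_sd,
        seed=seed,
    )


def simulate_reactivation(
    spec: MechanismSpec,
    dilution_factor: float,
    t_switch: float,
    times,
    I0: float = 2e-8,
    E0: float = 1e-10,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> ActivityTimeCourse:
    """Simulate inhibition followed by dilution-triggered reactivation.

    The enzyme is incubated with inhibitor at ``I0`` (no substrate present)
    from t=0 to ``t_switch`` minutes; at the switch every concentration is
    divided by ``dilution_factor`` (instantaneous, perfect mixing) and
    integration continues. Residual activity is the instantaneous fraction
    of catalytically competent (inhibitor-free) enzyme, which is what a
    sampling activity assay reports relative to an uninhibited control.

    ``times`` are absolute minutes and may span both phases. Recovery after
    a large dilution is governed by the slow unbinding/deacylation rates,
    so the fitted first-order recovery constant reports k_off (purely
    reversible scheme) or the deacylation rate when the covalent pool
    dominates.
    """
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    if t_switch < 0:
        raise ValueError("t_switch must be >= 0")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1-D array")

    Km = 1.0  # irrelevant: no substrate in the incubation
    pre_mask = times <= t_switch
    activity = np.empty_like(times)

    # phase 1: inhibition at I0
    y0 = np.array([0.0, 0.0, 0.0, 0.0])
    if t_switch > 0:
        t_pre = np.unique(np.concatenate([[0.0], times[pre_mask], [t_switch]]))
        y_pre = _integrate(spec, t_pre, y0, Km, E0, I0)
        bound_pre = y_pre[0] + y_pre[1] + y_pre[2]
        lut = dict(zip(t_pre, (E0 - bound_pre) / E0))
        activity[pre_mask] = [lut[t] for t in times[pre_mask]]
        y_switch = y_pre[:, -1] / dilution_factor
    else:
        activity[pre_mask] = 1.0
        y_switch = y0.copy()

    # phase 2: dilute everything and continue; fractions are continuous
    E0_post = E0 / dilution_factor
    I0_post = I0 / dilution_factor
    post = times[~pre_mask]
    if post.size:
        t_post = np.concatenate([[t_switch], post]) if post[0] > t_switch else post
        y_post = _integrate(spec, t_post, y_switch, Km, E0_post, I0_post)
        bound_post = (y_post[0] + y_post[1] + y_post[2])[-post.size :]
        activity[~pre_mask] = (E0_post - bound_post) / E0_post

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        activity = activity + rng.normal(0.0, noise_sd, activity.shape)
    return ActivityTimeCourse(
        times=times,
        residual_activity=activity,
        metadata={
            "I0_molar": I0,
            "E0_molar": E0,
            "dilution_factor": dilution_factor,
            "t_switch_min": t_switch,
        },
        noise_sd=noise_sd,
        seed=seed,
    )


def simulate_biphasic_inactivation(
    p: BiphasicParams,
    I: float,
    times,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> ActivityTimeCourse:
    """Simulate a residual-activity decay under two-conformer inactivation.

    Evaluates the two-exponential activity law (normalized to the total
    enzyme, so the noiseless trace starts at 1) and adds seeded Gaussian
    noise. A spec with ``E0_slow = 0`` yields the classical log-linear
    single-exponential decay.
    """
    times = np.asarray(times, dtype=float)
    activity = biphasic_activity(times, p, I) / p.E_tot
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        activity = activity + rng.normal(0.0, noise_sd, activity.shape)
    return ActivityTimeCourse(
        times=times,
        residual_activity=activity,
        metadata={"I_molar": I, "model": "two_conformer"},
        noise_sd=noise_sd,
        seed=seed,
    )
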