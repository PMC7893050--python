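"""Synthetic titration generator with known ground truth.

Raw potentiometric titration data for EPS samples are rarely published,
so every stage of the analysis pipeline is validated against simulated
curves whose ligand spectrum is known exactly. The simulator walks a
titrant schedule, and at each cumulative addition solves the proton
balance of the vessel for pH:

    f(pH) = (Cb - Ca + [H+] - Kw/[H+])
            - ( sum_i Ka_i * l_i / (Ka_i + [H+]) + s )  =  0

where l_i = L_Ti * m / V and s = S * m / V convert the per-gram spectrum
into solution concentrations at the current total volume V. f is strictly
decreasing in pH, so the root is unique; it is found by Brent bracketing
and polished with one Newton step to drive |f| to ~1e-15 M.

Measurement noise is optional and configurable: additive Gaussian on the
pH reading (glass-electrode repeatability, default sd 0.02) and
multiplicative Gaussian on each dispensed volume (default 0.5%). Dispensed
volumes are perturbed while the *nominal* cumulative volume is recorded,
as a real burette log would, so volume noise genuinely corrupts the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .chemistry import (
    ConfigError,
    DataError,
    TitrationCurve,
    TitrationPoint,
    VesselConfig,
)
from .inversion import LigandSpectrum

__all__ = [
    "TitrationSchedule",
    "NoiseModel",
    "SyntheticSpec",
    "solve_equilibrium_pH",
    "simulate_titration",
    "design_schedule",
    "preset_specs",
]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class TitrationSchedule:
    """One run's dosing plan.

    direction "forward" adds base in ``n_steps`` equal increments of
    ``step_volume`` (L); "reverse" adds acid the same way after a constant
    base ``predose_volume`` that first carries the vessel to high pH, so
    the acid leg sweeps back down through the analysis window.
    """

    direction: str
    step_volume: float
    n_steps: int
    predose_volume: float = 0.0

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "reverse"):
            raise ConfigError("direction must be 'forward' or 'reverse'")
        if not self.step_volume > 0:
            raise ConfigError("step_volume must be > 0")
        if self.n_steps < 2:
            raise ConfigError("need at least 2 titrant steps")
        if self.predose_volume < 0:
            raise ConfigError("predose_volume must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement noise: pH_sd additive, volume_sd multiplicative."""

    pH_sd: float = 0.02
    volume_sd: float = 0.005

    def __post_init__(self) -> None:
        if self.pH_sd < 0 or self.volume_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class SyntheticSpec:
    """Complete recipe for a reproducible synthetic titration data set."""

    truth: LigandSpectrum  # mol/g
    config: VesselConfig
    schedules: tuple[TitrationSchedule, ...]
    noise: NoiseModel = NoiseModel()
    n_replicates: int = 3
    seed: int = 0
    sample_id: str = "synthetic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "schedules", tuple(self.schedules))
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if not self.schedules:
            raise ConfigError("need at least one titrant schedule")


def _balance_terms(truth: LigandSpectrum, config: VesselConfig, total_volume: float):
    """Solution-phase site concentrations and constants for the balance."""
    scale = config.eps_mass / total_volume
    ka = 10.0 ** (-truth.pka)
    ell = truth.ligand_totals * scale
    s = truth.intercept * scale
    return ka, ell, s


def solve_equilibrium_pH(
    truth: LigandSpectrum,
    Ca: float,
    Cb: float,
    config: VesselConfig,
    *,
    total_volume: float | None = None,
) -> float:
    """pH at which the vessel's proton balance closes.

    Ca and Cb are the current (dilution-corrected) strong-acid and
    strong-base concentrations; ``total_volume`` (default: the initial
    volume) converts the per-gram truth spectrum into solution
    concentrations. Raises ConfigError if no root exists in (0, 14).
    """
    if Ca < 0 or Cb < 0:
        raise ConfigError("titrant concentrations must be >= 0")
    v = config.initial_volume if total_volume is None else total_volume
    ka, ell, s = _balance_terms(truth, config, v)
    kw = config.Kw
    gamma = config.proton_gamma

    def f(pH: float) -> float:
        h = 10.0 ** (-pH) / gamma
        return (Cb - Ca + h - kw / h) - (float(np.sum(ka * ell / (ka + h))) + s)

    lo, hi = 1e-3, 14.0 - 1e-3
    if f(lo) < 0 or f(hi) > 0:
        raise ConfigError("charge balance has no root in (0, 14); check the configuration")
    pH = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)
    # one Newton polish: f is smooth and strictly decreasing
    h = 10.0 ** (-pH) / gamma
    dfdpH = -_LN10 * (h + kw / h + float(np.sum(ka * ell * h / (ka + h) ** 2)))
    if dfdpH != 0:
        pH -= f(pH) / dfdpH
    return float(min(max(pH, 1e-3), 14.0 - 1e-3))


def _run_schedule(
    truth: LigandSpectrum,
    config: VesselConfig,
    schedule: TitrationSchedule,
    rng: np.random.Generator | None,
    noise: NoiseModel,
    sample_id: str,
    replicate_id: str,
) -> TitrationCurve:
    v0 = config.initial_volume
    noisy = rng is not None and (noise.pH_sd > 0 or noise.volume_sd > 0)
    nominal_steps = np.full(schedule.n_steps, schedule.step_volume)
    if noisy and noise.volume_sd > 0:
        actual_steps = nominal_steps * rng.normal(1.0, noise.volume_sd, schedule.n_steps)
        actual_steps = np.clip(actual_steps, 0.0, None)
    else:
        actual_steps = nominal_steps

    points = []
    # point 0: before the first addition (pre-dose already in the vessel)
    nominal_cum = np.concatenate([[0.0], np.cumsum(nominal_steps)])
    actual_cum = np.concatenate([[0.0], np.cumsum(actual_steps)])
    for v_nom, v_act in zip(nominal_cum, actual_cum):
        if schedule.direction == "forward":
            va_act, vb_act = 0.0, v_act
            va_nom, vb_nom = 0.0, v_nom
        else:
            va_act, vb_act = v_act, schedule.predose_volume
            va_nom, vb_nom = v_nom, schedule.predose_volume
        v_total = v0 + va_act + vb_act
        ca = config.acid_titrant_conc * va_act / v_total
        cb = config.base_titrant_conc * vb_act / v_total
        pH = solve_equilibrium_pH(truth, ca, cb, config, total_volume=v_total)
        if noisy and noise.pH_sd > 0:
            pH = float(np.clip(pH + rng.normal(0.0, noise.pH_sd), 1e-6, 14.0 - 1e-6))
        points.append(TitrationPoint(acid_volume_cum=va_nom, base_volume_cum=vb_nom, pH=pH))
    return TitrationCurve(
        sample_id=sample_id,
        replicate_id=replicate_id,
        direction=schedule.direction,
        config=config,
        points=tuple(points),
    )


def simulate_titration(spec: SyntheticSpec) -> list[TitrationCurve]:
    """All replicate curves of a synthetic spec, deterministically seeded.

    Each replicate gets its own random stream derived from
    (spec.seed, replicate index), so curve k is identical no matter how
    many replicates are requested. With zero noise all replicates coincide.
    """
    curves = []
    for r in range(spec.n_replicates):
        rng = np.random.default_rng([spec.seed, r])
        for schedule in spec.schedules:
            curves.append(
                _run_schedule(
                    spec.truth,
                    spec.config,
                    schedule,
                    rng,
                    spec.noise,
                    spec.sample_id,
                    f"rep{r + 1}",
                )
            )
    return curves


def design_schedule(
    truth: LigandSpectrum,
    config: VesselConfig,
    direction: str,
    *,
    n_steps: int = 80,
    pH_target_high: float = 10.5,
    pH_target_low: float = 3.5,
) -> TitrationSchedule:
    """Dosing plan whose noiseless run spans the pKa 4-10 analysis window.

    The base volume carrying the vessel to ``pH_target_high`` (and, for a
    reverse run, the subsequent acid volume returning it to
    ``pH_target_low``) is found by root-finding on the equilibrium model,
    then divided into ``n_steps`` equal increments.
    """

    def pH_at(va: float, vb: float) -> float:
        v_total = config.initial_volume + va + vb
        ca = config.acid_titrant_conc * va / v_total
        cb = config.base_titrant_conc * vb / v_total
        return solve_equilibrium_pH(truth, ca, cb, config, total_volume=v_total)

    # base volume reaching the high-pH end
    if pH_at(0.0, 0.0) >= pH_target_high:
        vb = 0.0  # already basic; only an acid-direction run makes sense
        if direction == "forward":
            raise ConfigError(
                "sample's natural pH is already above the high target; "
                "a base-direction run cannot span the analysis window"
            )
    else:
        vb_hi = 1e-6
        while pH_at(0.0, vb_hi) < pH_target_high:
            vb_hi *= 2.0
            if vb_hi > 1.0:
                raise ConfigError("cannot reach the target high pH with this configuration")
        vb = brentq(lambda v: pH_at(0.0, v) - pH_target_high, 0.0, vb_hi, xtol=1e-9)

    if direction == "forward":
        return TitrationSchedule("forward", step_volume=vb / n_steps, n_steps=n_steps)

    va_hi = 1e-6
    while pH_at(va_hi, vb) > pH_target_low:
        va_hi *= 2.0
        if va_hi > 1.0:
            raise ConfigError("cannot reach the target low pH with this configuration")
    va = brentq(lambda v: pH_at(v, vb) - pH_target_low, 0.0, va_hi, xtol=1e-9)
    return TitrationSchedule(
        "reverse", step_volume=va / n_steps, n_steps=n_steps, predose_volume=vb
    )


def _spectrum(sites: dict[float, float], intercept: float = 0.0) -> LigandSpectrum:
    """Spectrum from {pKa: L_T in mmol/g} given in mmol/g, stored in mol/g."""
    pka = np.array(sorted(sites))
    lt = np.array([sites[p] for p in sorted(sites)]) * 1e-3
    return LigandSpectrum(pka=pka, ligand_totals=lt, intercept=intercept * 1e-3)


def preset_specs(seed: int = 0) -> dict[str, SyntheticSpec]:
    """Named ground-truth scenarios with schedules spanning pKa 4-10.

    - "minimal": one carboxyl-range site (pKa 6.0, 0.10 mmol/g), zero
      noise, single replicate — the smallest end-to-end fixture.
    - "march-like": carboxyl-poor winter-mat composition (carboxyl 0.113,
      phosphoryl 0.149, amine 0.845 mmol/g), triplicate, default noise.
    - "october-like": carboxyl-rich dry-season composition (carboxyl class
      0.461 mmol/g split over two sites, phosphoryl 0.260, amine 0.721),
      triplicate, default noise.

    Ligand loads mirror the magnitudes measured on sabkha microbial-mat
    EPS; they are simulation parameters, not recoverable field values.
    """
    config = VesselConfig(eps_mass=0.050)
    specs: dict[str, SyntheticSpec] = {}

    truth_min = _spectrum({6.0: 0.10})
    specs["minimal"] = SyntheticSpec(
        truth=truth_min,
        config=config,
        schedules=(design_schedule(truth_min, config, "forward"),),
        noise=NoiseModel(pH_sd=0.0, volume_sd=0.0),
        n_replicates=1,
        seed=seed,
        sample_id="minimal",
    )

    truth_march = _spectrum({4.8: 0.113, 6.8: 0.149, 8.4: 0.845}, intercept=0.01)
    specs["march-like"] = SyntheticSpec(
        truth=truth_march,
        config=config,
        schedules=(
            design_schedule(truth_march, config, "forward"),
            design_schedule(truth_march, config, "reverse"),
        ),
        n_replicates=3,
        seed=seed,
        sample_id="march-like",
    )

    truth_oct = _spectrum({4.4: 0.200, 5.2: 0.261, 6.8: 0.260, 8.4: 0.721}, intercept=0.01)
    specs["october-like"] = SyntheticSpec(
        truth=truth_oct,
        config=config,
        schedules=(
            design_schedule(truth_oct, config, "forward"),
            design_schedule(truth_oct, config, "reverse"),
        ),
        n_replicates=3,
        seed=seed,
        sample_id="october-like",
    )
    return specs
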