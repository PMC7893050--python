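"""Titration data model and charge-excess computation.

A potentiometric titration of exopolymeric substances (EPS) records the
cumulative volumes of strong acid (HCl) and strong base (NaOH) added to a
small electrolyte-filled vessel together with the measured pH. The net
titratable charge of the EPS at each point — the *charge excess* — follows
from the proton balance of the solution:

    Q_j = (Cb_j - Ca_j + [H+]_j - [OH-]_j) * V_j / m

where Ca_j and Cb_j are the dilution-corrected titrant concentrations,
[H+]_j and [OH-]_j the proton and hydroxide concentrations inferred from
pH, V_j the total liquid volume at point j and m the EPS dry mass. Q is
expressed per gram of EPS (mol g^-1) so that fitted ligand concentrations
are directly comparable across samples of different mass.

Carbonate species are assumed absent (samples are degassed under N2 before
titration), so no carbonate terms appear in the balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VesselConfig",
    "TitrationPoint",
    "TitrationCurve",
    "ChargeExcessSeries",
    "proton_concentration",
    "hydroxide_concentration",
    "titrant_concentrations",
    "charge_excess",
    "davies_log10_gamma",
    "read_titration_csv",
    "write_titration_csv",
    "TITRATION_CSV_COLUMNS",
]

# Debye-Hueckel A coefficient at 25 C, kg^0.5 mol^-0.5
_DAVIES_A = 0.509

#: Canonical column order of the titration CSV dialect.
TITRATION_CSV_COLUMNS = [
    "sample_id",
    "replicate_id",
    "direction",
    "acid_volume_L",
    "base_volume_L",
    "pH",
]


class ConfigError(ValueError):
    """Invalid vessel or analysis configuration."""


class DataError(ValueError):
    """Malformed or inconsistent titration data."""


def davies_log10_gamma(ionic_strength: float, charge: int = 1) -> float:
    """log10 of the Davies activity coefficient for an ion of given charge.

    log10(gamma) = -A z^2 (sqrt(I)/(1+sqrt(I)) - 0.3 I), A = 0.509 at 25 C.
    """
    if ionic_strength < 0:
        raise ConfigError("ionic strength must be non-negative")
    s = math.sqrt(ionic_strength)
    return -_DAVIES_A * charge**2 * (s / (1.0 + s) - 0.3 * ionic_strength)


@dataclass(frozen=True)
class VesselConfig:
    """Experimental configuration of one titration vessel.

    Defaults follow the standard small-vessel protocol for EPS titrations:
    5 mL of 0.01 M KCl electrolyte, 0.1 M HCl and 0.01 M NaOH titrants,
    20-80 mg of purified EPS, 25 C.

    Parameters
    ----------
    eps_mass
        Dry mass of EPS in the vessel, grams. Required; typically 0.020-0.080.
    initial_volume
        Electrolyte volume before any titrant, litres.
    electrolyte_conc
        KCl concentration, mol/L; sets the ionic strength for the Davies model.
    acid_titrant_conc, base_titrant_conc
        HCl and NaOH titrant concentrations, mol/L.
    temperature
        Degrees Celsius (informational; pKw is set explicitly).
    pKw
        Negative log of the water ion product. 14.0 at 25 C.
    activity_model
        "ideal": [H+] = 10^(-pH).  "davies": the pH-meter activity is divided
        by a single-charge Davies coefficient at the electrolyte ionic strength.
    """

    eps_mass: float
    initial_volume: float = 5e-3
    electrolyte_conc: float = 0.01
    acid_titrant_conc: float = 0.1
    base_titrant_conc: float = 0.01
    temperature: float = 25.0
    pKw: float = 14.0
    activity_model: str = "ideal"

    def __post_init__(self) -> None:
        for name in ("eps_mass", "initial_volume", "electrolyte_conc",
                     "acid_titrant_conc", "base_titrant_conc"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be strictly positive")
        if not 13.0 <= self.pKw <= 15.0:
            raise ConfigError("pKw must lie in [13, 15]")
        if self.activity_model not in ("ideal", "davies"):
            raise ConfigError(
                f"unknown activity_model {self.activity_model!r}; "
                "expected 'ideal' or 'davies'"
            )

    @property
    def Kw(self) -> float:
        return 10.0 ** (-self.pKw)

    @property
    def proton_gamma(self) -> float:
        """Activity coefficient applied to [H+] (1.0 under the ideal model)."""
        if self.activity_model == "ideal":
            return 1.0
        return 10.0 ** davies_log10_gamma(self.electrolyte_conc)


@dataclass(frozen=True)
class TitrationPoint:
    """One titrant addition: cumulative volumes (L) and measured pH."""

    acid_volume_cum: float
    base_volume_cum: float
    pH: float

    def __post_init__(self) -> None:
        if self.acid_volume_cum < 0 or self.base_volume_cum < 0:
            raise DataError("cumulative titrant volumes must be >= 0")
        if not 0.0 < self.pH < 14.0:
            raise DataError(f"pH {self.pH} outside (0, 14)")


@dataclass(frozen=True)
class TitrationCurve:
    """One titration run (one direction, one replicate) of one EPS sample.

    Exactly one of the two cumulative titrant volumes varies along the
    curve (the active titrant) and it must be strictly increasing; the
    other stays constant (e.g. a base pre-dose before an acid-direction
    back-titration).
    """

    sample_id: str
    replicate_id: str
    direction: str
    config: VesselConfig
    points: tuple[TitrationPoint, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        if self.direction not in ("forward", "reverse"):
            raise DataError(f"direction must be 'forward' or 'reverse', got {self.direction!r}")
        if len(self.points) < 3:
            raise DataError("a titration curve needs at least 3 points")
        va = np.array([p.acid_volume_cum for p in self.points])
        vb = np.array([p.base_volume_cum for p in self.points])
        acid_varies = np.ptp(va) > 0
        base_varies = np.ptp(vb) > 0
        if acid_varies == base_varies:
            raise DataError(
                "exactly one of the acid/base cumulative volumes must vary along a curve"
            )
        active = va if acid_varies else vb
        if not np.all(np.diff(active) > 0):
            j = int(np.flatnonzero(np.diff(active) <= 0)[0]) + 1
            raise DataError(
                f"cumulative titrant volume must be strictly increasing (row {j})"
            )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def acid_volumes(self) -> np.ndarray:
        return np.array([p.acid_volume_cum for p in self.points])

    @property
    def base_volumes(self) -> np.ndarray:
        return np.array([p.base_volume_cum for p in self.points])

    @property
    def pH_values(self) -> np.ndarray:
        return np.array([p.pH for p in self.points])


@dataclass(frozen=True)
class ChargeExcessSeries:
    """Per-point charge excess of one titration run, mol per gram EPS."""

    sample_id: str
    replicate_id: str
    direction: str
    pH: np.ndarray
    Q: np.ndarray  # mol/g EPS

    def __post_init__(self) -> None:
        pH = np.asarray(self.pH, dtype=float)
        Q = np.asarray(self.Q, dtype=float)
        if pH.shape != Q.shape or pH.ndim != 1:
            raise DataError("pH and Q must be 1-D arrays of equal length")
        if not np.all(np.isfinite(Q)) or not np.all(np.isfinite(pH)):
            raise DataError("charge excess entries must be finite")
        object.__setattr__(self, "pH", pH)
        object.__setattr__(self, "Q", Q)

    def __len__(self) -> int:
        return len(self.pH)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "replicate_id": self.replicate_id,
                "direction": self.direction,
                "pH": self.pH,
                "Q_mol_per_g": self.Q,
            }
        )


def proton_concentration(pH: float, config: VesselConfig) -> float:
    """[H+] in mol/L from a pH reading.

    Under the ideal model pH is read as -log10[H+]. Under the Davies model
    the meter reading is an activity, so the concentration is the activity
    10^(-pH) divided by the single-charge Davies coefficient evaluated at
    the electrolyte ionic strength.
    """
    if not 0.0 < pH < 14.0:
        raise DataError(f"pH {pH} outside (0, 14)")
    return 10.0 ** (-pH) / config.proton_gamma


def hydroxide_concentration(pH: float, config: VesselConfig) -> float:
    """[OH-] in mol/L: Kw / [H+] with Kw = 10^(-pKw)."""
    return config.Kw / proton_concentration(pH, config)


def titrant_concentrations(point: TitrationPoint, config: VesselConfig) -> tuple[float, float]:
    """Dilution-corrected acid and base concentrations (Ca, Cb) at one point.

    Ca = C_HCl * Va / (V0 + Va + Vb) and analogously for Cb: the moles of
    titrant delivered so far divided by the current total volume.
    """
    v_total = config.initial_volume + point.acid_volume_cum + point.base_volume_cum
    ca = config.acid_titrant_conc * point.acid_volume_cum / v_total
    cb = config.base_titrant_conc * point.base_volume_cum / v_total
    return ca, cb


def charge_excess(curve: TitrationCurve) -> ChargeExcessSeries:
    """Charge excess Q_j (mol per gram EPS) at every point of a curve.

    Q_j = (Cb_j - Ca_j + [H+]_j - [OH-]_j) * V_total,j / eps_mass.

    The concentration-form proton balance is multiplied by the current
    total volume and divided by the EPS dry mass, so a subsequent ligand
    fit yields site concentrations directly in mol/g.
    """
    cfg = curve.config
    if cfg.eps_mass <= 0:  # defensive; VesselConfig already enforces it
        raise ConfigError("eps_mass must be positive")
    gamma = cfg.proton_gamma
    kw = cfg.Kw
    va = curve.acid_volumes
    vb = curve.base_volumes
    pH = curve.pH_values
    v_total = cfg.initial_volume + va + vb
    ca = cfg.acid_titrant_conc * va / v_total
    cb = cfg.base_titrant_conc * vb / v_total
    h = 10.0 ** (-pH) / gamma
    oh = kw / h
    q = (cb - ca + h - oh) * v_total / cfg.eps_mass
    return ChargeExcessSeries(
        sample_id=curve.sample_id,
        replicate_id=curve.replicate_id,
        direction=curve.direction,
        pH=pH,
        Q=q,
    )


# ---------------------------------------------------------------------------
# Titration CSV dialect
# ---------------------------------------------------------------------------

def write_titration_csv(curves: Iterable[TitrationCurve], path: str | Path) -> None:
    """Write curves in the titration CSV dialect.

    Header: sample_id,replicate_id,direction,acid_volume_L,base_volume_L,pH
    one row per point, UTF-8, '.' decimal separator, volumes and pH with
    6 significant digits (hash-stable across runs).
    """
    rows = []
    for c in curves:
        for p in c.points:
            rows.append(
                (
                    c.sample_id,
                    c.replicate_id,
                    c.direction,
                    f"{p.acid_volume_cum:.6g}",
                    f"{p.base_volume_cum:.6g}",
                    f"{p.pH:.6g}",
                )
            )
    df = pd.DataFrame(rows, columns=TITRATION_CSV_COLUMNS)
    df.to_csv(path, index=False)


def read_titration_csv(path: str | Path, config: VesselConfig) -> list[TitrationCurve]:
    """Read the titration CSV dialect into curves, one per
    (sample_id, replicate_id, direction) group, preserving row order.

    Raises DataError naming the offending CSV line on malformed rows.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "replicate_id": str, "direction": str})
    missing = [c for c in TITRATION_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"titration CSV missing columns: {missing}")
    if df.empty:
        raise DataError("titration CSV contains no data rows")
    curves: list[TitrationCurve] = []
    for (sample, rep, direction), g in df.groupby(
        ["sample_id", "replicate_id", "direction"], sort=False
    ):
        points = []
        for idx, row in g.iterrows():
            try:
                points.append(
                    TitrationPoint(
                        acid_volume_cum=float(row["acid_volume_L"]),
                        base_volume_cum=float(row["base_volume_L"]),
                        pH=float(row["pH"]),
                    )
                )
            except (DataError, ValueError) as exc:
                # +2: header line plus 1-based indexing
                raise DataError(f"invalid titration point at CSV line {idx + 2}: {exc}") from exc
        try:
            curves.append(
                TitrationCurve(
                    sample_id=str(sample),
                    replicate_id=str(rep),
                    direction=str(direction),
                    config=config,
                    points=tuple(points),
                )
            )
        except DataError as exc:
            raise DataError(
                f"invalid curve {sample}/{rep}/{direction}: {exc}"
            ) from exc
    return curves
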