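"""Discrete proton-binding spectrum inversion by linear programming.

The charge excess of an EPS sample is modelled as a mixture of independent
monoprotic ligands on a fixed pKa grid plus a constant offset:

    Q(pH) = sum_i Ka_i * L_Ti / (Ka_i + [H+])  +  S,    Ka_i = 10^(-pKa_i)

Each term is the deprotonated fraction of site class i times its total
concentration L_Ti (mol per gram EPS); S is the constant acid
neutralization capacity of the surface. Given observed (pH_j, Q_j) pairs
the spectrum is recovered by the classical linear programming method
(LPM): minimise the sum of absolute residuals subject to L_Ti >= 0, with S
free in sign, linearised with one slack variable per observation. The
candidate grid spans pKa 4-10 at 0.2-unit intervals by default (31 sites).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

from .chemistry import ChargeExcessSeries, ConfigError, DataError

__all__ = [
    "PKaGrid",
    "LigandSpectrum",
    "FitDiagnostics",
    "forward_model",
    "design_matrix",
    "resample_to_fit_grid",
    "fit_lpm",
]


@dataclass(frozen=True)
class PKaGrid:
    """Evenly spaced candidate pKa sites; also the pH evaluation grid.

    The default (4.0 to 10.0 step 0.2) gives 31 sites. The same grid is
    used both as the candidate pKa positions and, when resampling is
    enabled, as the pH values at which the charge excess is evaluated.
    """

    start: float = 4.0
    stop: float = 10.0
    step: float = 0.2

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ConfigError("grid start must be < stop")
        if not self.step > 0:
            raise ConfigError("grid step must be > 0")
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-9:
            raise ConfigError("(stop - start) must be an integral multiple of step")

    @property
    def n_sites(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def pka_values(self) -> np.ndarray:
        """Strictly increasing site pKa values (== evaluation pH values)."""
        return np.round(self.start + self.step * np.arange(self.n_sites), 10)


@dataclass(frozen=True)
class LigandSpectrum:
    """Fitted (or ground-truth) discrete site spectrum.

    pka
        Site pKa values, strictly increasing.
    ligand_totals
        Site concentrations L_Ti, same length as ``pka``, all >= 0.
        Units are whatever the charge excess carried (mol/g in the pipeline).
    intercept
        Constant offset S, free in sign, same units.
    """

    pka: np.ndarray
    ligand_totals: np.ndarray
    intercept: float = 0.0

    def __post_init__(self) -> None:
        pka = np.asarray(self.pka, dtype=float)
        lt = np.asarray(self.ligand_totals, dtype=float)
        if pka.shape != lt.shape or pka.ndim != 1:
            raise ConfigError("pka and ligand_totals must be 1-D arrays of equal length")
        if pka.size and np.any(np.diff(pka) <= 0):
            raise ConfigError("site pKa values must be strictly increasing")
        if np.any(lt < 0):
            raise ConfigError("ligand totals must be non-negative")
        object.__setattr__(self, "pka", pka)
        object.__setattr__(self, "ligand_totals", lt)

    @property
    def total_LT(self) -> float:
        """Sum of all site concentrations."""
        return float(self.ligand_totals.sum())

    def nonzero_sites(self) -> list[tuple[float, float]]:
        """(pKa, L_T) pairs with strictly positive concentration."""
        return [
            (float(p), float(l))
            for p, l in zip(self.pka, self.ligand_totals)
            if l > 0
        ]


@dataclass(frozen=True)
class FitDiagnostics:
    """Solver outcome and residual statistics of one LPM fit."""

    objective_value: float
    per_point_residuals: np.ndarray
    rmse: float
    n_active_sites: int
    solver_status: str  # optimal | infeasible | failed

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "per_point_residuals", np.asarray(self.per_point_residuals, dtype=float)
        )


def design_matrix(pka: np.ndarray, pH: np.ndarray) -> np.ndarray:
    """Deprotonated-fraction matrix A[j, i] = Ka_i / (Ka_i + [H+]_j)."""
    ka = 10.0 ** (-np.asarray(pka, dtype=float))
    h = 10.0 ** (-np.asarray(pH, dtype=float))
    return ka[None, :] / (ka[None, :] + h[:, None])


def forward_model(
    spectrum: LigandSpectrum, pH_values: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Predicted charge excess at the given pH values.

    Q_pred(pH) = sum_i Ka_i L_Ti / (Ka_i + 10^(-pH)) + S. Each site
    contributes L_Ti/2 at pH = pKa_i (half occupancy) and tends to 0 / L_Ti
    in the fully protonated / deprotonated limits.
    """
    pH = np.asarray(pH_values, dtype=float)
    if np.any(pH <= 0) or np.any(pH >= 14):
        raise DataError("pH values must lie in (0, 14)")
    a = design_matrix(spectrum.pka, pH)
    return a @ spectrum.ligand_totals + spectrum.intercept


def resample_to_fit_grid(series: ChargeExcessSeries, grid: PKaGrid) -> ChargeExcessSeries:
    """Linearly interpolate a charge-excess series onto the grid pH values.

    Points are sorted by pH and exact-duplicate pH readings are collapsed
    to their mean Q before interpolation. Grid pH values outside the
    measured span are omitted, never extrapolated.
    """
    order = np.argsort(series.pH, kind="stable")
    pH = series.pH[order]
    q = series.Q[order]
    uniq, inverse = np.unique(pH, return_inverse=True)
    if uniq.size < pH.size:
        q = np.bincount(inverse, weights=q) / np.bincount(inverse)
        pH = uniq
    if pH.size < 2:
        raise DataError("need at least 2 distinct pH points to resample")
    targets = grid.pka_values
    inside = (targets >= pH[0]) & (targets <= pH[-1])
    if not inside.any():
        raise DataError(
            f"measured pH span [{pH[0]:.2f}, {pH[-1]:.2f}] does not reach the "
            f"grid [{grid.start}, {grid.stop}]"
        )
    q_new = np.interp(targets[inside], pH, q)
    return ChargeExcessSeries(
        sample_id=series.sample_id,
        replicate_id=series.replicate_id,
        direction=series.direction,
        pH=targets[inside],
        Q=q_new,
    )


def _truncate_to_span(series: ChargeExcessSeries, grid: PKaGrid) -> ChargeExcessSeries:
    """Keep raw points whose pH lies within [grid.start, grid.stop], sorted."""
    order = np.argsort(series.pH, kind="stable")
    pH = series.pH[order]
    q = series.Q[order]
    keep = (pH >= grid.start) & (pH <= grid.stop)
    return ChargeExcessSeries(
        sample_id=series.sample_id,
        replicate_id=series.replicate_id,
        direction=series.direction,
        pH=pH[keep],
        Q=q[keep],
    )


def fit_lpm(
    series: ChargeExcessSeries,
    grid: PKaGrid | None = None,
    *,
    resample: bool = True,
    report_threshold: float = 1e-6,
    tol: float = 1e-9,
) -> tuple[LigandSpectrum, FitDiagnostics]:
    """Fit the discrete-site model to a charge-excess series by LPM.

    Minimises sum_j |Q_obs,j - Q_pred,j| over L_Ti >= 0 and unconstrained
    S, cast as a linear program with per-point slack variables t_j:

        min sum t_j   s.t.  -t_j <= Q_j - (A L + S) <= t_j,  L >= 0, t >= 0

    solved with the deterministic HiGHS simplex/IPM via scipy.

    Parameters
    ----------
    series
        Observed charge excess (any consistent amount-per-mass unit).
    grid
        Candidate pKa grid; default PKaGrid() (4-10 step 0.2).
    resample
        If True (default), fit on Q linearly interpolated at the grid pH
        values; if False, fit on the raw measured points truncated to the
        grid span (no interpolation error, appropriate for exact-recovery
        work and dense noise-free data).
    report_threshold
        Sites with fitted L_Ti below this (same units as Q) are reported
        as exactly zero, suppressing LP vertex noise.
    tol
        Solver feasibility/optimality tolerance.

    Returns
    -------
    (LigandSpectrum, FitDiagnostics); on solver failure the spectrum is
    all-zero and diagnostics.solver_status reports it.
    """
    if grid is None:
        grid = PKaGrid()
    work = resample_to_fit_grid(series, grid) if resample else _truncate_to_span(series, grid)
    if len(work) < 2:
        raise DataError("need at least 2 usable points within the fit grid")

    pka = grid.pka_values
    a = design_matrix(pka, work.pH)
    if np.any(np.all(a == 0.0, axis=0)):
        raise ConfigError("degenerate grid: a candidate site has an all-zero design column")
    q = work.Q
    m, n = a.shape

    # variables: [L (n), S+ , S-, t (m)]
    c = np.concatenate([np.zeros(n + 2), np.ones(m)])
    eye = np.eye(m)
    ones = np.ones((m, 1))
    # A L + S - t <= Q   and   -(A L + S) - t <= -Q
    a_ub = np.block([[a, ones, -ones, -eye], [-a, -ones, ones, -eye]])
    b_ub = np.concatenate([q, -q])
    res = linprog(
        c,
        A_ub=a_ub,
        b_ub=b_ub,
        bounds=[(0, None)] * (n + 2 + m),
        method="highs",
        options={"primal_feasibility_tolerance": tol, "dual_feasibility_tolerance": tol},
    )
    if not res.success:
        status = "infeasible" if res.status == 2 else "failed"
        diag = FitDiagnostics(
            objective_value=float("nan"),
            per_point_residuals=np.full(m, np.nan),
            rmse=float("nan"),
            n_active_sites=0,
            solver_status=status,
        )
        return LigandSpectrum(pka=pka, ligand_totals=np.zeros(n)), diag

    lt = res.x[:n].copy()
    s = float(res.x[n] - res.x[n + 1])
    lt[lt < report_threshold] = 0.0
    spectrum = LigandSpectrum(pka=pka, ligand_totals=lt, intercept=s)
    residuals = q - (a @ lt + s)
    diag = FitDiagnostics(
        objective_value=float(np.abs(residuals).sum()),
        per_point_residuals=residuals,
        rmse=float(np.sqrt(np.mean(residuals**2))),
        n_active_sites=int(np.count_nonzero(lt)),
        solver_status="optimal",
    )
    return spectrum, diag
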