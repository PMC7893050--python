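"""Agreement diagnostics for titration quality control.

Before a spectrum fit is trusted, charge-excess curves are compared:
forward vs reverse runs of the same sample (hysteresis check), replicate
vs replicate, and measured vs modelled (the fitted spectrum's prediction).
The statistics are the RMSE and maximum absolute difference of Q over a
shared pH grid, with a configurable pass threshold expressed as a fraction
of the observed Q range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemistry import ChargeExcessSeries, DataError
from .inversion import LigandSpectrum, PKaGrid, forward_model, resample_to_fit_grid

__all__ = ["AgreementReport", "compare_series", "measured_vs_modeled"]


@dataclass(frozen=True)
class AgreementReport:
    """RMSE / max-abs-difference agreement between two Q curves."""

    rmse: float
    max_abs_diff: float
    n_compared: int
    overlap_pH_span: tuple[float, float]
    pass_flag: bool

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "max_abs_diff": self.max_abs_diff,
            "n_compared": self.n_compared,
            "overlap_pH_span": list(self.overlap_pH_span),
            "pass": self.pass_flag,
        }


def _resample(series: ChargeExcessSeries, grid: PKaGrid) -> tuple[np.ndarray, np.ndarray]:
    r = resample_to_fit_grid(series, grid)
    return r.pH, r.Q


def compare_series(
    a: ChargeExcessSeries,
    b: ChargeExcessSeries,
    grid: PKaGrid | None = None,
    *,
    rel_threshold: float = 0.05,
) -> AgreementReport:
    """Agreement of two charge-excess curves on a shared pH grid.

    Both series are resampled to the grid pH values lying within both
    measured spans; RMSE and max |difference| of Q are computed over those
    shared points. Symmetric in its two arguments. pass_flag is true when
    the RMSE is at most ``rel_threshold`` times the pooled Q range.
    """
    if grid is None:
        grid = PKaGrid()
    pa, qa = _resample(a, grid)
    pb, qb = _resample(b, grid)
    shared, ia, ib = np.intersect1d(pa, pb, return_indices=True)
    if shared.size == 0:
        raise DataError("series have no overlapping pH span on the comparison grid")
    diff = qa[ia] - qb[ib]
    rmse = float(np.sqrt(np.mean(diff**2)))
    max_abs = float(np.max(np.abs(diff)))
    pooled = np.concatenate([qa[ia], qb[ib]])
    q_range = float(np.ptp(pooled))
    passed = rmse <= rel_threshold * q_range if q_range > 0 else rmse == 0.0
    return AgreementReport(
        rmse=rmse,
        max_abs_diff=max_abs,
        n_compared=int(shared.size),
        overlap_pH_span=(float(shared[0]), float(shared[-1])),
        pass_flag=bool(passed),
    )


def measured_vs_modeled(
    series: ChargeExcessSeries,
    spectrum: LigandSpectrum,
    *,
    rel_threshold: float = 0.05,
) -> AgreementReport:
    """Agreement between observed Q and the fitted spectrum's prediction.

    The forward model is evaluated at the series' own pH values (no
    resampling). pass_flag is true when RMSE <= rel_threshold * range(Q_obs).
    """
    if len(series) == 0:
        raise DataError("empty charge-excess series")
    pred = forward_model(spectrum, series.pH)
    diff = series.Q - pred
    rmse = float(np.sqrt(np.mean(diff**2)))
    max_abs = float(np.max(np.abs(diff)))
    q_range = float(np.ptp(series.Q))
    passed = rmse <= rel_threshold * q_range if q_range > 0 else rmse <= rel_threshold
    return AgreementReport(
        rmse=rmse,
        max_abs_diff=max_abs,
        n_compared=len(series),
        overlap_pH_span=(float(series.pH.min()), float(series.pH.max())),
        pass_flag=bool(passed),
    )
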