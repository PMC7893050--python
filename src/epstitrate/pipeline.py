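"""End-to-end wiring: curves -> charge excess -> LPM fit -> classes -> QC.

The unit conventions are fixed here: charge excess and fitted spectra are
carried in mol per gram EPS; functional-group totals are converted to
mMol/g for aggregation and reporting, matching how such results are
tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .chemistry import ChargeExcessSeries, TitrationCurve, charge_excess
from .groups import (
    DEFAULT_SCHEME,
    FunctionalGroupScheme,
    FunctionalGroupSummary,
    aggregate_replicates,
    bin_functional_groups,
)
from .inversion import FitDiagnostics, LigandSpectrum, PKaGrid, fit_lpm
from .qc import AgreementReport, compare_series, measured_vs_modeled

__all__ = ["CurveFit", "fit_curves", "summarize_samples", "qc_report"]

MOL_TO_MMOL = 1e3


@dataclass(frozen=True)
class CurveFit:
    """One curve's full analysis: data, spectrum, diagnostics, model QC."""

    curve: TitrationCurve
    series: ChargeExcessSeries
    spectrum: LigandSpectrum
    diagnostics: FitDiagnostics
    model_agreement: AgreementReport

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.curve.sample_id, self.curve.replicate_id, self.curve.direction)


def fit_curves(
    curves: Sequence[TitrationCurve],
    grid: PKaGrid | None = None,
    *,
    resample: bool = True,
    report_threshold: float = 1e-6,
    qc_rel_threshold: float = 0.05,
) -> list[CurveFit]:
    """Charge excess + LPM fit + measured-vs-modelled QC for every curve."""
    grid = grid or PKaGrid()
    out = []
    for curve in curves:
        series = charge_excess(curve)
        spectrum, diag = fit_lpm(
            series, grid, resample=resample, report_threshold=report_threshold
        )
        agreement = measured_vs_modeled(series, spectrum, rel_threshold=qc_rel_threshold)
        out.append(
            CurveFit(
                curve=curve,
                series=series,
                spectrum=spectrum,
                diagnostics=diag,
                model_agreement=agreement,
            )
        )
    return out


def summarize_samples(
    fits: Sequence[CurveFit] | Mapping[tuple[str, str, str], LigandSpectrum],
    scheme: FunctionalGroupScheme = DEFAULT_SCHEME,
) -> dict[str, FunctionalGroupSummary]:
    """Per-sample replicate summaries in mMol/g EPS.

    Every fitted curve (each replicate x direction) counts as one
    replicate measurement of its sample; class totals are binned per
    curve, converted to mMol/g, then averaged.
    """
    if isinstance(fits, Mapping):
        items = [(k, v) for k, v in fits.items()]
    else:
        items = [(f.key, f.spectrum) for f in fits]
    by_sample: dict[str, list[dict[str, float]]] = {}
    for (sample, _rep, _direction), spectrum in items:
        totals = bin_functional_groups(spectrum, scheme)
        by_sample.setdefault(sample, []).append(
            {k: v * MOL_TO_MMOL for k, v in totals.items()}
        )
    return {s: aggregate_replicates(reps) for s, reps in by_sample.items()}


def qc_report(
    fits: Sequence[CurveFit],
    grid: PKaGrid | None = None,
    *,
    rel_threshold: float = 0.05,
) -> dict:
    """Forward-vs-reverse, replicate-vs-replicate and model agreement.

    Returns a JSON-ready dict keyed by sample, with one entry per
    comparison pair and per fitted curve.
    """
    grid = grid or PKaGrid()
    by_sample: dict[str, list[CurveFit]] = {}
    for f in fits:
        by_sample.setdefault(f.curve.sample_id, []).append(f)

    report: dict = {}
    for sample, group in by_sample.items():
        entry: dict = {
            "forward_vs_reverse": {},
            "replicate_pairs": {},
            "measured_vs_modeled": {},
        }
        by_rep: dict[str, dict[str, CurveFit]] = {}
        for f in group:
            by_rep.setdefault(f.curve.replicate_id, {})[f.curve.direction] = f
            entry["measured_vs_modeled"][
                f"{f.curve.replicate_id}/{f.curve.direction}"
            ] = f.model_agreement.to_dict()
        for rep, directions in by_rep.items():
            if "forward" in directions and "reverse" in directions:
                rpt = compare_series(
                    directions["forward"].series,
                    directions["reverse"].series,
                    grid,
                    rel_threshold=rel_threshold,
                )
                entry["forward_vs_reverse"][rep] = rpt.to_dict()
        reps = sorted(by_rep)
        for i, ra in enumerate(reps):
            for rb in reps[i + 1 :]:
                for direction in ("forward", "reverse"):
                    fa = by_rep[ra].get(direction)
                    fb = by_rep[rb].get(direction)
                    if fa is not None and fb is not None:
                        rpt = compare_series(
                            fa.series, fb.series, grid, rel_threshold=rel_threshold
                        )
                        entry["replicate_pairs"][f"{ra}-vs-{rb}/{direction}"] = rpt.to_dict()
        report[sample] = entry
    return report
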