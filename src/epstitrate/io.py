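"""File formats: spectrum TSV, truth/diagnostics/QC JSON, YAML config.

All numeric output is serialized with 6 significant digits so repeated
runs with the same seed produce byte-identical files. Fitted spectra and
ground truths are stored in mMol per gram EPS (the reporting unit); the
in-memory pipeline works in mol/g and converts at this boundary.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .chemistry import ConfigError, DataError, VesselConfig
from .groups import DEFAULT_SCHEME, FunctionalGroupScheme, GroupClass
from .inversion import FitDiagnostics, LigandSpectrum, PKaGrid
from .simulate import NoiseModel, SyntheticSpec, TitrationSchedule, design_schedule

__all__ = [
    "write_spectrum_tsv",
    "read_spectrum_tsv",
    "write_truth_json",
    "read_truth_json",
    "diagnostics_to_dict",
    "write_json",
    "PipelineConfig",
    "load_pipeline_config",
    "spec_from_dict",
    "load_synthetic_spec",
]

MOL_TO_MMOL = 1e3


def _fmt(x: float) -> float:
    """Round to 6 significant digits for hash-stable serialization."""
    return float(f"{x:.6g}")


def write_spectrum_tsv(spectrum: LigandSpectrum, path: str | Path) -> None:
    """Spectrum TSV: columns pKa, L_T_mmol_per_g (+ one intercept row `S`)."""
    rows = [(f"{p:.6g}", f"{l * MOL_TO_MMOL:.6g}") for p, l in zip(spectrum.pka, spectrum.ligand_totals)]
    rows.append(("S", f"{spectrum.intercept * MOL_TO_MMOL:.6g}"))
    pd.DataFrame(rows, columns=["pKa", "L_T_mmol_per_g"]).to_csv(path, sep="\t", index=False)


def read_spectrum_tsv(path: str | Path) -> LigandSpectrum:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["pKa", "L_T_mmol_per_g"]:
        raise DataError(f"{path}: not a spectrum TSV")
    s_rows = df["pKa"] == "S"
    intercept = float(df.loc[s_rows, "L_T_mmol_per_g"].iloc[0]) / MOL_TO_MMOL if s_rows.any() else 0.0
    body = df.loc[~s_rows]
    return LigandSpectrum(
        pka=body["pKa"].astype(float).to_numpy(),
        ligand_totals=body["L_T_mmol_per_g"].astype(float).to_numpy() / MOL_TO_MMOL,
        intercept=intercept,
    )


def write_truth_json(spec: SyntheticSpec, path: str | Path) -> None:
    """Ground-truth sidecar for a simulated data set (mMol/g units)."""
    payload = {
        "sample_id": spec.sample_id,
        "seed": spec.seed,
        "n_replicates": spec.n_replicates,
        "sites": [
            {"pKa": _fmt(p), "L_T_mmol_per_g": _fmt(l * MOL_TO_MMOL)}
            for p, l in zip(spec.truth.pka, spec.truth.ligand_totals)
        ],
        "S_mmol_per_g": _fmt(spec.truth.intercept * MOL_TO_MMOL),
        "noise": {"pH_sd": spec.noise.pH_sd, "volume_sd": spec.noise.volume_sd},
        "vessel": asdict(spec.config),
    }
    write_json(payload, path)


def read_truth_json(path: str | Path) -> LigandSpectrum:
    with open(path) as fh:
        payload = json.load(fh)
    return LigandSpectrum(
        pka=np.array([s["pKa"] for s in payload["sites"]], dtype=float),
        ligand_totals=np.array(
            [s["L_T_mmol_per_g"] for s in payload["sites"]], dtype=float
        ) / MOL_TO_MMOL,
        intercept=float(payload["S_mmol_per_g"]) / MOL_TO_MMOL,
    )


def diagnostics_to_dict(diag: FitDiagnostics) -> dict:
    return {
        "objective_mol_per_g": _fmt(diag.objective_value),
        "rmse_mol_per_g": _fmt(diag.rmse),
        "n_active_sites": diag.n_active_sites,
        "solver_status": diag.solver_status,
    }


def write_json(payload: Mapping[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
        fh.write("\n")


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

class PipelineConfig:
    """Analysis configuration: vessel, fit grid, class scheme, options.

    Built from a YAML mapping with optional keys ``vessel``, ``grid``,
    ``scheme``, ``fit`` and ``qc``; anything omitted takes the package
    defaults. ``vessel.eps_mass`` (grams) is the only required field.
    """

    def __init__(
        self,
        vessel: VesselConfig,
        grid: PKaGrid | None = None,
        scheme: FunctionalGroupScheme | None = None,
        resample: bool = True,
        report_threshold: float = 1e-6,
        qc_rel_threshold: float = 0.05,
    ):
        self.vessel = vessel
        self.grid = grid or PKaGrid()
        self.scheme = scheme or DEFAULT_SCHEME
        self.resample = resample
        self.report_threshold = report_threshold
        self.qc_rel_threshold = qc_rel_threshold


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "vessel" not in raw or "eps_mass" not in raw["vessel"]:
        raise ConfigError("config must provide vessel.eps_mass (grams)")
    vessel = VesselConfig(**raw["vessel"])
    grid = PKaGrid(**raw.get("grid", {}))
    if "scheme" in raw:
        scheme = FunctionalGroupScheme(
            classes=tuple(GroupClass(c["name"], c["lo"], c["hi"]) for c in raw["scheme"])
        )
    else:
        scheme = DEFAULT_SCHEME
    fit = raw.get("fit", {})
    qc = raw.get("qc", {})
    return PipelineConfig(
        vessel=vessel,
        grid=grid,
        scheme=scheme,
        resample=bool(fit.get("resample", True)),
        report_threshold=float(fit.get("report_threshold", 1e-6)),
        qc_rel_threshold=float(qc.get("rel_threshold", 0.05)),
    )


def spec_from_dict(raw: Mapping[str, Any], seed: int | None = None) -> SyntheticSpec:
    """SyntheticSpec from a YAML mapping.

    Expected keys: ``truth`` ({sites: [{pKa, L_T_mmol_per_g}], S_mmol_per_g}),
    ``vessel`` (VesselConfig fields), optional ``schedules`` (list of
    {direction, step_volume_L, n_steps, predose_volume_L}; designed
    automatically from the truth when omitted), ``noise`` ({pH_sd,
    volume_sd}), ``n_replicates``, ``sample_id``, ``seed``.
    """
    truth_raw = raw["truth"]
    sites = sorted(truth_raw.get("sites", []), key=lambda s: s["pKa"])
    truth = LigandSpectrum(
        pka=np.array([s["pKa"] for s in sites], dtype=float),
        ligand_totals=np.array([s["L_T_mmol_per_g"] for s in sites], dtype=float) / MOL_TO_MMOL,
        intercept=float(truth_raw.get("S_mmol_per_g", 0.0)) / MOL_TO_MMOL,
    )
    vessel = VesselConfig(**raw["vessel"])
    if "schedules" in raw:
        schedules = tuple(
            TitrationSchedule(
                direction=s["direction"],
                step_volume=float(s["step_volume_L"]),
                n_steps=int(s["n_steps"]),
                predose_volume=float(s.get("predose_volume_L", 0.0)),
            )
            for s in raw["schedules"]
        )
    else:
        schedules = (
            design_schedule(truth, vessel, "forward"),
            design_schedule(truth, vessel, "reverse"),
        )
    noise = NoiseModel(**raw.get("noise", {}))
    return SyntheticSpec(
        truth=truth,
        config=vessel,
        schedules=schedules,
        noise=noise,
        n_replicates=int(raw.get("n_replicates", 3)),
        seed=int(seed if seed is not None else raw.get("seed", 0)),
        sample_id=str(raw.get("sample_id", "synthetic")),
    )


def load_synthetic_spec(path: str | Path, seed: int | None = None) -> SyntheticSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: not a synthetic-spec YAML mapping")
    return spec_from_dict(raw, seed=seed)
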