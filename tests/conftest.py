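import numpy as np
import pytest

from epstitrate import (
    LigandSpectrum,
    NoiseModel,
    SyntheticSpec,
    VesselConfig,
    design_schedule,
)


@pytest.fixture
def vessel() -> VesselConfig:
    """Standard 5 mL / 0.01 M KCl vessel with 50 mg EPS."""
    return VesselConfig(eps_mass=0.050)


@pytest.fixture
def single_site() -> LigandSpectrum:
    """One pKa-6 site at 0.10 mmol/g (stored in mol/g), S = 0."""
    return LigandSpectrum(pka=np.array([6.0]), ligand_totals=np.array([1e-4]))


def make_spectrum(sites: dict[float, float], intercept: float = 0.0) -> LigandSpectrum:
    """Spectrum from {pKa: L_T} (mol/g)."""
    pka = np.array(sorted(sites))
    return LigandSpectrum(
        pka=pka,
        ligand_totals=np.array([sites[p] for p in sorted(sites)]),
        intercept=intercept,
    )


def noiseless_spec(
    truth: LigandSpectrum,
    vessel: VesselConfig,
    directions=("forward", "reverse"),
    n_steps: int = 80,
    sample_id: str = "test",
) -> SyntheticSpec:
    """Noise-free single-replicate spec with auto-designed schedules."""
    schedules = tuple(design_schedule(truth, vessel, d, n_steps=n_steps) for d in directions)
    return SyntheticSpec(
        truth=truth,
        config=vessel,
        schedules=schedules,
        noise=NoiseModel(pH_sd=0.0, volume_sd=0.0),
        n_replicates=1,
        seed=0,
        sample_id=sample_id,
    )
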