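import numpy as np
import pytest

import dissosim as ds


@pytest.fixture
def dsa():
    """Weakly basic, highly permeable drug: pKa 7.6, S0 0.15 ug/mL."""
    return ds.IonizableCompound(
        name="DS-A",
        ionization="monoprotic_base",
        pKa=7.6,
        intrinsic_solubility_mg_ml=0.15e-3,
        true_density_g_ml=1.3,
        diffusion_coefficient_cm2_s=8e-6,
        molecular_weight_g_mol=450.0,
    )


@pytest.fixture
def dsa_tosylate(dsa):
    return ds.SaltForm(
        parent=dsa,
        counterion_pKa=-1.0,
        counterion_stoichiometry=1.0,
        salt_solubility_mg_ml=1.8,
        conversion_lag_min=3.0,
    )


@pytest.fixture
def acetate_ph45():
    return ds.Medium(
        name="pH45-acetate-50mM", volume_ml=900.0, bulk_pH=4.5,
        buffer_species=[(4.76, 50.0)],
    )


@pytest.fixture
def phosphate_ph65():
    return ds.Medium(
        name="pH65-phosphate-50mM", volume_ml=900.0, bulk_pH=6.5,
        buffer_species=[(7.2, 50.0)],
    )


@pytest.fixture
def dsa_population(dsa):
    psd = ds.gen_psd(median_diameter_um=30.0, geometric_sd=1.8,
                     n_points=200, seed=1)
    return ds.population_from_psd(psd, weighting="volume", n_bins=20,
                                  dose_mg=12.0, density_g_ml=dsa.true_density_g_ml)


@pytest.fixture
def t_grid_60():
    return np.arange(0.0, 61.0, 1.0)
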