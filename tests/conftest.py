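import numpy as np
import pytest

from lynchmave.calibration import ControlVariant, compute_oddspath
from lynchmave.simulate import SimulationConfig, make_tier_catalog
from lynchmave.variants import ClinicalClass, FunctionTier


@pytest.fixture
def rng():
    return np.random.default_rng(20231207)


@pytest.fixture
def small_config():
    """Desk-scale generator configuration for fast end-to-end runs."""
    return SimulationConfig(
        seed=11,
        n_variants=1500,
        n_carriers=3000,
        n_paired=300,
        frac_deleterious=0.15,
        frac_sole_msh2_missense=0.3,
    )


def build_control_set(rng, n_path=22, n_benign=26, n_path_intermediate=1):
    """Score-concordant control set with a configurable intermediate count."""
    path_abnormal = make_tier_catalog(
        {FunctionTier.DELETERIOUS_PROTEIN: n_path - n_path_intermediate},
        rng, classification=ClinicalClass.P, start=0,
    )
    path_intermediate = make_tier_catalog(
        {FunctionTier.INTERMEDIATE: n_path_intermediate},
        rng, classification=ClinicalClass.LP, start=1000,
    )
    benign = make_tier_catalog(
        {FunctionTier.NEUTRAL: n_benign},
        rng, classification=ClinicalClass.B, start=2000,
    )
    return [
        ControlVariant(v, classification_uses_functional_evidence=False)
        for v in path_abnormal + path_intermediate + benign
    ]


@pytest.fixture
def strong_calibration(rng):
    """An OddsPath calibration establishing strong evidence in both directions."""
    return compute_oddspath(build_control_set(rng))
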