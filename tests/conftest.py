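import numpy as np
import pytest

from bnct_fluence import (
    FluxMeasurement,
    FluxModel,
    MeasurementSeries,
    evaluate_flux,
    prescribe_fluence,
)

PLANNING_FLUX = 1.20e-15  # Bq/mA/atom
TENTATIVE_CHARGE = 43.2e3  # mC (12 mA x 1 h)


@pytest.fixture
def clinical_plan():
    """Planning parameters of the worked clinical example."""
    return prescribe_fluence(PLANNING_FLUX, TENTATIVE_CHARGE)


@pytest.fixture
def decaying_model():
    """A representative degrading-target model."""
    return FluxModel(a=2.0e-16, b=1.0e-5, c=1.0e-15)


def make_series(model, charges, target_id="t", rel_uncertainty=None, noise=None):
    """Measurement series lying on (or perturbed from) a model curve."""
    charges = np.asarray(charges, dtype=float)
    flux = evaluate_flux(model, charges)
    flux = np.atleast_1d(np.asarray(flux))
    if noise is not None:
        flux = flux * (1.0 + np.asarray(noise))
    points = [
        FluxMeasurement(float(m), float(f), rel_uncertainty=rel_uncertainty)
        for m, f in zip(charges, flux)
    ]
    return MeasurementSeries(target_id, points)
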