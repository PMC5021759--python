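import numpy as np
import pandas as pd
import pytest

from arborsim.synth.phantom import PhantomSpec, generate_neuron_phantom
from arborsim.synth.population import (
    ImagingPopulationSpec,
    PopulationSpec,
    generate_population,
    sample_phantom_spec,
)

VS = (1.0, 0.25, 0.25)


def straight_branch(center, r0, r1, direction=(0.0, 0.0, 1.0), step=0.25):
    """Radial polyline from radius r0 to r1 along a unit direction."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    rs = np.arange(r0, r1 + 1e-9, step)
    return np.asarray(center)[None, :] + rs[:, None] * d[None, :]


@pytest.fixture(scope="session")
def simple_phantom():
    """Soma + one straight dendrite spanning annuli 1-4, two punctae."""
    center = np.array([5.0, 40.0, 40.0])
    branch = straight_branch(center, 5.0, 31.2)
    puncta = pd.DataFrame(
        [
            {"z_um": 5.0, "y_um": 40.0, "x_um": 40.0 + 15.0, "channel": "VGlut1",
             "afu": 1.0, "on_neuron": True},
            {"z_um": 5.0, "y_um": 60.0, "x_um": 15.0, "channel": "VGlut1",
             "afu": 1.0, "on_neuron": False},
        ]
    )
    spec = PhantomSpec(
        shape=(11, 320, 320),
        soma_center_um=center,
        branches=[branch],
        puncta=puncta,
        noise_sd=5.0,
        seed=7,
    )
    vols, truth = generate_neuron_phantom(spec)
    return spec, vols, truth


@pytest.fixture(scope="session")
def rendered_phantom():
    """One sampled imaging phantom with full branch tree and punctae."""
    rng = np.random.default_rng(12)
    pop = ImagingPopulationSpec()
    spec = sample_phantom_spec(rng, pop, treated=False, seed=5)
    vols, truth = generate_neuron_phantom(spec)
    return spec, vols, truth


@pytest.fixture(scope="session")
def profile_pair():
    """Small direct-profile populations with the default contrasts."""
    return generate_population(PopulationSpec(n_per_group=8, seed=3))
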