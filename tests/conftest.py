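"""Shared fixtures: reference loadings and FE solutions reused across tests.

The contraction solves are session-scoped because the best-fit sweep is the
most expensive computation in the suite; every test that needs the deformed
construct shares one solution per mesh resolution.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fiberalign import fem, pca_alignment, preprocess, synthetic

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference_loading():
    """Master loading derived from the default synthetic aligned-muscle set."""
    ref = synthetic.gen_reference_set(
        synthetic.SpectrumModel(bands=synthetic._default_bands(0.8),
                                phase_deg=0.0, noise_sd=8.0, seed=6))
    cfg = preprocess.PreprocessConfig(average_replicates=False)
    return pca_alignment.derive_loading(preprocess.preprocess(ref, cfg))


@pytest.fixture(scope="session")
def mesh_100um():
    return fem.build_mesh(fem.Geometry(element_size_um=100.0))


@pytest.fixture(scope="session")
def mesh_200um():
    return fem.build_mesh(fem.Geometry(element_size_um=200.0))


@pytest.fixture(scope="session")
def bestfit_100um(mesh_100um):
    """Best-fit shrinkage sweep on the 100 um production mesh."""
    sweep = np.round(np.arange(0.0, 0.7001, 0.05), 10)
    return fem.fit_shrinkage_strain(0.60, mesh_100um, fem.Material(),
                                    sweep=sweep)


@pytest.fixture(scope="session")
def bestfit_200um(mesh_200um):
    """Same sweep on the coarse mesh, for convergence and monotonicity."""
    sweep = np.round(np.arange(0.0, 0.7001, 0.05), 10)
    return fem.fit_shrinkage_strain(0.60, mesh_200um, fem.Material(),
                                    sweep=sweep)
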