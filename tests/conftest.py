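import numpy as np
import pytest
from hypothesis import settings

import facetract as ft

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle10() -> ft.PairedSequenceBundle:
    """Small paired bundle with two shared latent channels."""
    return ft.make_bundle(n_frames=10, k_shared=2, noise_sd=2.0, seed=3)


@pytest.fixture(scope="session")
def refsel10(bundle10):
    sel_v = ft.select_reference(bundle10.seq_a, n_iterations=3, seed=10)
    sel_m = ft.select_reference(bundle10.seq_b, n_iterations=3, seed=11)
    return sel_v, sel_m


@pytest.fixture(scope="session")
def hybrid10(bundle10, refsel10) -> ft.HybridArray:
    sel_v, sel_m = refsel10
    return ft.build_hybrid(
        (list(bundle10.seq_a), sel_v.fields),
        (list(bundle10.seq_b), sel_m.fields),
    )


@pytest.fixture(scope="session")
def model10(hybrid10) -> ft.PCAModel:
    return ft.fit_pca(hybrid10)


@pytest.fixture(scope="session")
def matched_sequences10(bundle10, refsel10):
    """(video, mr) (frames, fields) tuples, already frame-matched."""
    sel_v, sel_m = refsel10
    return (
        (list(bundle10.seq_a), sel_v.fields),
        (list(bundle10.seq_b), sel_m.fields),
    )


@pytest.fixture()
def random_hybrid() -> ft.HybridArray:
    """Small random two-modality hybrid (no images needed)."""
    rng = np.random.default_rng(7)
    frames_a = [rng.uniform(0, 255, (4, 5, 3)) for _ in range(6)]
    frames_b = [rng.uniform(0, 255, (3, 4, 3)) for _ in range(6)]
    fields_a = [
        ft.WarpField(rng.normal(size=(4, 5)), rng.normal(size=(4, 5)))
        for _ in range(6)
    ]
    fields_b = [
        ft.WarpField(rng.normal(size=(3, 4)), rng.normal(size=(3, 4)))
        for _ in range(6)
    ]
    return ft.build_hybrid((frames_a, fields_a), (frames_b, fields_b))
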