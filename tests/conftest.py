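import numpy as np
import pytest

from skinmpm.phantom import PhantomParams, SkinPhantom, generate_phantom


@pytest.fixture(scope="session")
def small_phantom() -> SkinPhantom:
    """A compact default-parameter phantom shared across tests."""
    return generate_phantom(42, shape=(24, 128, 128), pitch_um=(5.0, 0.9, 0.9))


@pytest.fixture(scope="session")
def default_phantom() -> SkinPhantom:
    """The full default phantom geometry (heavier; generated once)."""
    return generate_phantom(7, shape=(40, 256, 256), pitch_um=(5.0, 0.9, 0.9))


def make_uniform_phantom(
    value: float = 1.0,
    fluorophore: str = "melanin",
    shape=(24, 64, 64),
    pitch=(5.0, 0.9, 0.9),
) -> SkinPhantom:
    """Hand-built phantom with one uniform concentration map (synthetic
    fixture for single-fluorophore chain tests)."""
    from skinmpm.phantom import DEFAULT_FLUOROPHORES

    conc = {f.name: np.zeros(shape, dtype=np.float32) for f in DEFAULT_FLUOROPHORES}
    conc[fluorophore][:] = value
    mel_truth = conc["melanin"] > 0
    return SkinPhantom(
        concentration=conc,
        voxel_pitch_um=pitch,
        layer_boundaries_um=(15.0, 60.0),
        melanin_truth=mel_truth,
        dendrite_truth=np.zeros(shape, dtype=bool),
        seed=0,
        params=PhantomParams(),
    )
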