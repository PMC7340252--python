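import numpy as np
import pytest
from scipy import ndimage

from cryopick.io_core import ParticleStack, standardize
from cryopick.simdata import SceneParams, generate_micrograph, particle_template

BENCH_EFF_PS = 5.0 * 4 * 15 / 64  # 60 px box at 5 A/px, binned by 4, resized to 64


def template_crop(kind: str, rng: np.random.Generator, noise_sd: float = 0.0,
                  diameter: int = 48) -> np.ndarray:
    """A standardized 64x64 crop of a randomly rotated particle template."""
    tmpl = particle_template(kind, diameter)
    img = ndimage.rotate(tmpl, rng.uniform(0.0, 360.0), reshape=False, order=1)
    pad = (64 - diameter) // 2
    img = np.pad(img, pad)[:64, :64]
    if noise_sd:
        img = img + noise_sd * rng.standard_normal((64, 64))
    return standardize(img)


def noise_crop(rng: np.random.Generator) -> np.ndarray:
    return standardize(rng.standard_normal((64, 64)))


def mixed_stack(n_template: int, n_noise: int, seed: int = 0,
                noise_sd: float = 0.8) -> ParticleStack:
    """A stack of template crops followed by pure-noise crops."""
    rng = np.random.default_rng(seed)
    crops = [template_crop("disk", rng, noise_sd) for _ in range(n_template)]
    crops += [noise_crop(rng) for _ in range(n_noise)]
    return ParticleStack(
        np.stack(crops), [("stack", 0.0, 0.0)] * (n_template + n_noise), 4, BENCH_EFF_PS
    )


@pytest.fixture(scope="session")
def small_scene():
    """One 512 px scene with 20 disks at snr 1.0, no contaminants."""
    params = SceneParams(size=512, n_particles=20, diameter_px=48, pixel_size_A=6.25,
                         snr=1.0, seed=11)
    return generate_micrograph(params)


@pytest.fixture(scope="session")
def ice_scene():
    """One 1024 px scene with 20 disks and 3 bright ice blobs."""
    params = SceneParams(size=1024, n_particles=20, diameter_px=60, snr=1.0,
                         n_contaminants=3, seed=7)
    return generate_micrograph(params)
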