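import numpy as np
import pytest

from cardiot1.phantom import (PhantomConfig, render_stack, annulus_mask,
                              make_ti_schedule)


@pytest.fixture(scope="session")
def ti_schedule():
    return make_ti_schedule(1000.0)


@pytest.fixture(scope="session")
def still_phantom():
    """Noise-free, motion-free 256-grid phantom slice."""
    cfg = PhantomConfig(noise_sd=0.0, motion_amplitude=0.0, seed=7)
    stack, truth = render_stack(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def annulus_128():
    """Annulus r 14-22 on a 128 grid, centred."""
    return annulus_mask(128, (63.5, 63.5), 14.0, 22.0)


def make_phantom_training_set(n, seed0, grid=64, noise_sd=0.02):
    """Random-geometry phantom image/mask pairs for segmenter training."""
    rng = np.random.default_rng(seed0)
    X, Y = [], []
    for i in range(n):
        r_endo = rng.uniform(5, 9)
        r_epi = r_endo + rng.uniform(3, 6)
        cy, cx = rng.uniform(grid * 0.375, grid * 0.625, 2)
        cfg = PhantomConfig(grid_size=grid, center=(float(cy), float(cx)),
                            r_endo=float(r_endo), r_epi=float(r_epi),
                            noise_sd=noise_sd, seed=seed0 + i)
        stack, truth = render_stack(cfg)
        k = int(rng.integers(0, 11))
        X.append(stack[k])
        Y.append(truth.masks_per_ti[k])
    return np.stack(X), np.stack(Y)
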