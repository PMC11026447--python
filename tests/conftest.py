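import numpy as np
import pytest

from vitseq import PhantomSpec, generate_dataset
from vitseq.vit_encoder import test_scale_config


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spec():
    """Small-grid phantom spec used by I/O and slicing tests."""
    return PhantomSpec(grid_shape=(32, 40, 32), n_per_class=2,
                       noise_sd=0.02, seed=7)


@pytest.fixture(scope="session")
def small_volumes(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture(scope="session")
def tiny_encoder_cfg():
    """Encoder on 32x32 inputs: 2x2 patch grid, 4 patches (+1 class token)."""
    return test_scale_config(image_side=32, seed=0)


def finite_difference_grads(build_loss, params, rng, n_probe=4, eps=1e-6,
                            atol=1e-5):
    """Assert analytic grads match central finite differences at probes."""
    loss = build_loss()
    loss.backward()
    for p in params:
        assert p.grad is not None, "parameter received no gradient"
        flat = p.data.ravel()
        gflat = p.grad.ravel()
        for i in rng.integers(0, flat.size, size=min(n_probe, flat.size)):
            orig = flat[i]
            flat[i] = orig + eps
            lp = float(build_loss().data)
            flat[i] = orig - eps
            lm = float(build_loss().data)
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - gflat[i]) < atol * max(1.0, abs(num)), \
                f"grad mismatch: analytic {gflat[i]}, numeric {num}"
        p.grad = None
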