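import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_phantom_set():
    """Four small, easy phantoms plus a two-sample validation split."""
    from eenet import PhantomSpec, generate_dataset

    spec = PhantomSpec(
        image_size=(32, 32),
        n_lesions=1,
        contrast=0.6,
        texture_strength=0.5,
        boundary_softness=1.0,
        seed=0,
    )
    train, val, test = generate_dataset(spec, 4, 2, 2, seed=11)
    return train, val, test


def dense_conv2d_oracle(image, kernel):
    """Brute-force 'same' cross-correlation with mirror padding.

    Independent loop-based reference used by several tests; operates on one
    (H, W) plane.
    """
    from eenet.tensor import reflect_indices

    h, w = image.shape
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    padded = image[np.ix_(reflect_indices(h, ph), reflect_indices(w, pw))]
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    acc += padded[i + a, j + b] * kernel[a, b]
            out[i, j] = acc
    return out


def edge_magnitude_oracle(plane, smooth, gx, gy, eps_mag):
    """Loop-based smoothing + Sobel-pair + magnitude reference."""
    sm = dense_conv2d_oracle(plane, smooth)
    rx = dense_conv2d_oracle(sm, gx)
    ry = dense_conv2d_oracle(sm, gy)
    return np.sqrt(rx**2 + ry**2 + eps_mag)
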