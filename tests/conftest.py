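"""Shared fixtures: seeded RNGs and small synthetic subjects."""

import numpy as np
import pytest

from cortox.lek import KernelSet, dlf_basis
from cortox.synthgen import make_latent_input, synthesize_output


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_in_span_system(rng, alpha=0.9, L=4, M=200, dt=0.25, k0=2.0):
    """Ground-truth kernels lying exactly in the Laguerre span."""
    basis = dlf_basis(alpha, L, M)
    coeffs = [rng.normal(size=L) for _ in range(3)]
    kernels = KernelSet(dt=dt, k0=k0,
                        k_abp=basis.reconstruct(coeffs[0]),
                        k_co2=basis.reconstruct(coeffs[1]),
                        k_cfv=basis.reconstruct(coeffs[2]))
    return basis, coeffs, kernels


def make_io_record(rng, kernels, duration_s=300.0, dt=0.25,
                   noise_nmse_pct=0.0, band=(0.01, 0.15), sd=1.0):
    """Band-limited inputs plus the model output they generate."""
    inputs = [make_latent_input(duration_s, dt, band[0], band[1], sd, rng)
              for _ in range(3)]
    output = synthesize_output(inputs, kernels, noise_nmse_pct, rng)
    return inputs, output
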