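import numpy as np
import pytest

import ieegloc as il


def make_sphere_mask(radius: float = 60.0, shape: int = 150) -> il.BinaryMask:
    c = (np.array([shape] * 3) - 1) / 2.0
    aff = np.eye(4)
    aff[:3, 3] = -c
    ii = np.arange(shape)[:, None, None] - c[0]
    jj = np.arange(shape)[None, :, None] - c[1]
    kk = np.arange(shape)[None, None, :] - c[2]
    return il.BinaryMask((ii ** 2 + jj ** 2 + kk ** 2) <= radius ** 2, aff)


def lattice_variants(es):
    """All 8 lattice symmetries of a numbered grid (4 rotations x flip)."""
    outs = []
    x = es
    for _ in range(4):
        outs.append(x)
        outs.append(il.flip_rotate(x, "flip_lr"))
        x = il.flip_rotate(x, "rot_cw")
    return outs


def matches_truth_up_to_symmetry(es, truth, rows, atol=1e-6):
    """True if the numbering equals truth after some flip/rotate op."""
    return any(v.spec.rows == rows and np.allclose(v.ordered(), truth, atol=atol)
               for v in lattice_variants(es))


@pytest.fixture(scope="session")
def mixed_phantom():
    """One 4x5 grid on an 80 mm cap plus one 8-contact depth array,
    noise sd 100 HU: the standard small validation phantom."""
    grid = il.ElectrodeArraySpec("grid", 4, 5, 10.0, "G")
    depth = il.ElectrodeArraySpec("depth", 1, 8, 10.0, "D")
    return il.make_phantom(
        [(grid, il.GridPlacement()),
         (depth, il.DepthPlacement(tip=(-20.0, 0.0, -20.0),
                                   direction=(1.0, 0.0, 0.0)))],
        noise_sd=100.0, seed=1)


@pytest.fixture(scope="session")
def sphere_mask60():
    return make_sphere_mask(60.0, 150)


@pytest.fixture(scope="session")
def sce60(sphere_mask60):
    return il.build_sce(sphere_mask60)
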