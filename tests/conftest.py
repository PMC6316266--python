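import numpy as np
import pytest

from pitcorr.mesh import CouponSpec, VoxelMesh


def make_box_mesh(nx: int, ny: int, nz: int, Le: float = 1.0) -> VoxelMesh:
    """Hand-built rectangular box mesh with brute-force triple-loop
    adjacency; serves as an independent oracle for mesh-based operations."""
    idx = {}
    ijk = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                idx[(i, j, k)] = len(ijk)
                ijk.append((i, j, k))
    n = len(ijk)
    neighbors = np.full((n, 6), -1, dtype=np.int64)
    shifts = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
    for e, (i, j, k) in enumerate(ijk):
        for f, (a, b, c) in enumerate(shifts):
            neighbors[e, f] = idx.get((i + a, j + b, k + c), -1)
    ijk = np.array(ijk)
    centers = (ijk + 0.5) * Le
    boundary = (neighbors < 0).any(axis=1)
    # CouponSpec is only carried along for bookkeeping here
    spec = CouponSpec(diameter=max(nx, ny) * Le * 2, thickness=nz * Le)
    return VoxelMesh(
        Le=Le, centers=centers, neighbors=neighbors, boundary=boundary,
        coupon=spec, ijk=ijk,
    )


@pytest.fixture(scope="session")
def coupon_3600():
    from pitcorr.mesh import build_coupon_mesh

    return build_coupon_mesh(15.0, 3.0, target_elements=3600)


@pytest.fixture(scope="session")
def mgznca_dataset():
    from pitcorr.immersion import builtin_mgznca_dataset

    return builtin_mgznca_dataset()
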