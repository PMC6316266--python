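"""Build the voxelized 15 mm x 3 mm disc coupon and export a VTK snapshot.

The coupon is discretized into ~3600 identical cubes (the element count of
the published calibration study); the summary shows the realized count, the
cube edge Le and how close the voxel volume is to the exact cylinder.
"""

import json

from pitcorr import (
    OPTIMIZED_MGZNCA_PARAMS,
    build_coupon_mesh,
    init_state,
    mesh_summary,
    write_field_snapshot,
)

mesh = build_coupon_mesh(diameter=15.0, thickness=3.0, target_elements=3600)
print(json.dumps(mesh_summary(mesh), indent=2))

state = init_state(mesh, OPTIMIZED_MGZNCA_PARAMS)
write_field_snapshot(mesh, state, "fresh_coupon.vtk")
print(
    f"\nwrote fresh_coupon.vtk: {mesh.n_elements} hexahedral cells with "
    "cell data 'damage' (all zero), 'lambda_p' (Weibull draws on the "
    "exposed surface, -1 in the interior) and 'status'."
)
print(
    "The voxel volume above should sit within ~2% of the exact cylinder "
    "volume pi*r^2*h; the difference is the jagged rim of the voxelization."
)
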