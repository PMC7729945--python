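"""Design sensor arrays by point packing at several target spacings.

Prints the channel count and the observed median nearest-sensor spacing
per target spacing: coarser sampling needs fewer sensors (roughly
area/spacing^2), and every scalp vertex above the brain's inferior edge is
guaranteed to be within one target spacing of a sensor.
"""

import numpy as np

from opmarray import make_cortex, make_scalp, offset_array, pack_sensors

scalp = make_scalp(seed=1)
space = make_cortex(scalp, seed=2)
z_floor = float(space.mesh.vertices[:, 2].min())

for spacing in (20.0, 30.0, 45.0):
    arr = pack_sensors(scalp, spacing, z_floor_mm=z_floor, seed=4)
    on_scalp = offset_array(arr, 6.5)  # wearable standoff
    med = np.median(on_scalp.nearest_sensor_distances())
    print(f"target {spacing:4.0f} mm -> {on_scalp.n_channels:4d} channels, "
          f"median observed spacing {med:.1f} mm")
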