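"""Build the synthetic head: spherical scalp, folded cortex, parcels and
depth-stratified sources.

Prints the mesh sizes, the vertex spacing (should be ~3 mm, like a
template cortical mesh), the depth range, and the depth separation of the
selected deep vs superficial source classes.
"""

import numpy as np

from opmarray import assign_parcels, make_cortex, make_scalp, select_sources

scalp = make_scalp(radius_mm=90.0, n_vertices=2562, seed=1)
space = assign_parcels(make_cortex(scalp, seed=2), n_parcels=90, seed=3)
sources = select_sources(space, n_deep=20, n_superficial=20)

print(f"scalp: {scalp.n_vertices} vertices, area {scalp.area:.0f} mm^2")
print(f"cortex: {space.n_vertices} vertices, "
      f"mean spacing {space.mesh.mean_vertex_spacing():.2f} mm")
print(f"depth range: {space.depth.min():.1f} - {space.depth.max():.1f} mm")
print(f"{space.n_parcels} parcels; {len(sources)} sources in "
      f"{len(np.unique(space.parcel_label[sources.vertex_indices]))} distinct parcels")
print(f"deep sources:        depth >= {space.depth[sources.deep].min():.1f} mm")
print(f"superficial sources: depth <= {space.depth[sources.superficial].max():.1f} mm")
# the two classes must not overlap in depth — that is what makes the
# deep-vs-superficial comparison meaningful downstream
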