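"""Export simplified geometry: helicoidal double ribbon and linker tube.

The ribbon is the mid-distance display model of a DNA strand — two
helicoid strips half a turn apart whose azimuth follows the twist
schedule, so a locally untwisted region is visibly straightened.  The tube
is the representation used for disordered protein linkers.  Both are
written as OBJ and VRML97 for use in external 3D tools.
"""

import numpy as np

from dnaxis import (BezierSegment, CurvePath, build_dna, export_mesh,
                    ribbon_mesh, tube_mesh)

path = CurvePath(
    [BezierSegment([[0, 0, 0], [120, 0, 60], [240, 0, -60], [360, 0, 0]])]
)
# untwist pairs 40..60 to show the schedule driving the ribbon
constraints = {40: 0.0, 60: -(60 - 40) * 2 * np.pi / 10.4}
model = build_dna(path, constraints)

ribbon = ribbon_mesh(model.frames, model.schedule, width=9.0)
print(f"ribbon: {ribbon.n_vertices} vertices, {ribbon.n_triangles} triangles "
      f"({model.n_base_pairs} base pairs x 2 ribbons x 2 edge vertices)")
export_mesh(ribbon, "ribbon.obj", format="obj")
export_mesh(ribbon, "ribbon.wrl", format="vrml")

linker = tube_mesh(path, radius=5.0, ring_spacing=3.4, sides=12)
print(f"tube:   {linker.n_vertices} vertices, {linker.n_triangles} triangles "
      "(12-sided rings every 3.4 Å, capped ends)")
export_mesh(linker, "linker.obj", format="obj")
print("wrote ribbon.obj, ribbon.wrl, linker.obj")
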