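"""Separating physically interacting cells with nuclear information.

Two cells whose somata touch form a single connected component, so any
purely intensity-based segmentation with a permissive merge threshold
returns one object. The nucleus rules split that object back into two:
each nucleus seeds a geodesic region inside the merged cluster.
"""

import numpy as np

import persicell as pc

scene = pc.generate_scene(pc.SynthParams(
    seed=3, n_cells=2, touching_pair_fraction=1.0, gaussian_sd=0.0, psf_sigma_um=0.0,
))

cells = scene.stack.channel(1)
thr = pc.otsu_threshold(cells)
mask = pc.foreground_mask(cells, thr, scene.stack.spacing_um)
graph = pc.build_voxel_graph(mask, cells)

# infinite delta forces every component into one cluster: the nucleus-free view
merged = pc.tomato_cluster(graph, pc.PBCParams(delta=np.inf))
print(f"without nuclei (delta=inf): {merged.n_coarse} cluster for 2 true cells")

seg = pc.refine(merged, scene.gt_nuclei)
print(f"after nucleus refinement:   {seg.n_cells} cells "
      f"(nucleus map: {seg.nucleus_of})")

report = pc.evaluate_segmentation(seg.labels, scene.gt_cells)
print(report.rows[["pred_id", "gt_id", "jaccard"]].round(3).to_string(index=False))
print("Both cells are recovered; the split boundary follows geodesic")
print("distance from each nucleus through the merged cluster.")
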