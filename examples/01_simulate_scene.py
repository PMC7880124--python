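"""Simulate a ground-truthed fundus-like scene.

Grows a synthetic vascular tree around the optic disc, rasterises it into a
grayscale image plus a binary truth mask, and reports what was generated.
"""

import numpy as np

import retivasc as rv

params = rv.TreeParams(seed=1)
tree = rv.simulate_tree(params)
scene = rv.render_scene(tree, seed=1)

majors = [s for s in tree.segments if s.parent_id is None]
print(f"tree: {tree.n_segments} segments, {len(majors)} major vessels "
      f"({sum(s.label == 'arteriole' for s in majors)} arterioles)")
print(f"total centreline length: {tree.total_arc_length():.0f} px")
print(f"image: {scene.image.shape}, vessel pixels: {scene.vessel_area_px} "
      f"({100 * scene.vessel_area_px / scene.image.size:.1f}% of the field)")
print(f"disc: centre {scene.disc_center}, radius {scene.disc_radius:.0f} px "
      f"(= {scene.disc_radius / scene.px_per_micron:.0f} um)")

# The truth mask is the rasteriser's >= 50% coverage level set; vessels are
# darker than their surroundings before noise, which is what the multiscale
# line detector in example 02 exploits.
img, truth = scene.image, scene.truth_mask
print(f"mean intensity on vessels {img[truth].mean():.3f} "
      f"vs background {img[~truth].mean():.3f}")
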