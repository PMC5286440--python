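"""End-to-end registration of a synthetic longitudinal pair.

Runs the whole pipeline (detection, two-tier matching, TPS, competitive
winner-guided refinement) and scores it against the generator's exact
landmark correspondence.
"""

import numpy as np

import thermoreg as tr

scene = tr.generate_scene(seed=7)
warp = tr.random_tps_warp(seed=8, shape=scene.shape, max_displacement=15.0)
source, target, lm_src, lm_tgt = tr.render_pair(
    scene, warp, noise_seed_source=9, noise_seed_target=10
)

result = tr.run_registration(source, target, tr.PipelineConfig(seed=7))

pred = tr.tps_apply(result.tps_forward, lm_src)
err = np.hypot(*(pred - lm_tgt).T)
print(f"control pairs used: {len(result.control_pairs)}")
print(f"landmark error: mean {err.mean():.2f} px, max {err.max():.2f} px")
print(f"SSIM  {result.metrics['ssim_before']:.3f} -> {result.metrics['ssim_after']:.3f}")
print(f"MI    {result.metrics['mi_before']:.3f} -> {result.metrics['mi_after']:.3f} nats")
# Sub-2-px mean landmark error means the recovered warp reproduces the
# hidden deformation to well under the vessel width.
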