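"""Featurize one synthetic eye-written trajectory.

Generates a noisy trace of the "loop" template (with a possible initiation
saccade), runs the deterministic front end, and prints the via-point
summary and auxiliary features the probabilistic model consumes.
"""

from eyewrite import GeneratorConfig, curated_templates, featurize, generate_trajectory

traj = generate_trajectory(curated_templates()["loop"], GeneratorConfig(), rng=1)
via_points, aux = featurize(traj)

print(f"{len(traj)} raw samples -> {len(via_points)} via-points")
print("  k    dx      dy      vx      vy   (px and px/s, relative displacements)")
for v in via_points:
    print(f"{v.index:3d} {v.dx:7.1f} {v.dy:7.1f} {v.vx:7.1f} {v.vy:7.1f}")
print(
    f"size {aux.sx:.1f} x {aux.sy:.1f} px, band energy above 2.6 Hz {aux.a:.1f} (px/s)^2,"
    f" pupil mean {aux.mu_p:+.2f}, pupil SD {aux.sigma_p:.2f}"
)
print("The first via-point is always (0, 0): eye writing has no absolute frame.")
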