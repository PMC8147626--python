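"""Recover a known diffusion coefficient from simulated free diffusion.

Simulates 300 obstacle-free trajectories at 500 fps with D = 0.5 µm²/s and
no localization noise, pools their MSD curves and fits D(τ) cumulatively.
For free Brownian motion the D(τ) curve is flat, so every entry should sit
near the input value.
"""

import numpy as np

import memdiff as m

field = m.build_obstacle_field(box_size=5.0, target_fraction=0.0, diameter_mean=0.101)
config = m.DiffusionSimConfig(
    d_free=0.5,
    frame_interval=1 / 500,
    n_trajectories=300,
    n_frames=200,
    length_dist="fixed",
    loc_noise_sigma=0.0,
    seed=1,
)
trajectories = m.simulate_trajectories(field, config)
curve = m.pooled_msd_from_trajectories(trajectories, n_max=50)
dcurve = m.build_d_curve(curve)

print(f"simulated D        : {config.d_free:.3f} um^2/s")
print(f"recovered D(4*dt)  : {dcurve.d_values[3]:.3f} um^2/s")
print(f"D(tau) range       : {dcurve.d_values.min():.3f} .. {dcurve.d_values.max():.3f}")
print(f"flatness max/min   : {dcurve.d_values.max() / dcurve.d_values.min():.3f}")
print()
print("A flat D(tau) within a few percent of 0.5 confirms the simulator and")
print("the pooled-MSD / through-origin fit chain are consistent: there is no")
print("obstruction, so the diffusion coefficient has no lag-time dependence.")
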