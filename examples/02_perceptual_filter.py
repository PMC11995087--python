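"""Run the Kalman-filter perceptual model for a single observer.

Physical circle diameters pass through a sigmoid sensory mapping and are
integrated with the running perceptual state; the printed trace shows the
Kalman gain settling and perceptual uncertainty decaying as exposure
accumulates.
"""

import numpy as np

import percgen as pg

schedule = pg.make_schedule(1, seed=3)
diameters = np.array([schedule.stimuli.diameter(e.stimulus) for e in schedule.entries])

params = pg.PerceptParams(beta0=-3.05, beta1=0.023, sigma_S=0.8, omega=0.002)
group = pg.GroupPerceptParams(eta=11.04)

print(f"sensory mean at the CS+ diameter (96.54 mm): "
      f"{pg.sensory_mean(96.54, params):.2f} on the 0-200 rating scale")

states = pg.filter_trajectory(diameters, params, group)
print(f"{'trial':>5} {'stimulus':>8} {'mu_S':>7} {'mu_psi':>7} {'sigma_psi':>9} {'gain':>6}")
for j in (0, 1, 5, 20, 50, 100, 197):
    s = states[j]
    print(f"{j:>5} {schedule.entries[j].stimulus:>8} {s.mu_S:7.2f} "
          f"{s.mu_psi:7.2f} {s.sigma_psi:9.2f} {s.kalman_gain:6.3f}")

# The gain stays high (sensory-driven perception) because sigma_S is small
# relative to the perceptual uncertainty; sigma_psi declines slowly at
# omega = 0.002, mirroring gradually stabilizing perception.
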