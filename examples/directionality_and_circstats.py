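"""Population-level growth directionality with circular statistics.

Generates a small population of south-elongated crowns, recovers each one's
largest-projection azimuth, and summarizes the population with the circular
mean/variance, the Rayleigh uniformity test, and Watson's two-sample test
against a symmetric population.
"""

import numpy as np

from crownsect import (
    CrownParams,
    azimuth_profile,
    build_alphashape,
    circular_summary,
    generate_crown,
    watson_two_sample,
)
from crownsect.change import largest_projection_azimuth


def population_azimuths(ratio: float, n: int, seed0: int) -> np.ndarray:
    out = []
    for t in range(n):
        p = CrownParams(asymmetry_ratio=ratio, asymmetry_azimuth_deg=180.0)
        tree = generate_crown(p, (0.0, 0.0), seed=seed0 + t)
        mesh = build_alphashape(tree.xyz, 1.0)
        prof = azimuth_profile(mesh, (0.0, 0.0), tree.xyz[:, 2].max())
        out.append(largest_projection_azimuth(prof))
    return np.array(out)


south = population_azimuths(ratio=1.5, n=12, seed0=100)
uniform = population_azimuths(ratio=1.0, n=12, seed0=200)

s = circular_summary(south)
print(f"south-elongated: mean {s.mean_deg:.1f} deg, variance {s.variance:.2f}, "
      f"Rayleigh p = {s.rayleigh_p:.2e}")
u = circular_summary(uniform)
print(f"symmetric:       variance {u.variance:.2f}, Rayleigh p = {u.rayleigh_p:.3f}")

w = watson_two_sample(south, uniform, n_permutations=2000, seed=0)
print(f"Watson U^2 = {w.u2:.3f} ({w.p_range}); permutation p = {w.p_permutation:.4f}")
# The asymmetric population concentrates near 180 deg (tiny Rayleigh p);
# the symmetric one does not reject uniformity, and Watson's test separates
# the two preferred-direction distributions.
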