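"""Phantom round trip: simulate DWI, fit tensors, recover the ALPS index.

One subject with known ground truth is pushed through the whole imaging
chain — tensor-field construction, 64-direction DWI simulation, OLS
tensor fit, spherical-ROI extraction — noiselessly and at 1% Rician
noise.  Noiseless recovery is exact to ~1e-6 relative; 1% noise perturbs
the index only in the third decimal.
"""

from dtialps import AcquisitionScheme, PhantomGeometry
from dtialps.pipeline import measure_subject

geometry = PhantomGeometry.default((48, 20, 20))  # compact desk-scale grid
scheme = AcquisitionScheme.default()              # 1 b0 + 64 dirs, b=1000

truth = {"dxx_proj": 1.58e-3, "dxx_assoc": 1.58e-3,
         "dyy_proj": 1.00e-3, "dzz_assoc": 1.00e-3}
true_alps = 1.58

for sigma in (0.0, 0.01):
    res = measure_subject(truth, geometry, scheme, noise_sigma=sigma, seed=7)
    print(f"noise {sigma:4.0%}:  measured ALPS = {res.index_bilateral:.6f}  "
          f"(truth {true_alps}, error {res.index_bilateral - true_alps:+.2e})")
print("ROI voxel counts:", dict(res.voxel_counts))
# The 5.4 mm spheres on the 1.8 mm grid cover 19 voxels each; all four
# extracted diffusivities feed the index mean(Dxx)/mean(Dyy_proj, Dzz_assoc).
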