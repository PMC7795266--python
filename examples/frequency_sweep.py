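"""Network strength and connectivity from a small-deformation sweep.

Fits G*(omega) = A_f * omega**(1/z) to a simulated 0.1-10 Hz frequency
sweep of the complex shear modulus.
"""

import doughrheo as dr

sweep = dr.simulate_frequency_sweep(A_f=15000.0, z=8.0, n_points=20, noise_cv=0.02, seed=3)
fit = dr.fit_gstar(sweep)

print(f"simulated truth: A_f = 15000 Pa s^(1/z), z = 8")
print(
    f"fit: A_f = {fit.A_f:.0f} +/- {fit.stderr_A_f:.0f} Pa s^(1/z), "
    f"z = {fit.z:.2f} +/- {fit.stderr_z:.2f} (r2_adj = {fit.r2_adj:.4f})"
)
print(
    "\nA_f scales the stiffness of the starch-gluten network; z measures\n"
    "how extensively it is connected (larger z = weaker frequency\n"
    "dependence = more interconnected network)."
)
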