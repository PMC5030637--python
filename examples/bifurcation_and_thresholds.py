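"""Homogeneous states, fold and Turing thresholds of the phytomass model.

Builds the reference parameter set, prints the uniform steady states,
the fold of the vegetated branch, and the finite-wavelength instability
threshold with its intrinsic wavelength.
"""

import numpy as np

from phytopattern import (
    ModelParams,
    bifurcation_diagram,
    critical_wavenumber,
    homogeneous_states,
    limit_point,
    turing_threshold,
)

p = ModelParams(eta=0.08, kappa=0.6, delta=0.02, gamma_nl=0.5, alpha_nl=0.125)

ss = homogeneous_states(p)
print(f"uniform states at eta={p.eta}: {[round(s, 4) for s in ss.states]}")
print("  (bare soil, unstable lower branch, vegetated upper branch)")

rho_L, eta_L = limit_point(p)
print(f"fold of the vegetated branch: rho_L={rho_L}, eta_L={eta_L}")
print("  -> above eta_L no uniform vegetated cover can exist")

roots = turing_threshold(p.kappa, p.delta, p.gamma_nl, p.alpha_nl)
for rho_c, eta_c in roots:
    disp = critical_wavenumber(rho_c, p.replace(eta=eta_c), check=False)
    print(
        f"Turing threshold: rho_c={rho_c:.4f}, eta_c={eta_c:.4f}, "
        f"k_c={disp.critical_wavenumber:.3f}, wavelength={disp.wavelength:.2f}"
    )
print("  -> between eta_c and eta_L the uniform cover breaks into a pattern")

df = bifurcation_diagram(np.linspace(0.01, 0.12, 12), p.kappa, p.delta,
                         p.gamma_nl, p.alpha_nl)
df.to_csv("bifurcation_diagram.csv", index=False)
print("bifurcation diagram written to bifurcation_diagram.csv")
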