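"""Bistability and hysteresis: the equilibrium branches in the external parameter E.

Sweeps E, prints the fixed-point census at a few values and the fold location
where the addicted and unstable branches merge and vanish.
"""

from addyn import all_equilibria, default_params, sweep_branches

params = default_params()
print(f"parameters: {params}\n")

for E in (-0.6, -0.3, 0.0, 0.02, 0.1):
    eqs = all_equilibria(params, E)
    print(f"E = {E:+.2f}: {len(eqs)} fixed point(s)")
    for eq in eqs:
        tag = "stable" if eq.stable else "UNSTABLE"
        print(
            f"   {eq.regime:9s} C* = {eq.C_star:.4f}  S* = {eq.S_star:+.4f}  "
            f"|eig| = ({eq.eigen_moduli[0]:.3f}, {eq.eigen_moduli[1]:.3f})  {tag}"
        )

diagram = sweep_branches(params, -0.6, 0.35, 0.005)
print(
    "\nequilibrium-count transitions at E = "
    + ", ".join(f"{f:.6f}" for f in diagram.E_folds)
)
print(
    "Between E = -0.5 (where the abstinent branch appears) and the fold near"
    " E = 0.0253, the abstinent and addicted states coexist: under identical"
    " external conditions, history alone decides which one a person occupies"
    " (hysteresis)."
)
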