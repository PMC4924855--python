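"""Getting addicted while changing lifestyle.

A person enters a new peer group: societal protection E decays from 1 toward
0 while the weekly cue intensity grows from 0.5 to 1.  Craving C fluctuates
with the cue-driven drinking; the switch into dependence is marked by the
vulnerability V jumping to 1, not by craving alone.
"""

from addyn import OnsetSchedule, default_params, run_onset

params = default_params()
schedule = OnsetSchedule()  # E: 1 -> 0, lam: 0.5 -> 1, both at 0.01/week
traj = run_onset(params, schedule, T=260, seed=7)

print("week    E    lam    R     A      C      S      V")
for t in range(0, 260, 20):
    r = traj.to_frame().iloc[t]
    print(
        f"{int(r.t):4d}  {r.E:.2f}  {r['lambda']:.2f}  {int(r.R):3d}  "
        f"{r.A:.3f}  {r.C:.3f}  {r.S:+.3f}  {r.V:.3f}"
    )

switch = (traj.V > 0.999).argmax() if (traj.V > 0.999).any() else None
if switch is not None:
    print(f"\nfull dependence (V ≈ 1) first reached in week {switch};")
    print("craving alone rises gradually, but V switches sharply once the")
    print("declining protection lets the addicted state capture the dynamics.")
else:
    print("\nthis realisation escaped full dependence within the horizon —")
    print("the outcome is stochastic; other seeds get captured.")
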