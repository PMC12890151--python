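"""Simulate the reference two-drug scenario and sweep an interaction term.

Builds the baseline pair (doses 0.6 and 1.0 x 10^3 mg; drug X rates all
0.5/h, drug Y 0.6/0.5/0.4/0.3/h), simulates 40 h, prints drug X's summary
PK metrics, then shows how an absorption coupling g_abs (drug Y promoting
or inhibiting drug X's absorption) shifts those metrics.
"""

from coupledpk import compute_metrics, make_scenario, metrics_table, simulate

system = make_scenario()
traj = simulate(system, horizon=40.0, output_step=0.001)
m = compute_metrics(traj, "x", window=40.0)
print("uncoupled drug X: "
      f"Cmax={m.c_max:.5f} (10^3 mg)  Tmax={m.t_max:.4f} h  "
      f"AUC[0,40]={m.auc:.5f} (10^3 mg h)  t1/2={m.t_half:.4f} h")

print("\nabsorption-coupling sweep (g_abs of drug X, driven by drug Y's gut amount):")
table = metrics_table(system, "x", "g_abs", [-0.4, -0.2, 0.0, 0.2, 0.4, 2.0])
print(table.round(5).to_string(index=False))
print("\nPositive g_abs accelerates absorption: the peak rises and arrives "
      "earlier, the half-life shortens, while total exposure (AUC) barely moves.")
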