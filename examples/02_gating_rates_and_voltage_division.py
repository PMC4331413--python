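"""Boltzmann gating rates and the series voltage division.

Evaluates the voltage-dependent open<->closed transition rates of a
subgate and divides a transjunctional voltage across the two series
hemichannels at one gating state.  The split is found by fixed-point
iteration because the hemichannel conductances themselves depend on the
voltages across them (rectification).
"""

from gjgate import (
    GatingParams,
    hemichannel_conductance,
    solve_voltage_division,
    transition_probabilities,
)

params = GatingParams(A=0.05, P=1, K=0.01, V0=25.0, Ro=80.0, Rc=40.0)

print("voltage (mV)   p_oc        p_co")
for v in (0.0, 25.0, 50.0, 75.0):
    p_oc, p_co = transition_probabilities(params, v)
    print(f"{v:12.1f} {p_oc:10.6f} {p_co:10.6f}")
print("At V = V0 = 25 mV both probabilities equal K/2; beyond it the "
      "closing\ntransition dominates (P = +1).")

vj = 60.0
# left hemichannel with 2 subgates closed, right with 4 closed
split = solve_voltage_division(vj, 2, 4, params, params)
g_left = hemichannel_conductance(2, params, split.v_left)
g_right = hemichannel_conductance(4, params, -split.v_right)
print(f"\nVj = {vj} mV divided as V_left = {split.v_left:.3f} mV, "
      f"V_right = {split.v_right:.3f} mV ({split.iterations} iterations)")
print(f"current balance: V_left*g_left = {split.v_left * g_left:.4f}, "
      f"V_right*g_right = {split.v_right * g_right:.4f}")
print("The more-closed right hemichannel has the lower conductance and "
      "therefore\ntakes the larger share of the voltage.")
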