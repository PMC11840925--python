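"""Four-state carrier model: flux ratios and counterflow.

The classical single-site alternating-access carrier predicts the
ratio of equilibrium-exchange to zero-trans-influx maximal rates,
V_ee/V_oi = (1 + c/h)/2 in the fast binding/release limit, where c is
the loaded translocation rate and h the empty-carrier return.  It also
produces the hallmark counterflow overshoot: trace label driven uphill
by saturating unlabelled ligand on the trans side.
"""

from glutx import (
    check_microscopic_reversibility,
    fast_binding_rates,
    protocol_vmax_km,
    ratio_vee_voi,
    ratio_vee_voi_closed_form,
    simulate_counterflow,
    steady_state,
)

print("V_ee/V_oi vs c/h (solver vs closed form):")
for c_over_h in (0.1, 1.0, 10.0, 200.0):
    rates = fast_binding_rates(c=c_over_h, h=1.0)
    print(f"  c/h = {c_over_h:6.1f}:  solver {ratio_vee_voi(rates):8.3f}   "
          f"closed form {ratio_vee_voi_closed_form(c_over_h):8.3f}")
print("c/h = 10 reproduces the classic 5.5-fold accelerated exchange;"
      "\nc/h <= 1 caps the ratio at 1 (no accelerated exchange).")

rates = fast_binding_rates(c=10.0, h=1.0)
ratio, verdict = check_microscopic_reversibility(rates)
print(f"\ncycle-product ratio (a c e h)/(b d f g) = {ratio:.3g} -> {verdict}")

v_oi, km = protocol_vmax_km(rates, "zero_trans_influx")
print(f"zero-trans influx: V_max = {v_oi:.3f} carrier^-1 ns^-1, "
      f"K_m = {km:.3g} mM")
s = steady_state(rates, G_out=10.0, G_in=0.0)
print(f"state occupancies at 10 mM outside: "
      + ", ".join(f"{k} {v:.2f}" for k, v in s.probabilities.items()))

res = simulate_counterflow(
    rates, volume_out=1.0, volume_in=1.0,
    labeled_out0=0.05, unlabeled_out0=0.0,
    labeled_in0=0.0, unlabeled_in0=200.0,
    t_end=50_000.0, n_points=2000,
)
peak, final = res["labeled_in"].max(), res["labeled_in"][-1]
print(f"\ncounterflow: internal label peaks at {peak:.4f} mM vs "
      f"{final:.4f} mM at equilibrium ({peak/final:.2f}x overshoot)")
print("The transient uphill accumulation of label is the counterflow"
      "\nsignature of a shared carrier.")
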