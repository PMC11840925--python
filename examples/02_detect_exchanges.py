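"""Detect and classify positional exchange events along the pore axis.

An exchange is a swap of Z-ordering between two ligands whose normalised
ordering gap changes by more than 0.4 (pore span mapped to [0, 1]) with
the event centred between Z = -15 and +12 Å; only the smallest
non-overlapping window per pair is kept.  Events come in three flavours:
close apposition (partners within 3.5 Å), wide bypass, and surface
exchange (a long-resident well-bound ligand displaced by a partner
arriving from solution).
"""

from glutx import DetectorConfig, default_config, detect_exchanges, exchange_series, simulate

traj = simulate(default_config("fluid", n_frames=500, seed=3))
events = detect_exchanges(traj, DetectorConfig())

series = exchange_series(events, time_bin=100.0)
print(f"{len(events)} exchange events in {traj.duration:.0f} ns")
print("by kind:", series["totals_by_kind"])
print("per 100-ns window:", list(series["bin_counts"]))

print("\nfirst events (time, mean Z, min distance, kind):")
for ev in events[:8]:
    print(f"  t = {ev.time_mid:6.1f} ns   Z = {ev.z_mean:6.1f} Å   "
          f"d_min = {ev.min_distance:4.1f} Å   {ev.kind:7s} "
          f"({ev.ligand_a} <-> {ev.ligand_b})")
print("\nEach line is one pairwise positional swap inside the pore; the"
      "\nmean Z locates it along the transport pathway and the minimum"
      "\napproach distance separates contact exchanges from bypasses.")
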