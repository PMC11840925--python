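"""The headline experiment: exchange persists while net transit collapses.

Runs the full pipeline (generator -> exchange detector -> transit
statistics) for the fluid and gel lipid-phase presets with paired seeds.
Gelation keeps the bottleneck gates closed ~98% of the time, so complete
solution-to-solution transits all but vanish — yet ligands crowded
between the closed gates keep exchanging positions, so the
exchange-to-net flux ratio explodes in the gel phase.
"""

from pathlib import Path

from glutx.pipeline import PipelineConfig, run_pipeline

out = Path("scratch/fluid_vs_gel")
report = run_pipeline(
    PipelineConfig(phases=("fluid", "gel"), seeds=(1, 2, 3), n_frames=600,
                   write_trajectories=False),
    out,
)

print(f"{'phase':8s} {'events':>7s} {'transits':>9s} {'exchange/net':>13s}")
for phase, block in report["phases"].items():
    p = block["pooled"]
    ratio = p["exchange_to_net_ratio"]
    shown = f"{ratio:.0f}" if ratio != float("inf") else ">{}".format(p["n_events"])
    print(f"{phase:8s} {p['n_events']:7d} {p['n_transits']:9d} {shown:>13s}")

print(f"\nper-replica detail and manifest written to {out}/")
print("Exchange counts stay the same order of magnitude across phases"
      "\nwhile transit counts collapse in the gel: the temperature"
      "\ninsensitivity of exchange flux relative to net flux.")
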