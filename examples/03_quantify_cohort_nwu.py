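"""End-to-end NWU quantification on a small synthetic cohort.

Builds one noise-free case per onset-to-CT time window with the window's
cohort-mean NWU as ground truth, runs the full pipeline (segmentation ->
registration -> mirroring -> quantification) and prints the recovered
per-window NWU.
"""

import tempfile
from pathlib import Path

from rssi_nwu.phantom import cohort_specs_like_study, generate_cohort
from rssi_nwu.pipeline import RunConfig, run_pipeline

root = Path(tempfile.mkdtemp(prefix="rssi_nwu_example_"))
specs, hours = cohort_specs_like_study(
    n_per_window=1, noise_sd_hu=0.0, thalamus_sd_hu=0.0, seed=1
)
generate_cohort(specs, hours, root / "cohort")

result = run_pipeline(
    RunConfig(out_dir=root / "run", cohort_dir=root / "cohort",
              write_enhanced=False, seed=1)
)
print(f"{'window':>10} {'truth NWU %':>12} {'measured NWU %':>15}")
for m, spec in zip(result.measurements, specs):
    print(f"{m.time_window:>10} {spec.lesion_nwu_pct:>12.1f} {m.nwu_pct:>15.2f}")
print(f"outputs in {result.out_dir}")
# On noise-free phantoms the recovered NWU matches the ground truth to well
# under one percentage point: the measured lesion sample stays inside the
# true lesion and its mirror stays inside homologous tissue.
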