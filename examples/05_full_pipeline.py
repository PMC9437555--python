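"""One reproducible end-to-end run on a small synthetic trial.

Simulates telemetry, self-reports and viral loads for 10 clinics, derives
monthly adherence, and writes every report table (agreement, diagnostic
accuracy with cluster-bootstrap CIs, trend coefficients, margins,
threshold sensitivity sweep) to ./pipeline_demo/.
"""

import pandas as pd

from adheremon import RunConfig, SimConfig, run_all

cfg = RunConfig(
    out_dir="pipeline_demo",
    sim=SimConfig(n_clinics=10, participants_per_clinic=10, months=6, seed=5),
    bootstrap_replicates=200,
)
paths = run_all(cfg)

print("outputs:")
for name, path in paths.items():
    print(f"  {name:12s} {path}")

table6 = pd.read_csv(paths["table6"])
print("\ndiagnostic accuracy of each measure for viral non-suppression:")
cols = ["test", "sensitivity", "specificity", "auc_binary",
        "sens_boot_low", "sens_boot_high"]
print(table6[cols].round(3).to_string(index=False))
print("\nThe self-report row shows the expected over-reporting signature:")
print("higher specificity but much lower sensitivity than the electronic")
print("measure. See run_log.txt for per-stage row accounting.")
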