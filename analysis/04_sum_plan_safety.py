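"""Two-course accumulation and reirradiation safety across the cohort.

Compares the original sum plan (course 1 + course 2, EQD2) with the SFRT
sum plan (course 1 + SFRT-boosted course 2) per phantom: OAR D0.03cc
changes, DVH gamma pass rates, brain V120/V100/V80 changes, and the
single-fraction headroom under the 120 Gy cumulative limit. Reads the
artifacts written by 03 if present, otherwise re-runs the pipeline.
Writes results/safety.csv."""

import csv
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from cohort import COHORT, RESULTS_DIR

import sfrtplan as sp


def main() -> None:
    out = Path(RESULTS_DIR)
    out.mkdir(exist_ok=True)
    rows = []
    for name, spec in COHORT:
        run_dir = Path("scratch/runs") / name
        report_path = run_dir / "report.json"
        if report_path.exists():
            report = json.loads(report_path.read_text())
        else:
            report = sp.run_pipeline(sp.RunConfig(phantom=spec), run_dir)
        s = report["safety"]
        brain_v120 = s["vx_cc"]["brain"]["V120Gy"]
        row = {"phantom": name, "technique": report["technique"]}
        for oar in ("brainstem", "chiasm"):
            comp = s["structures"][oar]
            row[f"{oar}_d003cc_diff_pct"] = round(comp["d003cc_diff_pct"], 2)
            row[f"{oar}_gamma_pct"] = round(comp["gamma_pass_rate_pct"], 1)
            row[f"{oar}_limit_ok"] = not comp["limit_violated"]
        row["brain_v120_diff_cc"] = round(brain_v120["diff_cc"], 2)
        row["headroom_floor_gy"] = report["headroom_single_fraction"]["floor_gy"]
        rows.append(row)
        print(f"{name}: brainstem dD0.03cc {row['brainstem_d003cc_diff_pct']:+.2f}% "
              f"(gamma {row['brainstem_gamma_pct']}%), "
              f"brain V120Gy {row['brain_v120_diff_cc']:+.2f} cc")
    with open(out / "safety.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    v120 = [r["brain_v120_diff_cc"] for r in rows]
    print(f"\nbrain V120Gy increase: mean {sum(v120) / len(v120):+.2f} cc; "
          f"single-fraction headroom {rows[0]['headroom_floor_gy']} Gy "
          f"-> {out / 'safety.csv'}")


if __name__ == "__main__":
    main()
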