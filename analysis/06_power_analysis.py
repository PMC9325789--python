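"""Schoenfeld power analysis for the survival screen: given the observed
event counts in the low/high expression groups across the three cohorts,
what hazard ratio is detectable with 80% power at alpha = 0.05, and what
power do we have against moderate effects?

Reads the per-cohort Cox table written by 05_survival_meta.py.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from mmdep import hr_for_power, power_two_group


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    cox = pd.read_csv(args.results / "survival_percohort.tsv", sep="\t")
    out = {}
    for endpoint, sub in cox.groupby("endpoint"):
        # one representative gene per cohort: event counts vary little by gene
        per_gene = sub.groupby("gene")["n_events"].sum()
        n_events = int(per_gene.median())
        p_low = (sub["n_low"].sum()) / (sub["n_low"].sum() + sub["n_high"].sum())
        hr80 = hr_for_power(n_events, p_low, 0.8)
        out[endpoint] = {
            "n_events": n_events,
            "allocation_low": round(float(p_low), 3),
            "hr_detectable_80pct": round(hr80, 3),
            "power_hr_1.3": round(power_two_group(n_events, p_low, 1.3), 3),
            "power_hr_1.5": round(power_two_group(n_events, p_low, 1.5), 3),
        }
        print(f"{endpoint.upper()}: {n_events} events in the compared quartiles; "
              f"80% power reaches HR = {hr80:.2f}; "
              f"power at HR 1.3 = {out[endpoint]['power_hr_1.3']:.2f}, "
              f"at HR 1.5 = {out[endpoint]['power_hr_1.5']:.2f}")
    (args.results / "power.json").write_text(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
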