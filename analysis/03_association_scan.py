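#!/usr/bin/env python
"""Per-trait Cox association scans with FDR control.

For every retained, rank-normalized trait, fits Models I (crude),
II (age, sex, stage) and III (II + BMI, operation-to-sample time, operation
type, CRP) for all-cause and CRC-specific mortality, on the whole cohort
and excluding stage 4; q-values are Benjamini-Hochberg within each scan.

Writes results/scan/association_scan.tsv and a Manhattan-style plot.
"""

from pathlib import Path

import pandas as pd

from glycoprog.io import read_clinical_table, read_peak_table, write_table
from glycoprog.io import PipelineConfig
from glycoprog.pipeline import compute_traits, _manhattan_plot
from glycoprog.survival import ModelSpec, association_scan


def main() -> None:
    peaks = read_peak_table("results/data/peak_table.tsv")
    clinical = read_clinical_table("results/data/clinical.tsv")
    matrix, _ = compute_traits(peaks, PipelineConfig())
    out = Path("results/scan")
    out.mkdir(parents=True, exist_ok=True)
    scans = []
    for outcome in ("all", "crc"):
        for model in ("I", "II", "III"):
            for stratum in ("whole", "exclude_stage4"):
                spec = ModelSpec(model, outcome, stratum)
                scans.append(association_scan(matrix, clinical, spec))
    scan = pd.concat(scans, ignore_index=True)
    write_table(scan, out / "association_scan.tsv")
    _manhattan_plot(scan, out / "association_manhattan.png")
    ok = scan[scan["status"] == "ok"]
    hits = ok[ok["q"] < 0.05]
    print(f"{len(ok)} fits; {len(hits)} trait-model associations with q<0.05")
    top = (ok[(ok["model"] == "II") & (ok["outcome"] == "all")
              & (ok["stratum"] == "whole")]
           .nsmallest(5, "p")[["trait", "hr", "ci_low", "ci_high", "p", "q"]])
    print("top whole-sample Model II (all-cause) traits:")
    print(top.to_string(index=False, float_format=lambda v: f"{v:.3g}"))


if __name__ == "__main__":
    main()
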