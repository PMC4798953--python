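"""Collect the stage outputs under results/ into one summary JSON.

Reads the TSVs written by the earlier numbered scripts and assembles the
headline numbers: strain verdicts, distribution diagnostics of amplified
gene sets, and the FDR estimates of the three engines.
"""

import argparse
import json
from pathlib import Path

import pandas as pd


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--resultsdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = {}

    calls = pd.read_csv(args.resultsdir / "karyotype_calls.tsv", sep="\t")
    out["heterogeneous_chromosomes"] = calls.loc[
        calls["verdict"] == "heterogeneous", ["strain", "chromosome", "c_hat"]
    ].to_dict("records")

    dist = pd.read_csv(args.resultsdir / "distribution_summaries.tsv", sep="\t")
    out["distributions"] = dist.to_dict("records")

    fdr = pd.read_csv(args.resultsdir / "single_strain_fdr.tsv", sep="\t")
    out["single_strain_fdr"] = fdr.to_dict("records")

    series = pd.read_csv(args.resultsdir / "series_fdr.tsv", sep="\t")
    out["series_slope_fdr"] = series.to_dict("records")

    path = args.resultsdir / "summary.json"
    path.write_text(json.dumps(out, indent=2) + "\n")
    print(json.dumps(out, indent=2))
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
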