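"""Simulate the strain panel used by the downstream analyses.

Generates four full-genome strains with three replicates each —
a euploid control, a stable trisomy of chromosome XII, a stable tetrasomy
of chromosome VIII, and a strain whose chromosome V is a 50/50 subpopulation
mixture of 2 and 3 copies (effective copy 2.5) — and writes the gene tables
plus the ground-truth karyotypes under results/tables/.
"""

import argparse
import json
from pathlib import Path

import aneudose as ad

PANEL = {
    "euploid_ctrl": ad.KaryotypeSpec(2, {}),
    "trisomyXII": ad.KaryotypeSpec(2, {"XII": 3}),
    "tetrasomyVIII": ad.KaryotypeSpec(2, {"VIII": 4}),
    "mixtureV": ad.KaryotypeSpec(2, {"V": [(0.5, 2), (0.5, 3)]}),
}


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/tables"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    layout = ad.genome_layout()
    noise = ad.NoiseModel(sigma_dna=0.10, sigma_rna_range=(0.4, 0.8))
    truths = {}
    for i, (name, karyo) in enumerate(PANEL.items()):
        table, truth = ad.simulate_strain(
            layout, karyo, noise, n_replicates=3,
            seed=args.seed + i, strain=name,
        )
        ad.write_gene_table(table, args.outdir / f"{name}.tsv")
        truths[name] = {
            "effective_copies": {c: v for c, v in truth.effective_copies.items()
                                 if v != 2.0},
            "n_genes": len(truth.dose),
        }
        print(f"{name}: {len(table)} rows, aneuploid "
              f"{truths[name]['effective_copies'] or 'none'}")
    (args.outdir / "truth.json").write_text(json.dumps(truths, indent=2) + "\n")
    print(f"wrote gene tables and truth.json to {args.outdir}")


if __name__ == "__main__":
    main()
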