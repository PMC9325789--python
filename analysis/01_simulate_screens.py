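"""Generate the synthetic DepMap-like screen pair used by the rest of the
analysis: 2000 genes x (40 myeloma + 400 other) cell lines, with planted
non-essential, commonly essential and myeloma-specific essential genes.

Writes CRISPR/shRNA gene-effect CSVs (DepMap dialect), line metadata and
the ground-truth gene classes under results/data/.
"""

import argparse
import json
from pathlib import Path

from mmdep import ScreenTruth, simulate_screens, write_screen_matrix


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    ap.add_argument("--n-genes", type=int, default=2000)
    ap.add_argument("--n-mm-lines", type=int, default=40)
    ap.add_argument("--n-other-lines", type=int, default=400)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    truth = ScreenTruth()
    crispr, shrna, meta, truth = simulate_screens(
        args.n_genes, args.n_mm_lines, args.n_other_lines, truth, seed=args.seed
    )
    write_screen_matrix(crispr, args.out / "crispr_gene_effect.csv")
    write_screen_matrix(shrna, args.out / "shrna_gene_effect.csv")
    meta.lineage.rename_axis("line_id").reset_index().to_csv(
        args.out / "line_metadata.csv", index=False
    )
    (args.out / "screen_truth.json").write_text(
        json.dumps(
            {
                "seed": args.seed,
                "class_means": truth.class_means,
                "noise_sd": truth.noise_sd,
                "slope": truth.slope,
                "platform_sd": truth.platform_sd,
                "missing_rates": truth.missing_rates,
                "gene_classes": truth.gene_classes.to_dict(),
            },
            indent=1,
        )
    )

    counts = truth.gene_classes.value_counts().to_dict()
    print(f"wrote screens to {args.out}")
    print(f"  genes: {args.n_genes} ({counts})")
    print(f"  lines: {args.n_mm_lines} myeloma + {args.n_other_lines} other")
    print(f"  missing entries: CRISPR {crispr.n_missing}, shRNA {shrna.n_missing}")


if __name__ == "__main__":
    main()
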