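#!/usr/bin/env python
"""Generate the synthetic study inputs with planted ground truth.

Writes, under results/sim/:
  ripseq/   — 2000-gene NB count matrix, 3 IP vs 3 input replicates, 5% of
              genes enriched at log2FC = 3, plus design and truth tables
  proteome/ — 1000 protein groups, 6 bait vs 3 control LFQ intensities with
              MNAR dropout, 5% planted interactors at +3 log2 units
"""

from pathlib import Path

import pandas as pd

from ripscore import io as rio
from ripscore.synthetic import (
    ProtSimConfig,
    RipSimConfig,
    simulate_proteome,
    simulate_ripseq,
)

SEED = 20230916
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    rip_dir = OUT / "ripseq"
    rip_dir.mkdir(parents=True, exist_ok=True)
    cm, rip_truth = simulate_ripseq(RipSimConfig(n_genes=2000, seed=SEED))
    rio.write_count_matrix(cm, rip_dir / "counts.tsv")
    pd.DataFrame(
        {"sample": cm.samples, "condition": cm.condition, "replicate": cm.replicate}
    ).to_csv(rip_dir / "design.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"id": rip_truth.planted_ids,
         "effect": [rip_truth.effects[g] for g in rip_truth.planted_ids]}
    ).to_csv(rip_dir / "truth.tsv", sep="\t", index=False)
    print(f"RIP-seq: {cm.n_genes} genes x {cm.n_samples} samples, "
          f"{len(rip_truth.planted_ids)} planted enriched genes -> {rip_dir}")

    prot_dir = OUT / "proteome"
    prot_dir.mkdir(parents=True, exist_ok=True)
    table, prot_truth = simulate_proteome(ProtSimConfig(n_groups=1000, seed=SEED))
    rio.write_protein_groups(table, prot_dir / "proteinGroups.tsv")
    pd.DataFrame({"sample": table.samples, "group": table.group}).to_csv(
        prot_dir / "design.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"id": prot_truth.planted_ids,
         "effect": [prot_truth.effects[g] for g in prot_truth.planted_ids]}
    ).to_csv(prot_dir / "truth.tsv", sep="\t", index=False)
    missing = float((table.values == 0).mean())
    print(f"proteome: {table.n_groups} groups x {len(table.samples)} samples, "
          f"{len(prot_truth.planted_ids)} planted interactors, "
          f"{missing:.1%} values below detection -> {prot_dir}")


if __name__ == "__main__":
    main()
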