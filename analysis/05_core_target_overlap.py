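#!/usr/bin/env python
"""Overlap of the shipped core Ssd1 target list with the RIP-seq target flags.

The 11-gene core list (mRNAs bound by Ssd1 in all four published binding
datasets) ships with the package; each row carries a flag for whether the
gene was also called a RIP-seq target of the bait. Reports the overlap.
"""

from ripscore.datasets import eif2a_flagged_set, load_ssd1_core_table, ssd1_core_set
from ripscore.setstats import overlap_count


def main() -> None:
    table = load_ssd1_core_table()
    res = overlap_count(ssd1_core_set(), eif2a_flagged_set())
    print(f"core Ssd1 targets: {res.n}")
    print(f"also RIP-seq targets of the bait: {res.k} of {res.n}")
    shared = ", ".join(sorted(table.loc[table["eif2a_target"], "gene"]))
    print(f"shared genes: {shared}")


if __name__ == "__main__":
    main()
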