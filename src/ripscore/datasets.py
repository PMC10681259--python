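"""Small published fixtures shipped with the package.

The core Ssd1 target list is the intersection of four published Ssd1
binding datasets (three RIP studies and one CRAC study): 11 mRNAs bound in
all four, each flagged for whether it was also called an eIF2A RIP-seq
target. 8 of the 11 carry the flag.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .setstats import GeneSet

__all__ = ["load_ssd1_core_table", "ssd1_core_set", "eif2a_flagged_set"]


def load_ssd1_core_table() -> pd.DataFrame:
    """Core Ssd1 target table: gene, eif2a_target flag ('+'), function."""
    ref = resources.files("ripscore.data") / "ssd1_core_targets.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
    df["eif2a_target"] = df["eif2a_target"].astype(str).str.strip().eq("+")
    return df


def ssd1_core_set() -> GeneSet:
    df = load_ssd1_core_table()
    return GeneSet.from_iterable("ssd1_core", df["gene"])


def eif2a_flagged_set() -> GeneSet:
    df = load_ssd1_core_table()
    return GeneSet.from_iterable("eif2a_targets", df.loc[df["eif2a_target"], "gene"])
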