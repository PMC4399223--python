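"""Packaged data: the published 80-hairpin hit table.

The table lists every shRNA clone whose abundance change between T2 and
T14 passed FDR <= 0.01 in the mammosphere screen, with its target gene,
log2 fold-change, average log2 CPM, exact-test p-value and BH FDR.  It is
an input fixture (transcribed from the publication), not a derived
artifact of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_table1"]


def load_table1() -> pd.DataFrame:
    """The published hit table as a results-style DataFrame.

    Indexed by clone id with columns gene, logFC, logCPM, pvalue, fdr —
    directly consumable by :func:`hairpinscreen.calls.classify_hits`.
    """
    with resources.files("hairpinscreen.data").joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df = df.rename(columns={"PValue": "pvalue", "FDR": "fdr"})
    return df.set_index("clone_id")
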