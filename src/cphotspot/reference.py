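"""Published reference data shipped with the package.

``actinidiaceae_markers.tsv`` is the published table of twenty fast-evolving
non-coding plastid loci of Actinidiaceae (five genomes: three newly
sequenced species plus the two public kiwifruit plastomes): per locus the
input length range, aligned length L, variable-character count NS and
parsimony-informative count, together with the percentages as printed.

Three printed percentages are arithmetically inconsistent with the printed
counts in the source table (``trnC(GCA)-petN`` both percentages match the
neighbouring row's aligned length; the PIC percentages of
``rps16-trnQ(UUG)`` and ``petA-psbL`` do not reproduce from 11/1544 and
11/1010); :func:`load_marker_table` therefore reports both the printed
values and the recomputed ones, and flags agreement per row.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import percent_variability


def load_marker_table() -> pd.DataFrame:
    """The published marker table with recomputed percentage columns.

    Adds ``pct_vc`` and ``pct_pic`` (recomputed as 100*count/L, half-up,
    2 decimals) and a boolean ``printed_consistent`` that is True where the
    printed percentages equal the recomputed ones.
    """
    path = resources.files("cphotspot.data") / "actinidiaceae_markers.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    df["pct_vc"] = [
        percent_variability(ns, l) for ns, l in zip(df["n_vc"], df["aligned_length"])
    ]
    df["pct_pic"] = [
        percent_variability(ns, l) for ns, l in zip(df["n_pic"], df["aligned_length"])
    ]
    df["printed_consistent"] = (df["pct_vc"] == df["pct_vc_printed"]) & (
        df["pct_pic"] == df["pct_pic_printed"]
    )
    return df
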