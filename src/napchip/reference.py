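"""Published top-20 enriched-region table for AbfR1_Ms in *Metallosphaera
sedula* (genome-wide ChIP occupancy characterization).

Each row of the printed table gives the peak id, the peak length, the genic
context of the 60-bp region around the summit ("Intergenic" or "ORF", with a
trailing asterisk when that 60-bp region is entirely within the labelled
context), the replicate-averaged fold enrichment and the locus tags of the
genes covered by the peak. These values serve as worked-example inputs for
the classification and category statistics.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_top20_reference"]

# (peak_id, width_bp, context, fully_within, fold_enrichment, covered locus tags)
_TOP20_ROWS = [
    ("472q", 1551, "coding", False, 4.6, ("msed_2065", "msed_2066", "msed_2067")),
    ("463d", 1864, "coding", False, 4.6, ("msed_2031", "msed_2032")),
    ("233f", 928, "intergenic", True, 4.4, ("msed_0969", "msed_0970", "msed_0972")),
    ("89d", 1692, "intergenic", True, 4.2, ("msed_0413", "msed_0414", "msed_0415")),
    ("263b", 816, "intergenic", False, 4.2, ("msed_1082", "msed_1083")),
    ("178d", 1239, "intergenic", True, 4.1, ("msed_0775", "msed_0776", "msed_0777")),
    ("198c", 1390, "intergenic", True, 4.0, ("msed_0850", "msed_0851")),
    ("84", 1310, "intergenic", True, 4.0, ("msed_0396", "msed_0397", "msed_0398")),
    ("221a", 1110, "intergenic", True, 3.8, ("msed_0933", "msed_0934")),
    ("344a", 1492, "intergenic", True, 3.8, ("msed_1382", "msed_1383")),
    ("122b", 841, "intergenic", True, 3.6, ("msed_0504", "msed_0505")),
    ("45d", 1560, "intergenic", True, 3.6, ("msed_0257", "msed_0258")),
    ("135e", 1032, "coding", True, 3.6, ("msed_0558", "msed_0559")),
    ("366a", 1877, "coding", True, 3.6,
     ("msed_1484", "msed_1485", "msed_1486", "msed_1487")),
    ("264", 637, "intergenic", True, 3.5, ("msed_1091", "msed_1092")),
    ("34c", 842, "coding", True, 3.5, ("msed_0183", "msed_0184")),
    ("168a", 1836, "coding", False, 3.5, ("msed_0747", "msed_0748", "msed_0749")),
    ("68b", 1304, "intergenic", True, 3.5, ("msed_0353", "msed_0354", "msed_0355")),
    ("268a", 1545, "intergenic", False, 3.4, ("msed_1116", "msed_1117")),
    ("148d", 1280, "intergenic", True, 3.3, ("msed_0631", "msed_0632")),
]


def load_top20_reference() -> pd.DataFrame:
    """The published top-20 enriched-region table as a DataFrame with
    columns peak_id, width_bp, context, window_fully_in_context,
    fold_enrichment, covered_genes (tuple of locus tags)."""
    return pd.DataFrame(
        _TOP20_ROWS,
        columns=["peak_id", "width_bp", "context", "window_fully_in_context",
                 "fold_enrichment", "covered_genes"],
    )
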