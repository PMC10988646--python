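"""Packaged reference data: the AD-gene panel, the resilience miRNA set,
and the published per-group contingency tables of the study cohort.

These are the small printed inputs the analysis runs against offline —
nothing here is downloaded or derived from raw sequencing data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "gene_panel",
    "resilience_mirnas",
    "cohort_contingency_tables",
    "GROUP_LABELS",
]

GROUP_LABELS = ("I-II", "III", "IV")

# 16 AD-relevant genes probed for miRNA binding sites, with RefSeq
# accessions and pathway category.
_GENE_PANEL = [
    ("ADAM10", "NM_001110.4", "Amyloid associated"),
    ("ADAM17", "NM_003183.6", "Amyloid associated"),
    ("APP", "NM_000484.4", "Amyloid associated"),
    ("BACE1", "NM_012104.6", "Amyloid associated"),
    ("CDK5", "NM_004935.4", "Tau associated"),
    ("GSK3A", "NM_019884.3", "Tau associated"),
    ("GSK3B", "NM_002093.4", "Tau associated"),
    ("MAPT", "NM_001377265.1", "Tau associated"),
    ("MME", "NM_007288.3", "Amyloid associated"),
    ("PSEN1", "NM_000021.4", "Amyloid associated"),
    ("PSEN2", "NM_000447.3", "Amyloid associated"),
    ("REST", "NM_001363453.2", "Transcription factor"),
    ("MAPK13", "NM_002754.5", "Tau associated"),
    ("IL1A", "NM_000575.5", "Cytokine"),
    ("IL1B", "NM_000576.3", "Cytokine"),
    ("IL6", "NM_000600.5", "Cytokine"),
]


def gene_panel() -> pd.DataFrame:
    """The default 16-gene AD pathway panel (gene, accession, category)."""
    return pd.DataFrame(_GENE_PANEL, columns=["gene", "accession", "category"])


# miRNAs differentially expressed between low (I/II) and high (III/IV)
# Braak-stage groups in cognitively intact elders; each named cluster is
# one entry.
_RESILIENCE = [
    ("miR-12121", "up"),
    ("miR-134", "up"),
    ("miR-3137", "up"),
    ("miR-4528", "up"),
    ("miR-4639-3p/548a-3p", "up"),
    ("miR-4705", "up"),
    ("miR-5692b", "up"),
    ("miR-617", "up"),
    ("miR-12118", "down"),
    ("miR-1320/8061", "down"),
    ("miR-4521", "down"),
    ("miR-548aj-5p", "down"),
]


def resilience_mirnas() -> pd.DataFrame:
    """The 12 resilience-related miRNAs (8 up-, 4 down-regulated)."""
    return pd.DataFrame(_RESILIENCE, columns=["mirna", "direction"])


def cohort_contingency_tables() -> dict[str, pd.DataFrame]:
    """Published per-group categorical counts of the 26-subject cohort.

    Rows are Braak-stage groups I-II / III / IV; columns the variable's
    levels.  These printed counts drive the chi-square comparisons
    offline (sex p ~= 0.84, ApoE ~= 0.28, CERAD ~= 0.16,
    NIA-Reagan < 0.01).
    """
    idx = pd.Index(GROUP_LABELS, name="group")
    return {
        "sex": pd.DataFrame(
            np.array([[4, 4], [3, 5], [5, 5]]), index=idx, columns=["male", "female"]
        ),
        "apoe": pd.DataFrame(
            np.array([[1, 4, 3], [0, 7, 1], [3, 5, 2]]),
            index=idx,
            columns=["e2/e3", "e3/e3", "e3/e4"],
        ),
        "cerad": pd.DataFrame(
            np.array([[1, 1, 2, 4], [0, 2, 1, 5], [2, 6, 0, 2]]),
            index=idx,
            columns=["Definite", "Probable", "Possible", "No AD"],
        ),
        "nia_reagan": pd.DataFrame(
            np.array([[1, 7], [2, 6], [8, 2]]),
            index=idx,
            columns=["Intermediate", "Low"],
        ),
    }
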