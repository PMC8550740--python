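"""Bundled datasets.

`load_uganda_counts` returns the host-plant x species count matrix
transcribed from the published July-August 2013 countrywide Uganda whitefly
survey (870 mtCO1-typed adult whiteflies over 59 host rows, previously
described plus novel putative species). The transcription was checksummed
against every printed row and column total.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: High-level genetic group (HLGG) of every species column in the bundled
#: survey matrix. SSA1 subgroup columns share SSA1's placement.
HLGG_OF_SPECIES = {
    "SSA1-SG1": "SSA",
    "SSA1-SG2": "SSA",
    "SSA1-SG3": "SSA",
    "SSA2": "SSA",
    "SSA6": "SSA",
    "SSA9": "SSA",
    "SSA16": "SSA",
    "SSA10": "New World",
    "SSA14": "New World",
    "SSA15": "New World",
    "SSA11": "Africa-Middle East-Asia Minor",
    "SSA12": "Africa-Middle East-Asia Minor",
    "SSA13": "Africa-Middle East-Asia Minor",
    "MED-ASL": "Africa-Middle East-Asia Minor",
    "MED-Q1": "Africa-Middle East-Asia Minor",
    "MEAM1": "Africa-Middle East-Asia Minor",
    "MEAM2": "Africa-Middle East-Asia Minor",
    "IO": "Africa-Middle East-Asia Minor",
    "EA1": "Africa-Middle East-Asia Minor",
    "B. Uganda1": "Uganda",
    "B. Uganda2": "Uganda",
    "B. Uganda3": "Uganda",
    "B. Uganda4": "Uganda",
    "B. Uganda5": "Uganda",
}


def load_uganda_counts(collapse_subgroups: bool = False) -> pd.DataFrame:
    """Host x species counts of the 2013 Uganda survey (grand total 870).

    With collapse_subgroups=True the three SSA1 subgroup columns are summed
    into a single SSA1 column.
    """
    path = resources.files("coidiv") / "data" / "uganda_2013_survey_counts.tsv"
    df = pd.read_csv(str(path), sep="\t")
    df = df.set_index("host_scientific")
    counts = df.drop(columns=["host_common", "host_family"]).astype(int)
    if collapse_subgroups:
        sg = [c for c in counts.columns if c.startswith("SSA1-SG")]
        counts.insert(0, "SSA1", counts[sg].sum(axis=1))
        counts = counts.drop(columns=sg)
    return counts


def clade_subtotals(counts: pd.DataFrame) -> pd.Series:
    """Total classified flies per high-level genetic group."""
    totals: dict[str, int] = {}
    for col in counts.columns:
        hlgg = HLGG_OF_SPECIES.get(col, HLGG_OF_SPECIES.get(col.split("-SG")[0], None))
        if hlgg is None and col == "SSA1":
            hlgg = "SSA"
        if hlgg is None:
            raise KeyError(f"unknown species column {col}")
        totals[hlgg] = totals.get(hlgg, 0) + int(counts[col].sum())
    return pd.Series(totals)
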