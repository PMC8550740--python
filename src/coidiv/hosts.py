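"""Host-plant association analyses over species-assigned survey records.

Builds host x species count matrices (hosts never visited by a whitefly are
explicit zero rows, not missing), species composition percentages, the
minimum-support association table (associations backed by at least `min_n`
flies), and the mixed-sample fraction (multi-fly field samples containing
more than one species).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assign import AssignmentReport, SpeciesAssignment
from .seq_io import CollectionRecord


def _species_column(a: SpeciesAssignment, collapse_subgroups: bool) -> str:
    if a.subgroup and not collapse_subgroups:
        return f"{a.call}-{a.subgroup}"
    return a.call


def build_count_matrix(
    records: list[CollectionRecord],
    report: AssignmentReport,
    collapse_subgroups: bool = False,
) -> pd.DataFrame:
    """Tally assigned flies into a hosts x species integer matrix.

    Every assignment's seq_id must belong to exactly one record (orphans
    raise, listing the ids). Rows cover every host present in the records,
    including hosts whose flies all failed QC: absence is an explicit 0.
    """
    fly_to_host: dict[str, str] = {}
    for rec in records:
        for wid in rec.whitefly_ids:
            fly_to_host[wid] = rec.host_scientific
    orphans = [a.seq_id for a in report.assignments if a.seq_id not in fly_to_host]
    if orphans:
        raise ValueError(f"assignments with no collection record: {orphans}")

    hosts = sorted({rec.host_scientific for rec in records})
    species = sorted({_species_column(a, collapse_subgroups) for a in report.assignments})
    matrix = pd.DataFrame(0, index=hosts, columns=species, dtype=int)
    for a in report.assignments:
        matrix.loc[fly_to_host[a.seq_id], _species_column(a, collapse_subgroups)] += 1
    assert int(matrix.to_numpy().sum()) == len(report.assignments)
    return matrix


def composition_percentages(matrix: pd.DataFrame) -> pd.Series:
    """Per-species percentage of all classified flies; sums to 100 exactly
    pre-rounding."""
    total = matrix.to_numpy().sum()
    if total == 0:
        raise ValueError("composition undefined for an all-zero matrix")
    return 100.0 * matrix.sum(axis=0) / total


def min_support_table(matrix: pd.DataFrame, min_n: int = 3) -> pd.DataFrame:
    """Keep only host x species cells supported by at least `min_n` flies.

    Cells below the support floor are zeroed; hosts with no surviving cell
    are dropped. With min_n = 1 this is the identity on non-zero cells.
    """
    kept = matrix.where(matrix >= min_n, 0)
    return kept.loc[kept.sum(axis=1) > 0]


def mixed_sample_fraction(
    records: list[CollectionRecord],
    report: AssignmentReport,
) -> tuple[float, int, int]:
    """Fraction of multi-fly samples whose flies span more than one species.

    Only samples with >= 2 assigned flies are eligible (a sample with one
    surviving fly cannot show a mixture). Returns (fraction, n_mixed,
    n_eligible); raises if no sample is eligible. Subgroups within a species
    do not count as distinct species.
    """
    call_of = {a.seq_id: a.call for a in report.assignments}
    n_eligible = n_mixed = 0
    for rec in records:
        calls = {call_of[w] for w in rec.whitefly_ids if w in call_of}
        if len([w for w in rec.whitefly_ids if w in call_of]) < 2:
            continue
        n_eligible += 1
        if len(calls) > 1:
            n_mixed += 1
    if n_eligible == 0:
        raise ValueError("no sample has >= 2 assigned flies")
    return n_mixed / n_eligible, n_mixed, n_eligible


def load_count_matrix_tsv(path) -> pd.DataFrame:
    """Read a hosts x species count TSV (hosts in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    numeric = df.select_dtypes(include=[np.number]).astype(int)
    return numeric


def write_count_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")
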