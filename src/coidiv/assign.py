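"""Distance-based species assignment and novel-species delimitation.

A QC-passing 651-nt barcode is compared to every reference in the panel by
p-distance (pairwise deletion). If the minimum divergence is below the
threshold (default 4%, the community convention for the *Bemisia tabaci*
complex), the query takes the nearest reference's species label; otherwise
it is a novel putative species. Novel queries are then grouped among
themselves by single linkage at the same threshold, and each group is named
by the clade of its nearest reference: groups nearest a *B. tabaci*-complex
reference continue the SSA numbering (SSA14, SSA15, ...), groups nearest the
Uganda clade continue B. Uganda numbering.

Subgroup calls (e.g. SSA1 SG1/SG2/SG3, ~1-1.5% apart) are nearest-subgroup-
reference assignments with the margin to the runner-up reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .distances import UndefinedDistanceError, p_distance
from .qc import ReferencePanel

DEFAULT_THRESHOLD = 0.04

#: HLGG labels regarded as inside the B. tabaci species complex; novel
#: groups nearest these continue the SSA numbering.
TABACI_HLGGS = frozenset({"SSA", "Africa-Middle East-Asia Minor", "New World"})


@dataclass
class SpeciesAssignment:
    seq_id: str
    call: str                 # known species label or novel group label
    novel: bool
    nearest_ref: str
    min_divergence: float
    hlgg: str
    subgroup: str | None = None
    subgroup_margin: float | None = None
    tie: bool = False
    diagnostics: list[str] = field(default_factory=list)


class UnassignableError(ValueError):
    """Distance to every reference is undefined."""


def _ref_divergences(query_nt: str, panel: ReferencePanel) -> list[tuple[float, str]]:
    out = []
    for entry in panel.entries:
        try:
            p, _ = p_distance(query_nt, entry.window_nt)
        except UndefinedDistanceError:
            continue
        out.append((p, entry.id))
    return out


def assign_species(
    query_nt: str,
    panel: ReferencePanel,
    seq_id: str = "",
    threshold: float = DEFAULT_THRESHOLD,
) -> SpeciesAssignment:
    """Classify one trimmed barcode: known species iff min divergence < threshold.

    Ties at the minimum divergence are broken by lexicographic reference id
    and flagged. A query exactly at the threshold is novel (>= rule).
    """
    divs = _ref_divergences(query_nt, panel)
    if not divs:
        raise UnassignableError(f"{seq_id}: undefined distance to every reference")
    divs.sort()
    best_p = divs[0][0]
    tied = sorted(rid for p, rid in divs if p == best_p)
    nearest = panel.by_id(tied[0])
    tie = len(tied) > 1
    novel = best_p >= threshold
    return SpeciesAssignment(
        seq_id=seq_id,
        call="novel" if novel else nearest.species,
        novel=novel,
        nearest_ref=nearest.id,
        min_divergence=best_p,
        hlgg=nearest.hlgg,
        tie=tie,
        diagnostics=[f"tie among references {tied}"] if tie else [],
    )


def _next_index(existing: list[str], prefix_re: str) -> int:
    nums = [int(m.group(1)) for s in existing for m in [re.match(prefix_re, s)] if m]
    return max(nums, default=0) + 1


def cluster_novel(
    novel: list[SpeciesAssignment],
    seqs: dict[str, str],
    panel: ReferencePanel,
    threshold: float = DEFAULT_THRESHOLD,
) -> dict[str, str]:
    """Group novel queries by single linkage at < threshold and name groups.

    Returns seq_id -> group label. Groups whose nearest reference lies in
    the B. tabaci complex are named SSA<next>, others B. Uganda<next>,
    continuing the numbering already present in the panel. Group numbering
    is canonical: groups are ordered by their smallest member id, so input
    order does not affect labels.
    """
    if not novel:
        return {}
    for a in novel:
        if a.min_divergence < threshold:
            raise ValueError(f"{a.seq_id} is not novel at threshold {threshold}")
    ids = sorted(a.seq_id for a in novel)
    by_id = {a.seq_id: a for a in novel}
    if len(ids) == 1:
        groups = {ids[0]: 0}
    else:
        n = len(ids)
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                p, _ = p_distance(seqs[ids[i]], seqs[ids[j]])
                dm[i, j] = dm[j, i] = p
        z = linkage(squareform(dm, checks=False), method="single")
        # single linkage at strictly-below-threshold: merge iff p < threshold
        flat = fcluster(z, t=threshold - 1e-12, criterion="distance")
        groups = {sid: int(c) for sid, c in zip(ids, flat)}

    # canonical order: by smallest-id member
    cluster_members: dict[int, list[str]] = {}
    for sid, c in groups.items():
        cluster_members.setdefault(c, []).append(sid)
    ordered = sorted(cluster_members.values(), key=lambda members: min(members))

    panel_species = [e.species for e in panel.entries]
    next_ssa = _next_index(panel_species, r"SSA(\d+)$")
    next_ug = _next_index(panel_species, r"B\. Uganda(\d+)$")
    labels: dict[str, str] = {}
    for members in ordered:
        # clade of the group = clade of the nearest reference of its first member
        rep = by_id[min(members)]
        if rep.hlgg in TABACI_HLGGS:
            name = f"SSA{next_ssa}"
            next_ssa += 1
        else:
            name = f"B. Uganda{next_ug}"
            next_ug += 1
        for sid in members:
            labels[sid] = name
    return labels


def assign_subgroup(
    query_nt: str,
    subgroup_refs: list[tuple[str, str]],
) -> tuple[str | None, float | None, bool]:
    """Nearest-subgroup call among (subgroup_label, window_nt) references.

    Returns (label, margin to the second-best subgroup, tie flag); (None,
    None, False) when no subgroup references exist. Ties go to the
    lexicographically first label and are flagged.
    """
    if not subgroup_refs:
        return None, None, False
    scored = sorted(
        (p_distance(query_nt, nt)[0], label) for label, nt in subgroup_refs
    )
    best_p, best_label = scored[0]
    tie = len(scored) > 1 and scored[1][0] == best_p
    margin = (scored[1][0] - best_p) if len(scored) > 1 else None
    return best_label, margin, tie


@dataclass
class AssignmentReport:
    assignments: list[SpeciesAssignment]
    tally: dict[str, int]

    def __post_init__(self) -> None:
        assert sum(self.tally.values()) == len(self.assignments)


def assign_all(
    queries: dict[str, str],
    panel: ReferencePanel,
    threshold: float = DEFAULT_THRESHOLD,
    subgroup_refs: dict[str, list[tuple[str, str]]] | None = None,
) -> AssignmentReport:
    """Assign every QC-passing barcode and tally calls per species.

    `queries` maps seq_id -> trimmed 651-nt barcode. `subgroup_refs` maps a
    species label to its subgroup references. Unassignable queries are
    tallied under 'unassignable'. Novel queries are grouped and renamed via
    cluster_novel; their `call` carries the group label.
    """
    subgroup_refs = subgroup_refs or {}
    assignments: list[SpeciesAssignment] = []
    for sid in sorted(queries):
        try:
            a = assign_species(queries[sid], panel, seq_id=sid, threshold=threshold)
        except UnassignableError:
            assignments.append(
                SpeciesAssignment(
                    seq_id=sid, call="unassignable", novel=False, nearest_ref="",
                    min_divergence=float("nan"), hlgg="",
                    diagnostics=["undefined distance to every reference"],
                )
            )
            continue
        if not a.novel and a.call in subgroup_refs:
            label, margin, tie = assign_subgroup(queries[sid], subgroup_refs[a.call])
            a.subgroup, a.subgroup_margin = label, margin
            if tie:
                a.tie = True
                a.diagnostics.append("subgroup tie, lexicographic break")
        assignments.append(a)

    novel = [a for a in assignments if a.novel]
    labels = cluster_novel(novel, queries, panel, threshold=threshold)
    for a in novel:
        a.call = labels[a.seq_id]

    tally: dict[str, int] = {}
    for a in assignments:
        tally[a.call] = tally.get(a.call, 0) + 1
    return AssignmentReport(assignments=assignments, tally=tally)


def write_assignments_tsv(report: AssignmentReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tcall\tnovel\tsubgroup\tnearest_ref\tmin_divergence\t"
                 "subgroup_margin\thlgg\ttie\n")
        for a in report.assignments:
            fh.write(
                f"{a.seq_id}\t{a.call}\t{int(a.novel)}\t{a.subgroup or ''}\t"
                f"{a.nearest_ref}\t{a.min_divergence:.6f}\t"
                f"{'' if a.subgroup_margin is None else f'{a.subgroup_margin:.6f}'}\t"
                f"{a.hlgg}\t{int(a.tie)}\n"
            )


def write_tally_tsv(report: AssignmentReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("call\tn\n")
        for call in sorted(report.tally):
            fh.write(f"{call}\t{report.tally[call]}\n")
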