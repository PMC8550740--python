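"""NUMT / pseudogene / PCR-artefact screening of candidate barcode reads.

The filter cascade mirrors standard practice for Sanger-derived mtCO1
barcodes checked against a curated panel of mitogenome-derived references:

1. align each query to its nearest reference (shared k-mer count picks the
   reference; global alignment with free end gaps, match +1 / mismatch -1 /
   gap open -5 / gap extend -1);
2. reject queries with any indel inside the 651-nt barcode window — a
   frameshift there is diagnostic of a nuclear copy;
3. trim survivors to exactly 651 nt (217 codons) on the panel's window;
4. translate with the invertebrate mitochondrial code and reject any
   in-frame stop codon;
5. reject amino-acid substitutions at panel-invariant ("highly conserved")
   columns of the reference amino-acid profile.

Coordinates are 0-based half-open throughout. Gaps strictly inside the
window trigger rejection; flanking (primer-region) gaps are ignored since
flanks are trimmed away before translation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .seq_io import BarcodeSequence, GeneticCode, INVERT_MITO_CODE, translate

WINDOW_NT = 651
WINDOW_AA = WINDOW_NT // 3

PASS = "pass"
FAIL_INDEL = "fail_indel"
FAIL_STOP = "fail_premature_stop"
FAIL_CONSERVED = "fail_conserved_violation"
FAIL_LENGTH = "fail_length"
STATUSES = (PASS, FAIL_INDEL, FAIL_STOP, FAIL_CONSERVED, FAIL_LENGTH)

MIN_QUERY_LEN = 400
MIN_WINDOW_IDENTITY = 0.70
MIN_REF_WINDOW_COVERAGE = 0.90


def make_aligner(match: float = 1.0, mismatch: float = -1.0,
                 gap_open: float = -5.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    """Global aligner with free end gaps (overlap-style), deterministic."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aligner.open_end_gap_score = 0.0
    aligner.extend_end_gap_score = 0.0
    return aligner


@dataclass
class PanelEntry:
    id: str
    species: str
    hlgg: str
    nt: str
    window: tuple[int, int]  # barcode window on this entry's own coordinates

    @property
    def window_nt(self) -> str:
        return self.nt[self.window[0] : self.window[1]]


@dataclass
class ReferencePanel:
    """Species-labelled reference set with derived amino-acid profile.

    conserved_mask[j] is True iff every panel peptide agrees at window
    amino-acid column j (the strictest reading of "highly conserved").
    """

    entries: list[PanelEntry]
    aa_profile: list[str]
    conserved_mask: np.ndarray
    consensus_peptide: str
    code: GeneticCode = field(default_factory=lambda: INVERT_MITO_CODE)
    rejected: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise ValueError("a reference panel needs >= 2 aligned references")

    def by_id(self, ref_id: str) -> PanelEntry:
        for e in self.entries:
            if e.id == ref_id:
                return e
        raise KeyError(ref_id)


@dataclass
class QueryAlignment:
    """Pairwise alignment of a query against its nearest panel reference."""

    query_id: str
    ref: PanelEntry
    ref_row: str    # gapped reference row
    query_row: str  # gapped query row
    window_cols: list[int]          # alignment columns of reference window positions
    internal_gap_cols: list[int]    # in-window columns carrying an internal gap
    missing_window_positions: int   # window ref positions not covered by the query
    window_identity: float


@dataclass
class QCResult:
    seq_id: str
    status: str
    frame_offset: int = 0
    trimmed_nt: str | None = None
    peptide: str | None = None
    diagnostics: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status}")
        if self.status == PASS:
            assert self.trimmed_nt is not None and len(self.trimmed_nt) == WINDOW_NT
            assert self.peptide is not None and len(self.peptide) == WINDOW_AA


def _gapped_rows(alignment) -> tuple[str, str]:
    return str(alignment[0]), str(alignment[1])


def _map_to_anchor(aligner: Align.PairwiseAligner, anchor_nt: str, ref_nt: str,
                   anchor_window: tuple[int, int]) -> tuple[tuple[int, int] | None, str]:
    """Locate the anchor's barcode window on another reference.

    Returns ((start, end), "") on that reference's own coordinates, or
    (None, reason) if the reference cannot provide a gap-free, >=90%-covered
    copy of the window.
    """
    alignment = aligner.align(anchor_nt, ref_nt)[0]
    a_row, r_row = _gapped_rows(alignment)
    a_pos = r_pos = 0
    mapped: list[int | None] = [None] * len(anchor_nt)
    insertions_inside = 0
    for ca, cr in zip(a_row, r_row):
        if ca != "-" and cr != "-":
            mapped[a_pos] = r_pos
        if ca == "-" and anchor_window[0] < a_pos < anchor_window[1]:
            insertions_inside += 1
        if ca != "-":
            a_pos += 1
        if cr != "-":
            r_pos += 1
    window_map = mapped[anchor_window[0] : anchor_window[1]]
    covered = [m for m in window_map if m is not None]
    if len(covered) < MIN_REF_WINDOW_COVERAGE * (anchor_window[1] - anchor_window[0]):
        return None, f"covers only {len(covered)}/{WINDOW_NT} window positions"
    if len(covered) < WINDOW_NT or insertions_inside:
        return None, "indel inside the barcode window"
    start, end = covered[0], covered[-1] + 1
    if end - start != WINDOW_NT:
        return None, "window maps to a non-contiguous region"
    return (start, end), ""


def build_panel(
    refs: list[tuple[str, str, str, str]],
    window_anchor: str,
    window_start: int = 0,
    code: GeneticCode = INVERT_MITO_CODE,
    aligner: Align.PairwiseAligner | None = None,
) -> ReferencePanel:
    """Build a ReferencePanel from (id, species, hlgg, nt) tuples.

    The barcode window is fixed at ``[window_start, window_start + 651)`` on
    the anchor reference and located on every other reference by pairwise
    alignment. References that cannot supply a gap-free window at >= 90%
    coverage are rejected and listed in ``panel.rejected``.
    """
    if aligner is None:
        aligner = make_aligner()
    by_id = {r[0]: r for r in refs}
    if window_anchor not in by_id:
        raise ValueError(f"window anchor '{window_anchor}' not among references")
    anchor_nt = by_id[window_anchor][3]
    if window_start + WINDOW_NT > len(anchor_nt):
        raise ValueError("anchor too short for the 651-nt window at this offset")
    anchor_window = (window_start, window_start + WINDOW_NT)

    entries: list[PanelEntry] = []
    rejected: list[tuple[str, str]] = []
    for rid, species, hlgg, nt in refs:
        if "-" in nt:
            raise ValueError(f"reference {rid} contains gaps; provide ungapped sequences")
        if not species:
            raise ValueError(f"reference {rid} has an empty species label")
        if rid == window_anchor:
            window = anchor_window
        else:
            window, reason = _map_to_anchor(aligner, anchor_nt, nt, anchor_window)
            if window is None:
                rejected.append((rid, reason))
                continue
        entries.append(PanelEntry(id=rid, species=species, hlgg=hlgg, nt=nt, window=window))

    if len(entries) < 2:
        raise ValueError(f"fewer than 2 alignable references (rejected: {rejected})")

    aa_profile = []
    for e in entries:
        pep, stops = translate(e.window_nt, 0, code)
        if stops:
            raise ValueError(f"reference {e.id} has in-frame stops in the barcode window")
        aa_profile.append(pep)
    profile = np.array([list(p) for p in aa_profile])
    conserved_mask = np.all(profile == profile[0], axis=0)
    consensus = "".join(
        Counter(profile[:, j]).most_common(1)[0][0] for j in range(WINDOW_AA)
    )
    return ReferencePanel(
        entries=entries,
        aa_profile=aa_profile,
        conserved_mask=conserved_mask,
        consensus_peptide=consensus,
        code=code,
        rejected=rejected,
    )


def _kmer_set(nt: str, k: int) -> set[str]:
    return {nt[i : i + k] for i in range(len(nt) - k + 1)}


def nearest_reference(query_nt: str, panel: ReferencePanel, k: int = 8) -> PanelEntry:
    """Reference sharing the most k-mers; ties broken by lexicographic id."""
    qk = _kmer_set(query_nt, k)
    best = max(
        panel.entries,
        key=lambda e: (len(qk & _kmer_set(e.nt, k)), e.id),
    )
    # max with tuple key prefers the lexicographically LARGEST id on ties;
    # re-scan for the smallest id among the top scorers instead.
    top = len(qk & _kmer_set(best.nt, k))
    tied = [e for e in panel.entries if len(qk & _kmer_set(e.nt, k)) == top]
    return min(tied, key=lambda e: e.id)


def align_query(
    query: BarcodeSequence,
    panel: ReferencePanel,
    aligner: Align.PairwiseAligner | None = None,
) -> QueryAlignment:
    """Globally align a query against its k-mer-nearest panel reference."""
    if len(query.nt) < MIN_QUERY_LEN:
        raise ValueError(f"{query.id}: query shorter than {MIN_QUERY_LEN} nt")
    if aligner is None:
        aligner = make_aligner()
    ref = nearest_reference(query.nt, panel)
    alignment = aligner.align(ref.nt, query.nt)[0]
    r_row, q_row = _gapped_rows(alignment)

    wstart, wend = ref.window
    q_chars = [i for i, c in enumerate(q_row) if c != "-"]
    q_first, q_last = q_chars[0], q_chars[-1]

    window_cols: list[int] = []
    internal_gaps: list[int] = []
    missing = 0
    matches = comparable = 0
    r_pos = 0
    for col, (cr, cq) in enumerate(zip(r_row, q_row)):
        if cr == "-":
            # insertion in the query relative to the reference
            if wstart < r_pos < wend and q_first <= col <= q_last:
                internal_gaps.append(col)
            continue
        if wstart <= r_pos < wend:
            window_cols.append(col)
            if cq == "-":
                if q_first < col < q_last:
                    internal_gaps.append(col)
                else:
                    missing += 1
            else:
                comparable += 1
                if cq == cr:
                    matches += 1
        r_pos += 1

    identity = matches / comparable if comparable else 0.0
    return QueryAlignment(
        query_id=query.id,
        ref=ref,
        ref_row=r_row,
        query_row=q_row,
        window_cols=window_cols,
        internal_gap_cols=internal_gaps,
        missing_window_positions=missing,
        window_identity=identity,
    )


def screen_indels(aln: QueryAlignment) -> str:
    """PASS or FAIL_INDEL: any internal gap column inside the window fails."""
    return FAIL_INDEL if aln.internal_gap_cols else PASS


def trim_to_barcode(aln: QueryAlignment) -> tuple[str, int]:
    """Extract the 651-nt barcode window from the query row.

    Requires an indel-free window; raises if the query does not span it.
    The frame offset is 0 by construction of the panel window.
    """
    if aln.internal_gap_cols:
        raise ValueError("trim requires an indel-free window")
    if aln.missing_window_positions:
        raise ValueError(
            f"query covers only {WINDOW_NT - aln.missing_window_positions}/{WINDOW_NT} "
            "window positions"
        )
    trimmed = "".join(aln.query_row[c] for c in aln.window_cols)
    assert len(trimmed) == WINDOW_NT
    return trimmed, 0


def screen_peptide(trimmed_nt: str, panel: ReferencePanel, seq_id: str = "") -> QCResult:
    """Translate the trimmed barcode and apply the stop / conserved screens."""
    if len(trimmed_nt) != WINDOW_NT:
        raise ValueError(f"expected {WINDOW_NT} nt, got {len(trimmed_nt)}")
    peptide, stops = translate(trimmed_nt, 0, panel.code)
    if stops:
        return QCResult(
            seq_id=seq_id,
            status=FAIL_STOP,
            diagnostics=[(i, "premature stop codon") for i in stops],
        )
    violations = [
        j
        for j in range(WINDOW_AA)
        if panel.conserved_mask[j]
        and peptide[j] != "X"
        and peptide[j] != panel.consensus_peptide[j]
    ]
    if violations:
        return QCResult(
            seq_id=seq_id,
            status=FAIL_CONSERVED,
            diagnostics=[
                (j, f"substitution {panel.consensus_peptide[j]}->{peptide[j]} at conserved column")
                for j in violations
            ],
        )
    return QCResult(
        seq_id=seq_id, status=PASS, frame_offset=0, trimmed_nt=trimmed_nt, peptide=peptide
    )


def qc_single(query: BarcodeSequence, panel: ReferencePanel,
              aligner: Align.PairwiseAligner | None = None) -> QCResult:
    if len(query.nt) < MIN_QUERY_LEN:
        return QCResult(
            seq_id=query.id, status=FAIL_LENGTH,
            diagnostics=[(len(query.nt), f"query shorter than {MIN_QUERY_LEN} nt")],
        )
    aln = align_query(query, panel, aligner)
    if aln.window_identity < MIN_WINDOW_IDENTITY:
        return QCResult(
            seq_id=query.id, status=FAIL_LENGTH,
            diagnostics=[(0, f"unalignable: window identity {aln.window_identity:.2f} < "
                             f"{MIN_WINDOW_IDENTITY}")],
        )
    if screen_indels(aln) == FAIL_INDEL:
        return QCResult(
            seq_id=query.id, status=FAIL_INDEL,
            diagnostics=[(c, "gap column inside barcode window") for c in aln.internal_gap_cols],
        )
    if aln.missing_window_positions:
        return QCResult(
            seq_id=query.id, status=FAIL_LENGTH,
            diagnostics=[(aln.missing_window_positions, "window positions not covered")],
        )
    trimmed, _frame = trim_to_barcode(aln)
    return screen_peptide(trimmed, panel, seq_id=query.id)


def qc_pipeline(
    queries: list[BarcodeSequence],
    panel: ReferencePanel,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[list[QCResult], dict[str, int]]:
    """Screen a batch; never aborts. Returns per-sequence results + tally."""
    if aligner is None:
        aligner = make_aligner()
    results = [qc_single(q, panel, aligner) for q in queries]
    summary = {status: 0 for status in STATUSES}
    for r in results:
        summary[r.status] += 1
    assert sum(summary.values()) == len(queries)
    return results, summary
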