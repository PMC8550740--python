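"""NUMT/pseudogene screening: panel construction and the filter cascade."""

import numpy as np
import pytest

from coidiv import qc, simulate
from coidiv.qc import (
    FAIL_CONSERVED,
    FAIL_INDEL,
    FAIL_LENGTH,
    FAIL_STOP,
    PASS,
    align_query,
    build_panel,
    qc_pipeline,
    screen_indels,
    screen_peptide,
    trim_to_barcode,
)
from coidiv.seq_io import BarcodeSequence, translate


def _refs_from(nts, species=None, hlgg="SSA"):
    species = species or [f"SSA{i+1}" for i in range(len(nts))]
    return [(f"R{i}", sp, hlgg, nt) for i, (sp, nt) in enumerate(zip(species, nts))]


class TestBuildPanel:
    def test_identical_references_conserved_everywhere(self, seed_orf):
        panel = build_panel(_refs_from([seed_orf] * 3), window_anchor="R0")
        assert panel.conserved_mask.all()
        assert panel.conserved_mask.shape == (qc.WINDOW_AA,)

    def test_single_aa_difference_unmasks_one_column(self, seed_orf):
        # force a nonsynonymous change in codon 40 only
        codon = seed_orf[120:123]
        for base in "ACGT":
            trial = codon[0] + base + codon[2]
            pep0 = translate(codon, 0)[0]
            if trial not in ("TAA", "TAG") and translate(trial, 0)[0] != pep0:
                other = seed_orf[:121] + base + seed_orf[122:]
                break
        panel = build_panel(_refs_from([seed_orf, other]), window_anchor="R0")
        assert not panel.conserved_mask[40]
        assert panel.conserved_mask.sum() == qc.WINDOW_AA - 1

    def test_mask_matches_direct_column_scan(self, panel):
        profile = np.array([list(p) for p in panel.aa_profile])
        direct = np.array(
            [len(set(profile[:, j])) == 1 for j in range(qc.WINDOW_AA)]
        )
        assert (panel.conserved_mask == direct).all()

    def test_fewer_than_two_refs_rejected(self, seed_orf):
        with pytest.raises(ValueError, match="2"):
            build_panel(_refs_from([seed_orf]), window_anchor="R0")

    def test_unalignable_reference_reported(self, seed_orf):
        rng = np.random.default_rng(0)
        garbage = "".join(rng.choice(list("ACGT"), 651))
        panel = build_panel(
            _refs_from([seed_orf, seed_orf, garbage]), window_anchor="R0"
        )
        assert len(panel.entries) == 2
        assert panel.rejected and panel.rejected[0][0] == "R2"


class TestAlignAndTrim:
    def test_identical_query_zero_gaps_full_identity(self, panel):
        entry = panel.entries[0]
        aln = align_query(BarcodeSequence(id="q", nt=entry.window_nt), panel)
        assert aln.ref.id == entry.id
        assert aln.internal_gap_cols == []
        assert aln.window_identity == 1.0
        trimmed, frame = trim_to_barcode(aln)
        assert trimmed == entry.window_nt and frame == 0

    def test_one_deleted_base_one_gap_column(self, panel):
        nt = panel.entries[0].window_nt
        query = nt[:300] + nt[301:]
        aln = align_query(BarcodeSequence(id="q", nt=query), panel)
        assert len(aln.internal_gap_cols) == 1
        assert screen_indels(aln) == FAIL_INDEL

    def test_flanking_sequence_maps_window_to_interior(self, seed_orf):
        rng = np.random.default_rng(3)
        flank5 = "".join(rng.choice(list("ACGT"), 20))
        flank3 = "".join(rng.choice(list("ACGT"), 20))
        refs = _refs_from([flank5 + seed_orf + flank3, flank5 + seed_orf + flank3])
        panel = build_panel(refs, window_anchor="R0", window_start=20)
        # amplicon-style query: extra flanks, no internal gaps
        query = BarcodeSequence(id="q", nt=flank5 + seed_orf + flank3)
        aln = align_query(query, panel)
        assert aln.internal_gap_cols == []
        trimmed, _ = trim_to_barcode(aln)
        assert trimmed == seed_orf

    def test_query_missing_window_tail_fails_length(self, panel):
        nt = panel.entries[0].window_nt[:-10]
        res = qc.qc_single(BarcodeSequence(id="q", nt=nt), panel)
        assert res.status == FAIL_LENGTH

    def test_short_query_fails_length(self, panel):
        res = qc.qc_single(BarcodeSequence(id="q", nt="ACGT" * 50), panel)
        assert res.status == FAIL_LENGTH


class TestScreenPeptide:
    def test_panel_members_pass_their_own_panel(self, panel):
        for entry in panel.entries:
            res = screen_peptide(entry.window_nt, panel, seq_id=entry.id)
            assert res.status == PASS
            assert len(res.peptide) == qc.WINDOW_AA

    def test_planted_stop_at_codon_50(self, panel):
        nt = panel.entries[0].window_nt
        mutated = nt[:150] + "TAA" + nt[153:]
        res = screen_peptide(mutated, panel)
        assert res.status == FAIL_STOP
        assert res.diagnostics[0][0] == 50

    def test_nonstop_substitution_at_conserved_column(self, panel):
        nt = panel.entries[0].window_nt
        col = int(np.flatnonzero(panel.conserved_mask)[10])
        codon = nt[3 * col : 3 * col + 3]
        pep0 = panel.consensus_peptide[col]
        mutated = None
        for pos in range(3):
            for base in "ACGT":
                trial = codon[:pos] + base + codon[pos + 1 :]
                if trial in ("TAA", "TAG") or trial == codon:
                    continue
                if translate(trial, 0)[0] != pep0:
                    mutated = nt[: 3 * col] + trial + nt[3 * col + 3 :]
                    break
            if mutated:
                break
        res = screen_peptide(mutated, panel)
        assert res.status == FAIL_CONSERVED
        assert res.diagnostics[0][0] == col


class TestPipeline:
    def test_clean_plus_frameshifted_batch(self, panel):
        queries, _ = simulate.simulate_queries(panel, 2, 0.01, seed=4)
        numts, truth = simulate.simulate_numts(panel, 4, indel_p=1.0, stop_p=0.0, seed=5)
        batch = [BarcodeSequence(id=k, nt=v) for k, v in {**queries, **numts}.items()]
        results, summary = qc_pipeline(batch, panel)
        assert summary[PASS] == len(queries)
        assert summary[FAIL_INDEL] == len(numts)
        assert sum(summary.values()) == len(batch)

    def test_empty_batch(self, panel):
        results, summary = qc_pipeline([], panel)
        assert results == [] and sum(summary.values()) == 0

    def test_all_numt_batch_zero_passes(self, panel):
        numts, _ = simulate.simulate_numts(panel, 10, indel_p=0.5, stop_p=0.5, seed=6)
        _, summary = qc_pipeline(
            [BarcodeSequence(id=k, nt=v) for k, v in numts.items()], panel
        )
        assert summary[PASS] == 0

    def test_determinism(self, panel):
        queries, _ = simulate.simulate_queries(panel, 3, 0.01, seed=7)
        batch = [BarcodeSequence(id=k, nt=v) for k, v in queries.items()]
        r1, s1 = qc_pipeline(batch, panel)
        r2, s2 = qc_pipeline(batch, panel)
        assert s1 == s2
        assert [(a.seq_id, a.status, a.trimmed_nt) for a in r1] == [
            (a.seq_id, a.status, a.trimmed_nt) for a in r2
        ]
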