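"""Generator ground truth: divergence targets, defect planting, survey design."""

import numpy as np
import pytest

from coidiv import qc, simulate
from coidiv.distances import p_distance
from coidiv.seq_io import BarcodeSequence, translate
from coidiv.simulate import SimulationConfig, default_host_profiles


class TestPanel:
    def test_pairwise_divergence_near_target(self, panel_and_refs):
        panel, refs = panel_and_refs
        for i in range(len(refs)):
            for j in range(i + 1, len(refs)):
                p, _ = p_distance(refs[i][3], refs[j][3])
                assert 0.07 <= p <= 0.09

    def test_panel_passes_its_own_qc(self, panel):
        batch = [BarcodeSequence(id=e.id, nt=e.window_nt) for e in panel.entries]
        _, summary = qc.qc_pipeline(batch, panel)
        assert summary[qc.PASS] == len(panel.entries)

    def test_references_are_stop_free(self, panel_and_refs):
        _, refs = panel_and_refs
        for _rid, _sp, _hlgg, nt in refs:
            _, stops = translate(nt, 0)
            assert stops == []

    def test_single_species_panel_rejected(self):
        with pytest.raises(ValueError):
            simulate.simulate_panel(SimulationConfig(seed=1, n_species=1))


class TestQueries:
    def test_zero_intra_gives_identical_queries(self, panel):
        queries, truth = simulate.simulate_queries(panel, 3, 0.0, seed=1)
        windows = {e.species: e.window_nt for e in panel.entries}
        for _, row in truth.iterrows():
            assert queries[row.seq_id] == windows[row.species]

    def test_divergence_envelope(self, panel):
        queries, truth = simulate.simulate_queries(panel, 10, 0.01, seed=2)
        windows = {e.species: e.window_nt for e in panel.entries}
        for _, row in truth.iterrows():
            own, _ = p_distance(queries[row.seq_id], windows[row.species])
            assert own <= round(0.01 * 651) / 651
            for sp, nt in windows.items():
                if sp != row.species:
                    other, _ = p_distance(queries[row.seq_id], nt)
                    assert other >= 0.06

    def test_zero_queries(self, panel):
        queries, truth = simulate.simulate_queries(panel, 0, 0.01, seed=3)
        assert queries == {} and truth.empty


class TestNumts:
    def test_all_stop_defects_fail_stop_screen(self, panel):
        numts, truth = simulate.simulate_numts(panel, 12, indel_p=0.0, stop_p=1.0, seed=4)
        assert set(truth.defect) == {"premature_stop"}
        _, summary = qc.qc_pipeline(
            [BarcodeSequence(id=k, nt=v) for k, v in numts.items()], panel
        )
        assert summary[qc.FAIL_STOP] == 12

    def test_all_indel_defects_fail_indel_screen(self, panel):
        numts, truth = simulate.simulate_numts(panel, 12, indel_p=1.0, stop_p=0.0, seed=5)
        assert set(truth.defect) == {"indel"}
        _, summary = qc.qc_pipeline(
            [BarcodeSequence(id=k, nt=v) for k, v in numts.items()], panel
        )
        assert summary[qc.FAIL_INDEL] == 12

    def test_zero_numts(self, panel):
        numts, truth = simulate.simulate_numts(panel, 0, 1.0, 1.0, seed=6)
        assert numts == {} and truth.empty

    def test_zero_rates_rejected(self, panel):
        with pytest.raises(ValueError):
            simulate.simulate_numts(panel, 5, 0.0, 0.0, seed=7)


class TestSurvey:
    def _config(self, panel, **kw):
        species = [e.species for e in panel.entries]
        defaults = dict(
            seed=8, n_species=len(species), n_samples=60,
            host_profiles=default_host_profiles(species),
        )
        defaults.update(kw)
        return SimulationConfig(**defaults)

    def test_structure_and_truth_bookkeeping(self, panel):
        cfg = self._config(panel)
        records, barcodes, truth_flies, truth_matrix = simulate.simulate_survey(panel, cfg)
        assert len(records) == 60
        assert all(len(r.whitefly_ids) == 3 for r in records)
        assert len(barcodes) == 180
        assert int(truth_matrix.to_numpy().sum()) == 180
        # truth matrix agrees with the per-fly table
        pivot = truth_flies.pivot_table(
            index="host", columns="species", values="seq_id",
            aggfunc="count", fill_value=0,
        )
        for host in pivot.index:
            for sp in pivot.columns:
                assert truth_matrix.loc[host, sp] == pivot.loc[host, sp]

    def test_mixing_zero_gives_monospecific_samples(self, panel):
        cfg = self._config(panel, mixing_p=0.0)
        records, _, truth_flies, _ = simulate.simulate_survey(panel, cfg)
        by_sample = truth_flies.groupby("sample_id").species.nunique()
        assert (by_sample == 1).all()

    def test_mixing_flag_matches_composition(self, panel):
        cfg = self._config(panel, mixing_p=0.5)
        _, _, truth_flies, _ = simulate.simulate_survey(panel, cfg)
        for sid, grp in truth_flies.groupby("sample_id"):
            assert (grp.species.nunique() > 1) == bool(grp.mixed_sample.iloc[0])

    def test_specialist_dominates_own_host(self, panel):
        species = [e.species for e in panel.entries]
        cfg = self._config(
            panel, n_samples=240,
            host_profiles=default_host_profiles(species, specialist_weight=0.95),
        )
        _, _, _, truth_matrix = simulate.simulate_survey(panel, cfg)
        sp0, host0 = species[0], "host00"
        col = truth_matrix[sp0]
        assert col.idxmax() == host0

    def test_determinism(self, panel):
        cfg = self._config(panel)
        out1 = simulate.simulate_survey(panel, cfg)
        out2 = simulate.simulate_survey(panel, cfg)
        assert out1[1] == out2[1]
        assert out1[3].equals(out2[3])


class TestBlockMatrix:
    def test_shape_and_determinism(self):
        m1 = simulate.simulate_block_matrix(seed=5)
        m2 = simulate.simulate_block_matrix(seed=5)
        assert m1.shape == (16, 12)
        assert m1.equals(m2)

    def test_block_structure_dominates(self):
        m = simulate.simulate_block_matrix(seed=6)
        for b in range(4):
            block = m.iloc[4 * b : 4 * b + 4, 3 * b : 3 * b + 3]
            off = m.iloc[4 * b : 4 * b + 4].drop(columns=block.columns)
            assert block.to_numpy().mean() > 10 * max(off.to_numpy().mean(), 0.1)


def test_end_to_end_truth_recovery(panel):
    """qc -> assign -> count matrix reproduces the generator's truth matrix."""
    from coidiv.assign import assign_all
    from coidiv.hosts import build_count_matrix

    species = [e.species for e in panel.entries]
    cfg = SimulationConfig(
        seed=13, n_species=len(species), n_samples=50,
        host_profiles=default_host_profiles(species),
    )
    records, barcodes, truth_flies, truth_matrix = simulate.simulate_survey(panel, cfg)
    results, summary = qc.qc_pipeline(
        [BarcodeSequence(id=k, nt=v) for k, v in sorted(barcodes.items())], panel
    )
    assert summary[qc.PASS] == len(barcodes)
    passing = {r.seq_id: r.trimmed_nt for r in results}
    report = assign_all(passing, panel)
    matrix = build_count_matrix(records, report)
    aligned = matrix.reindex(index=truth_matrix.index, columns=truth_matrix.columns,
                             fill_value=0)
    assert aligned.equals(truth_matrix)
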