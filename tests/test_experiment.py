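import numpy as np
import pandas as pd
import pytest

from symcoev.dynamics import SimParams
from symcoev.experiment import (ParameterGrid, analysis_bin, read_results,
                                run_canonical_study, run_grid,
                                summarize_by_bin, write_results)
from symcoev.matrices import make_gfg_master


@pytest.fixture(scope="module")
def tiny_grid_result(random_masters_module):
    from symcoev.sampling import (MatrixEnsemble, MatrixRecord,
                                  _projection_batch, specificity_bin)
    from symcoev.specificity import specificity_2x2_batch

    records = []
    for i, m in enumerate(random_masters_module):
        scores = {k: float(specificity_2x2_batch(
            _projection_batch(m.entries[None], k))[0])
            for k in ("HP", "SP", "HS")}
        records.append(MatrixRecord(
            id=f"m{i:05d}", sampler="iud", entries=m.entries,
            S_HP=scores["HP"], S_SP=scores["SP"], S_HS=scores["HS"],
            bin=specificity_bin(scores["HP"])))
    ens = MatrixEnsemble(target_kind="HP", per_bin=0, rng_seed=778,
                         matrices=records)
    combos = [SimParams(s_H=0.5, s_P=0.5, c=c, v=v, tau=0.0,
                        n_generations=600, burn_in=300)
              for c in (0.05, 0.5) for v in (0.99, 1.0)]
    return run_grid(ens, combos, seed=3, n_random_inits=2)


@pytest.fixture(scope="module")
def random_masters_module():
    from symcoev.matrices import MasterMatrix
    from symcoev.sampling import _draw_accepted

    gen = np.random.default_rng(778)
    return [MasterMatrix(e) for e in _draw_accepted(gen, 5, "iud")]


class TestParameterGrid:
    def test_design_counts(self):
        grid = ParameterGrid()
        assert grid.n_fitness_combos == 27
        assert grid.n_combos == 108
        assert len(grid.combos(n_generations=100, burn_in=50)) == 108

    def test_nontrivial_excludes_cost_at_or_above_selection(self):
        combos = ParameterGrid().nontrivial_combos()
        assert all(p.c < p.s_H for p in combos)
        assert len(combos) == 72

    def test_representative_subset_spans_transmission_regimes(self):
        combos = ParameterGrid().representative_nontrivial(12)
        assert len(combos) == 12
        assert {p.tau for p in combos} == {0.0, 0.01}
        assert {p.v for p in combos} == {0.99, 1.0}
        assert len({(p.s_H, p.s_P, p.c) for p in combos}) >= 6


class TestRunGrid:
    def test_one_row_per_model(self, tiny_grid_result, random_masters_module):
        assert len(tiny_grid_result) == len(random_masters_module) * 4

    def test_full_grid_on_one_matrix_yields_108_rows(self, random_masters_module):
        df = run_grid(random_masters_module[:1],
                      ParameterGrid(), seed=0, n_random_inits=0,
                      n_generations=40, burn_in=20)
        assert len(df) == 108

    def test_trivial_combos_flagged_and_lose_symbionts(self, tiny_grid_result):
        trivial = tiny_grid_result[tiny_grid_result.trivial]
        assert (trivial.c >= trivial.s_H).all()
        assert (~trivial.both_symbiont_alleles).all()

    def test_determinism(self, random_masters_module):
        combos = [SimParams(s_H=0.5, s_P=0.5, c=0.05, n_generations=300,
                            burn_in=100)]
        a = run_grid(random_masters_module[:2], combos, seed=9, n_random_inits=3)
        b = run_grid(random_masters_module[:2], combos, seed=9, n_random_inits=3)
        pd.testing.assert_frame_equal(a, b)

    def test_checkpoint_resume_and_corruption_refusal(
            self, random_masters_module, tmp_path):
        combos = [SimParams(s_H=0.5, s_P=0.5, c=0.05, n_generations=200,
                            burn_in=100)]
        ck = tmp_path / "ck"
        a = run_grid(random_masters_module, combos, seed=1, n_random_inits=0,
                     checkpoint_dir=ck, chunk_size=2)
        files = sorted(ck.glob("chunk_*.csv"))
        assert files
        b = run_grid(random_masters_module, combos, seed=1, n_random_inits=0,
                     checkpoint_dir=ck, chunk_size=2)
        pd.testing.assert_frame_equal(a, b)
        files[0].write_text(files[0].read_text()[:-40])  # truncate: corrupt
        with pytest.raises(RuntimeError, match="corrupt"):
            run_grid(random_masters_module, combos, seed=1, n_random_inits=0,
                     checkpoint_dir=ck, chunk_size=2)


class TestSummaries:
    def test_analysis_binning_edges(self):
        scores = np.array([0.0, 1e-9, 0.05, 0.1, 0.15, 1.0])
        assert list(analysis_bin(scores)) == [0, 1, 1, 1, 2, 10]

    def test_canonical_matrices_land_in_expected_bins(self):
        from symcoev.matrices import make_canonical_square, project
        from symcoev.specificity import specificity_2x2

        s_ma = specificity_2x2(make_canonical_square("MA", 2)).index
        s_gfg = specificity_2x2(make_canonical_square("GFG", 2)).index
        assert analysis_bin(s_ma) == 10 and analysis_bin(s_gfg) == 0
        # symbiont-augmented masters: GFG stays non-specific in HP
        s_gfg_m = specificity_2x2(
            project(make_gfg_master(0.5), "HP").entries).index
        assert analysis_bin(s_gfg_m) == 0

    def test_identical_outcomes_give_identical_aggregates(self, tiny_grid_result):
        df = tiny_grid_result.copy()
        nontrivial = summarize_by_bin(df, "HP")
        occupied = nontrivial[nontrivial.n_models > 0]
        assert (occupied.frac_cycling.between(0, 1)).all()
        assert nontrivial.n_models.sum() == (~df.trivial).sum()
        assert nontrivial.attrs["n_excluded_trivial"] == int(df.trivial.sum())

    def test_stratified_summary(self, tiny_grid_result):
        strat = summarize_by_bin(tiny_grid_result, "SP", stratify=["v"])
        assert set(strat["v"]) == {0.99, 1.0}

    def test_empty_bins_reported_with_zero_count(self, tiny_grid_result):
        out = summarize_by_bin(tiny_grid_result, "HP")
        assert len(out) == 11
        assert (out.n_models >= 0).all()


@pytest.fixture(scope="module")
def tiny_canonical_report():
    return run_canonical_study(deltas=(0.4, 0.8), costs=(0.0, 0.1, 0.3),
                               seed=0, n_generations=3000, burn_in=1500)


class TestCanonicalStudy:
    def test_table_covers_all_cells(self, tiny_canonical_report):
        assert len(tiny_canonical_report["table"]) == 2 * 2 * 3
        assert set(tiny_canonical_report["table"].fate) <= {"fixed", "extinct", "polymorphic"}

    def test_cheap_symbionts_fix_and_ma_cycles(self, tiny_canonical_report):
        t = tiny_canonical_report["table"]
        cheap_ma = t[(t.model == "MA") & (t.c == 0.0)]
        assert (cheap_ma.fate == "fixed").all()
        assert cheap_ma.cycling.all()

    def test_gfg_stabilises(self, tiny_canonical_report):
        assert not tiny_canonical_report["table"].query("model == 'GFG'").cycling.any()

    def test_s2_more_common_in_gfg(self, tiny_canonical_report):
        kept = tiny_canonical_report["table"].query(
            "model == 'GFG' and fate != 'extinct'")
        assert (kept.mean_S2 >= kept.mean_S1).all()


class TestResultsIO:
    def test_roundtrip_identical(self, tiny_grid_result, tmp_path):
        path = tmp_path / "out.csv"
        write_results(tiny_grid_result, path, seed=3)
        back = read_results(path)
        pd.testing.assert_frame_equal(back, tiny_grid_result.reset_index(drop=True),
                                      check_exact=False, atol=1e-12)
        assert back.attrs["metadata"]["seed"] == 3

    def test_missing_seed_warns_but_loads(self, tiny_grid_result, tmp_path):
        path = tmp_path / "noseed.csv"
        write_results(tiny_grid_result, path)
        with pytest.warns(UserWarning, match="seed"):
            read_results(path)

    def test_checksum_detects_corruption(self, tiny_grid_result, tmp_path):
        path = tmp_path / "out.csv"
        write_results(tiny_grid_result, path, seed=0)
        text = path.read_text()
        path.write_text(text.replace("True", "False", 1))
        with pytest.raises(ValueError, match="checksum"):
            read_results(path)

    def test_schema_version_checked(self, tiny_grid_result, tmp_path):
        path = tmp_path / "out.csv"
        write_results(tiny_grid_result, path, seed=0)
        text = path.read_text().replace('"schema_version": 1',
                                        '"schema_version": 99')
        path.write_text(text)
        with pytest.raises(ValueError, match="schema"):
            read_results(path)
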