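"""Eight-filter screening funnel: matching rules, set filters, layer
selection, annotations, and the end-to-end workflow driver."""

import numpy as np
import pytest

from dbpscreen._data import load_dbp_peak_table, load_default_lser
from dbpscreen.io_core import Formula, MassSpectrum, PeakRecord
from dbpscreen.retention_modeling import ElutionPoint, kovats_index
from dbpscreen.screening_pipeline import (FunnelReport, MatchTolerance,
                                          WorkflowConfig, annotate_isotope_fit,
                                          annotate_ri_fit,
                                          evaluate_elution_concordance,
                                          filter_match_threshold, records_match,
                                          run_workflow, select_best_layer,
                                          set_filter)
from dbpscreen.spectral_identity import isotope_pattern, monoisotopic_mass
from dbpscreen.synthetic_data import truth_library


def rec(rt1=1.0, rt2=2.0, name=None, mf=None, layer=0, spec=None, rid=None):
    return PeakRecord(sample_id="s", layer=layer, rt1=rt1, rt2=rt2,
                      apex_spectrum=spec, hit_name=name, match_factor=mf,
                      record_id=rid)


TOL = MatchTolerance()


class TestRecordsMatch:
    def test_record_matches_itself(self):
        r = rec(name="x", mf=900)
        assert records_match(r, r, TOL)

    def test_retention_difference_beyond_tolerance(self):
        assert not records_match(rec(rt1=1.0), rec(rt1=1.0 + 2 * TOL.rt1_tol), TOL)

    def test_same_rt_different_names(self):
        assert not records_match(rec(name="a"), rec(name="b"), TOL)

    def test_same_name_matches_in_widened_window(self):
        a, b = rec(rt1=1.0, name="x"), rec(rt1=1.0 + 2 * TOL.rt1_tol, name="x")
        assert records_match(a, b, TOL)
        far = rec(rt1=1.0 + (TOL.name_window_scale + 1) * TOL.rt1_tol, name="x")
        assert not records_match(a, far, TOL)


class TestSetFilter:
    def test_empty_reference_subtract_is_identity(self):
        primary = [rec(rt1=i, name=f"p{i}") for i in range(3)]
        assert set_filter(primary, [], "subtract", TOL) == primary

    def test_self_subtract_is_empty(self):
        primary = [rec(rt1=i, name=f"p{i}") for i in range(3)]
        assert set_filter(primary, list(primary), "subtract", TOL) == []

    def test_toy_post_minus_pre(self):
        p1, p2, p3 = (rec(rt1=i, name=f"P{i}") for i in (1, 2, 3))
        kept = set_filter([p1, p2, p3], [rec(rt1=2, name="P2")], "subtract", TOL)
        assert kept == [p1, p3]

    def test_intersect_keeps_matching(self):
        p1, p2 = rec(rt1=1, name="a"), rec(rt1=2, name="b")
        kept = set_filter([p1, p2], [rec(rt1=1, name="a")], "intersect", TOL)
        assert kept == [p1]

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            set_filter([], [], "union", TOL)


class TestSelectBestLayer:
    def test_highest_match_factor_wins(self):
        """A compound deconvolved into layer 1 at MF 893 beats its layer-2
        duplicate at MF 708."""
        l1 = rec(name="x", mf=893, layer=1)
        l2 = rec(name="x", mf=708, layer=2)
        assert select_best_layer([l2, l1], TOL) == [l1]

    def test_singleton_kept(self):
        r = rec(name="only", mf=850, layer=2)
        assert select_best_layer([r], TOL) == [r]

    def test_tie_resolved_to_lowest_layer(self):
        l1 = rec(name="x", mf=850, layer=1)
        l3 = rec(name="x", mf=850, layer=3)
        assert select_best_layer([l3, l1], TOL) == [l1]


class TestMatchThreshold:
    def test_reference_table_retains_22(self):
        records = load_dbp_peak_table()
        kept = filter_match_threshold(records, 800)
        assert len(kept) == 22
        assert sum(1 for r in kept if "layer_only" in r.flags) == 7

    def test_nothing_reaches_999(self):
        assert filter_match_threshold(load_dbp_peak_table(), 999) == []

    def test_empty_and_identity(self):
        assert filter_match_threshold([], 800) == []
        records = load_dbp_peak_table()
        assert filter_match_threshold(records, 0) == records


class TestAnnotateIsotopeFit:
    def _spectrum_from(self, formula, extra=()):
        pat = isotope_pattern(formula)
        mz = list(pat.masses) + [m for m, _ in extra]
        inten = list(pat.abundances * 5.0) + [i for _, i in extra]
        return MassSpectrum(mz, inten)

    def test_exact_pattern_scores_perfectly(self):
        spec = self._spectrum_from("C6H5ClO", extra=[(51.0, 500.0)])
        r = rec(name="4-chlorophenol", spec=spec)
        cand, = annotate_isotope_fit([r], {"4-chlorophenol": "C6H5ClO"})
        assert cand.isotope_fit.molecular_ion_status == "appeared"
        assert cand.isotope_fit.cosine == pytest.approx(1.0, abs=1e-9)
        assert cand.isotope_fit.mass_error_ppm == pytest.approx(0.0, abs=1e-9)
        assert cand.isotope_ok is True

    def test_absent_molecular_ion_is_indeterminate(self):
        spec = MassSpectrum([51.0, 63.0], [100.0, 40.0])  # fragments only
        r = rec(name="4-chlorophenol", spec=spec)
        cand, = annotate_isotope_fit([r], {"4-chlorophenol": "C6H5ClO"})
        assert cand.isotope_fit.molecular_ion_status == "absent"
        assert cand.isotope_fit.cosine is None
        assert cand.isotope_ok is None  # record kept, evidence indeterminate

    def test_halved_m2_follows_vector_oracle(self):
        pat = isotope_pattern("C6H5ClO")
        obs = pat.abundances.copy()
        obs[pat.indices() == 2] *= 0.5
        spec = MassSpectrum(pat.masses, obs * 3.0)
        r = rec(name="4-chlorophenol", spec=spec)
        cand, = annotate_isotope_fit([r], {"4-chlorophenol": "C6H5ClO"},
                                     cosine_floor=0.999)
        # direct formula oracle on the index-aligned (M+k summed) vectors
        idx = pat.indices()
        t = np.array([pat.abundances[idx == k].sum() for k in np.unique(idx)])
        o_rel = 100.0 * obs / obs.max()
        o = np.array([o_rel[idx == k].sum() for k in np.unique(idx)])
        expected = float(t @ o / (np.linalg.norm(t) * np.linalg.norm(o)))
        assert cand.isotope_fit.cosine == pytest.approx(expected, abs=1e-9)
        assert cand.isotope_ok is (expected >= 0.999)

    def test_missing_formula_indeterminate(self):
        r = rec(name="mystery", spec=MassSpectrum([100.0], [1.0]))
        cand, = annotate_isotope_fit([r], {})
        assert cand.isotope_ok is None and cand.isotope_fit is None


class TestAnnotateRiFit:
    def test_perfect_and_outlier_and_missing(self):
        solutes, phases = load_default_lser()
        db1 = phases["DB-1"]
        name = "Phenol, 4-chloro-"
        calc = kovats_index(solutes[name], db1)
        records = [rec(name=name, mf=900), rec(name="Hexane, 2-bromo-", mf=850),
                   rec(name="naphthalene", mf=880)]
        cands = annotate_isotope_fit(records, {})
        reference = {name: calc,
                     "Hexane, 2-bromo-": kovats_index(
                         solutes["Hexane, 2-bromo-"], db1) + 122.0}
        cands = annotate_ri_fit(cands, solutes, db1, reference, dI_floor=50.0)
        assert cands[0].ri_comparison.dI == pytest.approx(0.0, abs=1e-9)
        assert cands[0].ri_ok is True
        assert cands[1].ri_comparison.dI == pytest.approx(-122.0, abs=1e-9)
        assert cands[1].ri_ok is False
        assert cands[2].ri_ok is None  # no reference index


class TestElutionConcordance:
    def _candidates(self, n=6):
        rng = np.random.default_rng(0)
        pts, cands = {}, []
        for i in range(n):
            i1 = 800.0 + 120 * i + 7 * rng.random()
            u2 = 1.0 + 0.3 * i
            # observed = similarity transform (uniform scale + shift) of the
            # predicted configuration
            rt1 = 0.01 * i1 + 2.0
            rt2 = 0.01 * u2 + 0.5
            cands.extend(annotate_isotope_fit([rec(rt1=rt1, rt2=rt2,
                                                   name=f"c{i}", mf=900)], {}))
            pts[f"c{i}"] = ElutionPoint(I1=i1, I2=i1 + 100 * np.log(u2) / np.log(1.6),
                                        u2=u2)
        return cands, pts

    def test_similarity_map_gives_zero_disparity(self):
        cands, pts = self._candidates()
        cands, report = evaluate_elution_concordance(cands, pts)
        assert report is not None
        assert report.procrustes_disparity < 1e-10
        assert report.r1 == pytest.approx(1.0)

    def test_displaced_candidate_has_max_loo_contribution(self):
        cands, pts = self._candidates()
        pts["c3"] = ElutionPoint(I1=3000.0, I2=3000.0, u2=9.0)
        cands, report = evaluate_elution_concordance(cands, pts,
                                                     drop_threshold=1e-6)
        flags = {c.record.hit_name: c.elution_ok for c in cands}
        assert flags["c3"] is False
        # exhaustive leave-one-out oracle: dropping c3 shrinks disparity most
        from dbpscreen.retention_modeling import procrustes_concordance
        matched = [c for c in cands if c.elution_point is not None]
        pred = [(c.elution_point.I1, c.elution_point.u2) for c in matched]
        obs = [(c.record.rt1, c.record.rt2) for c in matched]
        loo = [procrustes_concordance(pred[:i] + pred[i + 1:],
                                      obs[:i] + obs[i + 1:]).procrustes_disparity
               for i in range(len(matched))]
        assert matched[int(np.argmin(loo))].record.hit_name == "c3"

    def test_fewer_than_three_yields_no_report(self):
        cands, pts = self._candidates(2)
        out, report = evaluate_elution_concordance(cands, pts)
        assert report is None and out == cands


class TestFunnelReport:
    def test_conservation_enforced(self):
        funnel = FunnelReport()
        funnel.add("a", 100, 60)
        with pytest.raises(ValueError):
            funnel.add("b", 50, 40)   # chain broken
        funnel.add("b", 60, 60)
        with pytest.raises(ValueError):
            funnel.add("c", 60, 70)   # n_out > n_in
        assert [s.n_removed for s in funnel.stages] == [40, 0]


@pytest.fixture(scope="module")
def workflow_result(mini_study, mini_library):
    samplers, truth = mini_study
    cfg = WorkflowConfig(library=mini_library,
                         formulas={e.name: e.formula for e in mini_library})
    roles = {"blank": [c for s, c in samplers if s.startswith("blank")],
             "pre": [c for s, c in samplers if s.startswith("pre")],
             "post": [c for s, c in samplers if s.startswith("post")]}
    return run_workflow(roles, cfg), truth


class TestRunWorkflow:
    def test_recovers_spiked_set(self, workflow_result):
        result, truth = workflow_result
        got = sorted(c.record.hit_name for c in result.candidates)
        spiked = sorted(c.name for c in truth
                        if c.membership == frozenset({"post"}))
        assert got == spiked

    def test_funnel_conserved_and_chained(self, workflow_result):
        result, _ = workflow_result
        stages = result.funnel.stages
        assert len(stages) == 8
        for a, b in zip(stages, stages[1:]):
            assert a.n_out == b.n_in
        for s in stages:
            assert s.n_out == s.n_in - s.n_removed >= 0

    def test_annotation_filters_remove_nothing(self, workflow_result):
        result, _ = workflow_result
        for s in result.funnel.stages[5:]:
            assert s.n_removed == 0

    def test_candidates_traceable_to_source(self, workflow_result):
        result, _ = workflow_result
        for c in result.candidates:
            assert c.record.source_id and c.record.record_id

    def test_blanks_identical_to_posts_empty_candidates(self, mini_study,
                                                        mini_library):
        samplers, _ = mini_study
        post = [c for s, c in samplers if s.startswith("post")]
        cfg = WorkflowConfig(library=mini_library)
        result = run_workflow({"blank": post, "pre": post, "post": post}, cfg)
        assert result.candidates == []
        assert result.funnel.stages[0].n_out == 0

    def test_missing_role_rejected(self, mini_library):
        with pytest.raises(ValueError, match="missing sampler role"):
            run_workflow({"blank": [], "pre": [], "post": []},
                         WorkflowConfig(library=mini_library))

    def test_output_files_written(self, workflow_result, tmp_path):
        from dbpscreen.screening_pipeline import _write_outputs
        result, _ = workflow_result
        _write_outputs(result, tmp_path)
        assert (tmp_path / "candidates.csv").exists()
        assert (tmp_path / "funnel.json").exists()
        assert (tmp_path / "candidates.msp").exists()
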