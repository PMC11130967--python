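"""NNSVD seeding, multiplicative-update NMF, and layer construction."""

import itertools

import numpy as np
import pytest

from dbpscreen.nmf_deconvolution import (build_layers, deconvolve_peak,
                                         nmf_frobenius, nnsvd_seed)
from dbpscreen.peak_detection import detect_peaks
from dbpscreen.spectral_identity import match_factor
from dbpscreen.synthetic_data import generate_chromatogram

from conftest import make_compound, make_design


def _cosine(a, b):
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    return float(a @ b / (na * nb)) if na and nb else 0.0


def _random_nonneg(rng, m, n):
    return rng.random((m, n)) * (rng.random((m, n)) > 0.3)


class TestNNSVD:
    def test_rank1_exactness(self):
        rng = np.random.default_rng(0)
        w, h = rng.random(12), rng.random(9)
        V = np.outer(w, h)
        W0, H0 = nnsvd_seed(V, 1)
        assert np.linalg.norm(V - W0 @ H0) / np.linalg.norm(V) < 1e-6

    def test_seeds_non_negative(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            V = _random_nonneg(rng, 20, 15) + 1e-6
            W0, H0 = nnsvd_seed(V, 3)
            assert W0.min() >= 0 and H0.min() >= 0

    def test_seeded_loss_beats_flat_seeding(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            V = _random_nonneg(rng, 20, 15) + 1e-6
            W0, H0 = nnsvd_seed(V, 3)
            flat = np.linalg.norm(V - np.ones((20, 3)) @ np.ones((3, 15)))
            assert np.linalg.norm(V - W0 @ H0) <= flat

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty region"):
            nnsvd_seed(np.zeros((4, 4)), 2)
        with pytest.raises(ValueError):
            nnsvd_seed(np.ones((3, 3)), 5)


class TestNMF:
    def test_rank1_final_error(self):
        rng = np.random.default_rng(3)
        V = np.outer(rng.random(10), rng.random(8))
        res = nmf_frobenius(V, 1)
        assert res.objective_trace[-1] / np.linalg.norm(V) < 1e-6

    def test_factors_stay_non_negative(self):
        rng = np.random.default_rng(4)
        V = _random_nonneg(rng, 25, 18) + 1e-9
        res = nmf_frobenius(V, 4)
        assert res.W.min() >= 0 and res.H.min() >= 0

    def test_objective_trace_monotone_on_random_problems(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            V = _random_nonneg(rng, 15, 12) + 1e-9
            res = nmf_frobenius(V, 3, tol=1e-8, max_iter=60)
            t = np.array(res.objective_trace)
            assert np.all(np.diff(t) <= 1e-9 * t[0] + 1e-12)

    def test_two_component_recovery(self):
        """Well-separated synthetic mixtures: each recovered spectrum matches
        a truth spectrum at cosine >= 0.95 after best-permutation assignment,
        over 50 seeded problems."""
        scans = np.arange(30)
        for seed in range(50):
            rng = np.random.default_rng(seed)
            Wt = np.zeros((40, 2))
            for j in range(2):
                idx = rng.choice(40, size=6, replace=False)
                Wt[idx, j] = rng.uniform(0.2, 1.0, 6)
            Ht = np.stack([np.exp(-0.5 * ((scans - 10) / 4.0) ** 2),
                           np.exp(-0.5 * ((scans - 20) / 4.0) ** 2)])
            V = Wt @ Ht
            res = nmf_frobenius(V, 2, tol=1e-7, max_iter=2000)
            best = max(
                min(_cosine(res.W[:, p[j]], Wt[:, j]) for j in range(2))
                for p in itertools.permutations(range(2))
            )
            assert best >= 0.95, f"seed {seed}: {best:.3f}"

    def test_matches_sklearn_reference(self):
        """Final reconstruction error agrees with scikit-learn's NMF
        (nndsvd + multiplicative updates) as an independent reference."""
        sklearn_nmf = pytest.importorskip("sklearn.decomposition").NMF
        rng = np.random.default_rng(7)
        for _ in range(5):
            V = _random_nonneg(rng, 30, 20) + 1e-6
            ours = nmf_frobenius(V, 3, tol=1e-7, max_iter=500).objective_trace[-1]
            ref = sklearn_nmf(n_components=3, init="nndsvda", solver="mu",
                              tol=1e-7, max_iter=500).fit(V)
            theirs = np.linalg.norm(V - ref.transform(V) @ ref.components_)
            assert ours <= theirs * 1.05

    def test_bad_seeds_rejected(self):
        V = np.ones((4, 4))
        with pytest.raises(ValueError):
            nmf_frobenius(V, 2, W0=-np.ones((4, 2)), H0=np.ones((2, 4)))
        with pytest.raises(ValueError):
            nmf_frobenius(V, 2, tol=0)


def _overlapped_pair(ratio=1.0):
    a = make_compound(name="major", formula="C6H5ClO", rt1=1.5, rt2=2.5,
                      amplitude=1500.0, seed=3)
    b = make_compound(name="minor", formula="C2HBr3O", rt1=1.5 + 0.8 * a.sigma1,
                      rt2=2.5 + 0.8 * a.sigma2, amplitude=1500.0 * ratio, seed=8,
                      membership=frozenset({"post"}))
    design = make_design([a, b], mz_start=33, mz_end=340)
    chrom, _ = generate_chromatogram(design, "post")
    return chrom, a, b


class TestDeconvolvePeak:
    def test_pure_blob_single_component(self, single_peak_chromatogram):
        chrom, c = single_peak_chromatogram
        blob = detect_peaks(chrom)[0]
        comps = deconvolve_peak(blob, chrom)
        assert len(comps) == 1
        spec, _, _ = comps[0]
        truth = np.zeros(chrom.mz_end - chrom.mz_start + 1)
        for m, i in zip(c.spectrum.mz, c.spectrum.intensity):
            truth[int(round(m)) - chrom.mz_start] += i
        got = np.zeros_like(truth)
        for m, i in zip(spec.mz, spec.intensity):
            got[int(round(m)) - chrom.mz_start] += i
        assert _cosine(got, truth) >= 0.99

    def test_coeluted_pair_two_components(self):
        chrom, a, b = _overlapped_pair(1.0)
        blobs = detect_peaks(chrom)
        assert len(blobs) == 1  # truly co-eluted: one blob
        comps = deconvolve_peak(blobs[0], chrom)
        assert len(comps) == 2

    def test_contribution_ordering(self):
        chrom, a, b = _overlapped_pair(0.5)
        blob = detect_peaks(chrom)[0]
        contribs = [c for _, _, c in deconvolve_peak(blob, chrom)]
        assert contribs == sorted(contribs, reverse=True)


class TestBuildLayers:
    def test_separated_study_fills_layer1_only(self):
        a = make_compound(name="a", rt1=0.8, rt2=1.5)
        b = make_compound(name="b", formula="C7H8", rt1=2.2, rt2=3.6, seed=5)
        chrom, _ = generate_chromatogram(make_design([a, b]), "post")
        blobs = detect_peaks(chrom)
        layers = build_layers(blobs, chrom, sample_id="s")
        assert len(layers.records(1)) == 2
        for deep in (2, 3, 4):
            assert layers.records(deep) == []

    def test_minority_compound_in_layer2(self):
        chrom, a, b = _overlapped_pair(0.4)
        blobs = detect_peaks(chrom)
        layers = build_layers(blobs, chrom, sample_id="s")
        l2 = layers.records(2)
        assert len(l2) == 1
        mf_minor = match_factor(l2[0].apex_spectrum, b.spectrum)
        mf_major = match_factor(l2[0].apex_spectrum, a.spectrum)
        assert mf_minor > mf_major

    def test_layer_match_beats_contaminated_raw_match(self):
        """With a co-eluting contaminant, the library match of the layer-1
        spectrum exceeds the raw apex spectrum's match (deconvolution
        recovers the clean spectrum)."""
        chrom, a, b = _overlapped_pair(0.7)
        blob = detect_peaks(chrom)[0]
        layers = build_layers([blob], chrom, sample_id="s")
        raw_mf = match_factor(blob.apex_spectrum, a.spectrum)
        layer_mf = match_factor(layers.records(1)[0].apex_spectrum, a.spectrum)
        assert layer_mf > raw_mf
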