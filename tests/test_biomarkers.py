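"""Biomarker extraction: hit counts, 2D feature histograms, and the frozen
PCA basis with an explicit linear-algebra oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kneeae.biomarkers import (feature_profile, fit_pca_basis,
                               number_of_hits, project_candidates,
                               quadrant_hit_distribution, biomarker_table)
from kneeae.segmentation import detect_cycles, quadrant_boundaries, \
    smooth_and_differentiate
from kneeae.synthetic import simulate_angle_trace, simulate_hit_stream
from kneeae.types import BinConfig, QUADRANTS


def hit_frame(n, quadrant="Q1", asl=45.0, peak=55.0, seed=None):
    rng = np.random.default_rng(seed or 0)
    return pd.DataFrame({
        "onset_time_s": np.sort(rng.uniform(0, 10, n)),
        "peak_db": np.full(n, peak) if np.isscalar(peak) else peak,
        "asl_db": np.full(n, asl) if np.isscalar(asl) else asl,
        "duration_s": np.full(n, 1e-3),
        "quadrant": [quadrant] * n,
        "cycle_index": [0] * n})


def labelled_cycles(n=5, seed=0):
    tr = simulate_angle_trace(n, noise_sd=0.3, seed=seed)
    kin = smooth_and_differentiate(tr)
    return [quadrant_boundaries(kin, c) for c in detect_cycles(kin)]


class TestNumberOfHits:
    def test_empty_and_window(self):
        assert number_of_hits(hit_frame(0)) == 0
        h = hit_frame(20, seed=1)
        assert number_of_hits(h) == 20
        t = h["onset_time_s"].iloc[10]
        assert number_of_hits(h, t_start=t) + number_of_hits(h, t_end=t) == 20

    def test_generator_count_ground_truth(self):
        cycles = labelled_cycles()
        hits = simulate_hit_stream(cycles, 120, seed=2)
        assert number_of_hits(hits) == 120

    def test_within_session_repeatability_of_hit_counts(self):
        """Two sets generated at identical rates scatter tightly about the
        diagonal: first-set vs repeat-set correlation exceeds 0.9."""
        rng = np.random.default_rng(3)
        lam = rng.gamma(2.0, 80.0, size=60)         # per-knee rates
        set1 = rng.poisson(lam)
        set2 = rng.poisson(lam)
        r = np.corrcoef(set1, set2)[0, 1]
        assert r > 0.9


class TestFeatureProfile:
    def test_single_bin_concentration(self):
        prof = feature_profile(hit_frame(10, "Q1", asl=45.0, peak=55.0))
        assert prof.total == 10
        assert prof.counts[0].max() == 10
        assert prof.counts[1:].sum() == 0

    def test_total_equals_on_cycle_count_with_clamping(self):
        h = pd.concat([hit_frame(7, "Q2", asl=25.0, peak=120.0, seed=4),
                       hit_frame(5, "off", seed=5)], ignore_index=True)
        prof = feature_profile(h)
        assert prof.total == 7            # off-cycle excluded, outliers clamped
        assert prof.n_off_cycle == 5

    def test_uniform_amplitudes_fill_bins_uniformly(self):
        rng = np.random.default_rng(6)
        n = 4000
        bins = BinConfig()
        asl = rng.uniform(30, 90, n)
        peak = rng.uniform(36, 100, n)
        prof = feature_profile(hit_frame(n, "Q3", asl=asl, peak=peak))
        counts = prof.counts[2].reshape(-1)
        chi2 = ((counts - n / 64) ** 2 / (n / 64)).sum()
        assert stats.chi2.sf(chi2, 63) > 0.001

    def test_normalized_mode_and_bad_edges(self):
        prof = feature_profile(hit_frame(8), normalized=True)
        assert prof.total == pytest.approx(1.0)
        with pytest.raises(ValueError):
            BinConfig(asl_edges=(50.0, 40.0))


class TestPCABasis:
    def _profiles(self, scores, direction_seed=7):
        """Profiles lying exactly on a line in bin space."""
        rng = np.random.default_rng(direction_seed)
        bins = BinConfig()
        base = rng.uniform(1, 5, size=bins.shape)
        direction = rng.uniform(0, 1, size=bins.shape)
        out = []
        for s in scores:
            prof = feature_profile(hit_frame(1))
            prof.counts = base + s * direction
            out.append(prof)
        return out

    def test_collinear_profiles_explained_by_one_component(self):
        basis = fit_pca_basis(self._profiles([0, 1, 2, 3, 4.0]))
        assert basis.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_loadings_orthonormal_and_variance_nonincreasing(self):
        rng = np.random.default_rng(8)
        profs = self._profiles(rng.normal(size=10))
        for p in profs:
            p.counts = p.counts + rng.uniform(0, 0.5, p.counts.shape)
        basis = fit_pca_basis(profs)
        G = basis.components @ basis.components.T
        assert np.allclose(G, np.eye(3), atol=1e-10)
        assert np.all(np.diff(basis.explained_variance_ratio) <= 1e-12)

    def test_developmental_split_separates_severity_groups(self):
        """Five low-amplitude and three high-amplitude knees separate on
        PC1 with no overlap, mirroring a mild/severe developmental set."""
        cycles = labelled_cycles(seed=9)
        profs, label = [], []
        for k in range(8):
            loud = k >= 5
            hits = simulate_hit_stream(
                cycles, 150,
                amplitude_mean_above_threshold_db=14.0 if loud else 4.0,
                seed=20 + k)
            profs.append(feature_profile(hits))
            label.append(loud)
        basis = fit_pca_basis(profs)
        pc1 = np.array([project_candidates(p, basis)[0] for p in profs])
        lo, hi = pc1[~np.array(label)], pc1[np.array(label)]
        assert max(lo.max(), hi.max()) - min(lo.min(), hi.min()) > 0
        assert (lo.max() < hi.min()) or (hi.max() < lo.min())

    def test_projection_matches_explicit_dot_product(self):
        rng = np.random.default_rng(10)
        profs = self._profiles(rng.normal(size=6))
        basis = fit_pca_basis(profs)
        p = profs[2]
        expected = [(p.flattened() - basis.mean) @ basis.components[j]
                    for j in range(3)]
        assert project_candidates(p, basis) == pytest.approx(expected)

    def test_mean_profile_scores_zero_and_fit_consistency(self):
        profs = self._profiles([0, 1, 2, 5.0])
        basis = fit_pca_basis(profs)
        mean_prof = profs[0]
        mean_prof = feature_profile(hit_frame(1))
        mean_prof.counts = np.mean([p.counts for p in profs], axis=0)
        assert project_candidates(mean_prof, basis) == pytest.approx(
            (0.0, 0.0, 0.0), abs=1e-9)

    def test_order_invariance_and_linearity(self):
        rng = np.random.default_rng(11)
        profs = self._profiles(rng.normal(size=8))
        b1 = fit_pca_basis(profs)
        b2 = fit_pca_basis(profs[::-1])
        p = profs[0]
        s1 = np.abs(project_candidates(p, b1))
        s2 = np.abs(project_candidates(p, b2))
        assert s1 == pytest.approx(s2, abs=1e-9)   # up to component sign
        # doubling all counts doubles centered scores under the same basis
        doubled = feature_profile(hit_frame(1))
        doubled.counts = 2 * p.counts
        d = np.array(project_candidates(doubled, b1))
        base = np.array(project_candidates(p, b1))
        extra = (p.flattened() @ b1.components.T)
        assert d == pytest.approx(base + extra, abs=1e-8)

    def test_fingerprint_mismatch_rejected(self):
        profs = self._profiles([0, 1, 2, 3.0])
        basis = fit_pca_basis(profs)
        other = feature_profile(hit_frame(3),
                                bins=BinConfig(asl_edges=(30.0, 60.0, 90.0)))
        with pytest.raises(ValueError, match="fingerprint|bin grid"):
            project_candidates(other, basis)
        with pytest.raises(ValueError):
            fit_pca_basis(profs[:3])


class TestQuadrantDistribution:
    def test_skewed_proportions_rank_q1_q4_highest(self):
        cycles = labelled_cycles(seed=12)
        per_set = {}
        kl = []
        rng = np.random.default_rng(13)
        for i in range(30):
            hits = simulate_hit_stream(cycles, 200, (0.4, 0.1, 0.1, 0.4),
                                       seed=100 + i)
            per_set[(f"P{i}", 1, 1, 1)] = hits
            kl.append(int(rng.integers(1, 5)))
        tab = biomarker_table(per_set)
        summ = quadrant_hit_distribution(tab, np.array(kl))
        for g in ("KL1", "KL>=2"):
            med = {r.quadrant: r.median for r in
                   summ[summ["group"] == g].itertuples()}
            assert min(med["Q1"], med["Q4"]) > max(med["Q2"], med["Q3"])

    def test_equal_proportions_show_no_systematic_ordering(self):
        cycles = labelled_cycles(seed=14)
        counts = {q: [] for q in QUADRANTS}
        for i in range(40):
            hits = simulate_hit_stream(cycles, 100, (.25, .25, .25, .25),
                                       seed=200 + i)
            vc = hits["quadrant"].value_counts()
            for q in QUADRANTS:
                counts[q].append(vc.get(q, 0))
        _, p = stats.kruskal(*[counts[q] for q in QUADRANTS])
        assert p > 0.01

    def test_zero_hits_summaries_are_zero(self):
        empty = pd.DataFrame({"onset_time_s": [], "peak_db": [], "asl_db": [],
                              "duration_s": [], "quadrant": [],
                              "cycle_index": []})
        tab = biomarker_table({("P1", 1, 1, 1): empty})
        summ = quadrant_hit_distribution(tab, np.array([1]))
        assert (summ[summ["group"] == "KL1"]["median"] == 0).all()
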