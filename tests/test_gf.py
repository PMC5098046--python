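import numpy as np
import pytest

from oracles import enumerate_histogram, random_prm
from specnet import (Config, HistogramCache, PRMSpectrum, build_histogram,
                     estimate_theta, gaussian_p_value, p_value,
                     score_pair, to_prm)
from specnet.gf import discretize_scores
from specnet.simulate import spectrum_from_peptide


def _prm(sid, masses, scores, M=2000.0):
    return PRMSpectrum(sid, float(M), np.asarray(masses, dtype=float),
                       np.asarray(scores, dtype=float))


def test_two_peak_histogram_matches_enumeration(cfg):
    # scores 0.1 and 0.2 discretize to 1 and 2 grid units
    h = build_histogram(_prm("x", [100.0, 200.0], [0.1, 0.2]), 0.05, cfg)
    assert h.density[0] == pytest.approx(0.9025, abs=1e-12)
    assert h.density[1] == pytest.approx(0.0475, abs=1e-12)
    assert h.density[2] == pytest.approx(0.0475, abs=1e-12)
    assert h.density[3] == pytest.approx(0.0025, abs=1e-12)
    assert p_value(h, 0.2) == pytest.approx(0.05, abs=1e-12)


def test_empty_spectrum_histogram_is_point_mass(cfg):
    h = build_histogram(_prm("x", [], []), 0.05, cfg)
    assert h.density.tolist() == [1.0]
    assert p_value(h, 0.0) == 1.0


@pytest.mark.parametrize("trial", range(20))
def test_dp_matches_subset_enumeration(trial, cfg):
    rng = np.random.default_rng(3000 + trial)
    n = int(rng.integers(1, 16))
    masses, scores, M = random_prm(rng, n)
    prm = _prm("x", masses, scores, M)
    theta = float(rng.uniform(0.01, 0.3))
    h = build_histogram(prm, theta, cfg)
    ints = discretize_scores(scores, cfg.score_grid)
    brute = enumerate_histogram([int(s) for s in ints], theta)
    assert abs(h.density.sum() - 1.0) < 1e-9
    for t, prob in brute.items():
        assert h.density[t] == pytest.approx(prob, abs=1e-12)
    assert np.count_nonzero(h.density) == len(brute)


def test_empty_alignment_probability_floor(cfg):
    rng = np.random.default_rng(0)
    masses, scores, M = random_prm(rng, 40)
    h = build_histogram(_prm("x", masses, scores, M), 0.05, cfg)
    assert h.density[0] >= (1 - 0.05) ** 40 - 1e-12


def test_p_value_tails_and_monotonicity(cfg):
    rng = np.random.default_rng(1)
    masses, scores, M = random_prm(rng, 12)
    h = build_histogram(_prm("x", masses, scores, M), 0.05, cfg)
    assert p_value(h, 0.0) == 1.0
    assert p_value(h, h.max_score + 1.0) == 0.0
    grid = np.linspace(0, h.max_score + 0.5, 200)
    ps = [p_value(h, t) for t in grid]
    assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


def test_p_value_rounds_observed_score_down(cfg):
    h = build_histogram(_prm("x", [100.0, 200.0], [0.1, 0.2]), 0.05, cfg)
    # T = 0.19 sits below the second bin boundary: conservative bin 1
    assert p_value(h, 0.19) == pytest.approx(float(h.survival[1]))


def test_theta_must_be_probability(cfg):
    prm = _prm("x", [100.0], [1.0])
    for bad in (0.0, 1.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            build_histogram(prm, bad, cfg)


def test_histogram_cache_memoizes(cfg):
    prm = _prm("x", [100.0, 200.0], [1.0, 2.0])
    cache = HistogramCache(cfg)
    assert cache.get(prm) is cache.get(prm)


def test_identical_spectra_pair_is_significant(cfg, rng):
    s = to_prm(spectrum_from_peptide("ELVISLIVESKGASPVTLNDQR", "a:0", "sp",
                                     rng, noise_peak_fraction=0.0), cfg)
    twin = _prm("a:1", s.masses.copy(), s.scores.copy(), s.precursor_mass)
    res = score_pair(s, twin, cfg)
    assert res.pair_p == max(res.p1, res.p2)
    assert res.pair_p < 5e-9
    # analytic bound: matching all N peaks has null probability theta^N
    assert res.pair_p >= 0.05 ** s.n_peaks - 1e-30


def test_disjoint_spectra_pair_p_is_one(cfg):
    a = _prm("x:1", [100.0, 200.0], [1.0, 1.0], 900.0)
    b = _prm("x:2", [500.0, 600.0], [1.0, 1.0], 905.0)
    res = score_pair(a, b, cfg)
    assert res.t1 == 0.0 and res.t2 == 0.0
    assert res.pair_p == 1.0


def test_null_simulation_calibration(cfg):
    # p-values of scores simulated from the Bernoulli null are uniform-valid
    rng = np.random.default_rng(11)
    masses, scores, M = random_prm(rng, 80, score_range=(0.5, 6.0))
    prm = _prm("x", masses, scores, M)
    h = build_histogram(prm, 0.05, cfg)
    ints = discretize_scores(scores, cfg.score_grid)
    n_sim = 20000
    draws = rng.random((n_sim, 80)) < 0.05
    totals = draws @ ints
    ps = np.where(totals <= 0, 1.0,
                  h.survival[np.minimum(totals, h.survival.size - 1)])
    alpha = 1e-2
    freq = float(np.mean(ps <= alpha))
    se = np.sqrt(alpha * (1 - alpha) / n_sim)
    assert abs(freq - alpha) <= 3 * se


def test_exact_p_value_separates_better_than_gaussian(cfg):
    # planted true pairs vs decoys: ranking by the exact pair p-value should
    # recover at least as many true pairs as the Gaussian approximation
    rng = np.random.default_rng(21)
    from specnet.simulate import _random_peptide, SimConfig
    sim = SimConfig()
    true_scores, null_scores, gauss_true, gauss_null = [], [], [], []
    for _ in range(40):
        pep = _random_peptide(rng, sim)
        s1 = to_prm(spectrum_from_peptide(pep, "a:0", "sp", rng,
                                          noise_peak_fraction=1.5), cfg)
        s2 = to_prm(spectrum_from_peptide(pep, "a:1", "sp", rng,
                                          noise_peak_fraction=1.5), cfg)
        other = _random_peptide(rng, sim)
        d = to_prm(spectrum_from_peptide(other, "a:2", "sp", rng,
                                         noise_peak_fraction=1.5), cfg)
        if min(s1.n_peaks, s2.n_peaks, d.n_peaks) == 0:
            continue
        res = score_pair(s1, s2, cfg)
        true_scores.append(res.pair_p)
        gauss_true.append(max(gaussian_p_value(s1, res.t1, cfg),
                              gaussian_p_value(s2, res.t2, cfg)))
        if abs(d.precursor_mass - s1.precursor_mass) <= cfg.max_mod_mass_da:
            dres = score_pair(s1, d, cfg)
            null_scores.append(dres.pair_p)
            gauss_null.append(max(gaussian_p_value(s1, dres.t1, cfg),
                                  gaussian_p_value(d, dres.t2, cfg)))

    def recall_at_full_precision(true_p, null_p):
        cut = min(null_p) if null_p else 1.0
        return sum(1 for p in true_p if p < cut)

    assert recall_at_full_precision(true_scores, null_scores) >= \
        recall_at_full_precision(gauss_true, gauss_null)


def test_estimate_theta_behaves_like_match_probability(cfg, rng):
    spectra = [to_prm(spectrum_from_peptide("ELVISLIVESKGASPVTK", f"a:{i}",
                                            "sp", rng), cfg)
               for i in range(5)]
    t1 = estimate_theta(spectra, np.random.default_rng(3), 400, cfg)
    assert 0.0 < t1 < 0.2
    wide = Config(fragment_tolerance_da=0.8)
    t2 = estimate_theta(spectra, np.random.default_rng(3), 400, wide)
    assert t2 > t1
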