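import numpy as np
import pandas as pd
import pytest

import tilecall as tc
from tilecall.detection import (CandidateRegion, ResidualProfile,
                                screen_candidate_regions)

import helpers_oracle as oracle


def _as_dicts(design, table):
    return dict(zip(design.probe_ids(), table.values.to_numpy()))


def test_null_residual_zero_when_samples_identical(small_design, true_model,
                                                   noisefree_pair):
    wt, _, _ = noisefree_pair
    profile = tc.residual_profile(true_model, small_design, wt, wt)
    assert np.allclose(profile.null_residual, 0.0)


def test_noise_free_substitution_self_consistency(small_genome, small_design,
                                                  true_model, small_foldings,
                                                  noisefree_pair):
    """E_i*(b*) vanishes and D_i* is inflated at the implanted site."""
    wt, mut, truth = noisefree_pair
    rec = truth.records[0]
    e_alt = tc.position_residual(true_model, small_design, wt, mut,
                                 rec.position, rec.alt_base,
                                 folding=small_foldings)
    d = tc.position_residual(true_model, small_design, wt, mut,
                             rec.position, folding=small_foldings)
    assert e_alt == pytest.approx(0.0, abs=1e-18)
    assert d > 1.0


def test_residuals_and_llr_match_brute_force(small_genome, small_design,
                                             true_model, small_foldings,
                                             noisefree_pair):
    """Vectorized E_i(b), D_i and LLR equal the naive recomputation from
    their definitions."""
    wt, mut, truth = noisefree_pair
    wt_d, mut_d = _as_dicts(small_design, wt), _as_dicts(small_design, mut)
    fold_d = dict(zip(small_design.probe_ids(), small_foldings))
    probe_list = list(small_design)  # materialise once for the naive loops
    rec = truth.records[0]
    positions = [rec.position, rec.position + 3, 57]
    for i in positions:
        ref = small_genome[i - 1]
        d_naive = oracle.position_residual(
            true_model, probe_list, wt_d, mut_d, fold_d, i, None,
            small_genome)
        d_pkg = tc.position_residual(true_model, small_design, wt, mut, i,
                                     folding=small_foldings)
        assert d_pkg == pytest.approx(d_naive, rel=1e-10, abs=1e-12)
        for b in "ACGT":
            if b == ref:
                continue
            e_naive = oracle.position_residual(
                true_model, probe_list, wt_d, mut_d, fold_d, i, b,
                small_genome)
            e_pkg = tc.position_residual(true_model, small_design, wt, mut,
                                         i, b, folding=small_foldings)
            assert e_pkg == pytest.approx(e_naive, rel=1e-10, abs=1e-12)
            llr_naive = oracle.likelihood_ratio(
                true_model, probe_list, wt_d, mut_d, fold_d, i, b,
                small_genome)
            llr_pkg = tc.likelihood_ratio(true_model, small_design, wt, mut,
                                          i, b, folding=small_foldings)
            assert llr_pkg == pytest.approx(llr_naive, rel=1e-10, abs=1e-12)


def test_llr_argmax_at_implanted_substitution(small_design, true_model,
                                              small_foldings, noisefree_pair,
                                              small_genome):
    wt, mut, truth = noisefree_pair
    rec = truth.records[0]
    best = None
    for i in range(rec.position - 5, rec.position + 6):
        ref = small_genome[i - 1]
        for b in "ACGT":
            if b == ref:
                continue
            llr = tc.likelihood_ratio(true_model, small_design, wt, mut, i,
                                      b, folding=small_foldings)
            if best is None or llr > best[0]:
                best = (llr, i, b)
    assert (best[1], best[2]) == (rec.position, rec.alt_base)


def test_null_data_gives_nonpositive_llr(small_design, true_model,
                                         small_foldings, noisefree_pair,
                                         small_genome):
    """With mut == wt every log-likelihood ratio is <= 0."""
    wt, _, _ = noisefree_pair
    for i in (40, 333, 1500):
        ref = small_genome[i - 1]
        for b in "ACGT":
            if b == ref:
                continue
            assert tc.likelihood_ratio(true_model, small_design, wt, wt, i,
                                       b, folding=small_foldings) <= 0.0


def test_profile_statistics_streaming_oracle(small_design, true_model,
                                             small_foldings, noisefree_pair):
    """Running average and threshold agree with a direct two-pass
    recomputation."""
    wt, mut, _ = noisefree_pair
    profile = tc.residual_profile(true_model, small_design, wt, mut,
                                  window=11, k_sd=2.0,
                                  folding=small_foldings,
                                  exclude_structural=False)
    d = profile.null_residual
    L = len(d)
    for i in (0, 57, L - 1):
        window_vals = [d[(i + off) % L] for off in range(-5, 6)]
        assert profile.running_avg[i] == pytest.approx(
            float(np.mean(window_vals)), rel=1e-10)
    assert profile.theta_R == pytest.approx(
        float(np.mean(d) + 2.0 * np.std(d)), rel=1e-12)


def test_constant_profile_and_threshold_dominance(small_design, true_model,
                                                  noisefree_pair):
    wt, mut, _ = noisefree_pair
    profile = tc.residual_profile(true_model, small_design, wt, mut,
                                  k_sd=1e9)
    assert not (profile.running_avg > profile.theta_R).any()
    assert tc.screen_candidate_regions(profile) == []
    const = ResidualProfile(np.full(100, 2.0), np.full(100, 2.0), 3.0, 11,
                            2.0, True)
    assert np.allclose(const.running_avg, 2.0)


def test_even_window_rejected(small_design, true_model, noisefree_pair):
    wt, mut, _ = noisefree_pair
    with pytest.raises(ValueError):
        tc.residual_profile(true_model, small_design, wt, mut, window=10)


def _profile_from_mask(mask, theta=0.5):
    """Profile whose running average is 1 on mask positions, else 0."""
    avg = mask.astype(float)
    return ResidualProfile(avg.copy(), avg, theta, 11, 2.0, circular=True)


def test_screen_length_rules():
    L = 400
    mask = np.zeros(L, dtype=bool)
    mask[10:19] = True     # 9 bp: too short, dropped
    mask[50:70] = True     # 20 bp: substitution candidate
    mask[100:200] = True   # 100 bp: structural
    regions = screen_candidate_regions(_profile_from_mask(mask))
    assert len(regions) == 2
    cand, struct = regions
    assert (cand.start, cand.end, cand.structural) == (51, 70, False)
    assert (struct.start, struct.end, struct.structural) == (101, 200, True)
    # exactly-80-bp runs are structural, 79 bp are candidates
    mask2 = np.zeros(L, dtype=bool)
    mask2[0:80] = True
    assert screen_candidate_regions(_profile_from_mask(mask2))[0].structural
    mask3 = np.zeros(L, dtype=bool)
    mask3[0:79] = True
    assert not screen_candidate_regions(
        _profile_from_mask(mask3))[0].structural


def test_screen_wraps_circular_origin():
    L = 300
    mask = np.zeros(L, dtype=bool)
    mask[:8] = True
    mask[-8:] = True
    regions = screen_candidate_regions(_profile_from_mask(mask))
    assert len(regions) == 1
    r = regions[0]
    assert (r.start, r.end) == (293, 8)
    assert r.length(L) == 16
    assert list(r.positions(L)) == list(range(293, 301)) + list(range(1, 9))


def test_no_calls_at_infinite_threshold(small_design, true_model,
                                        small_foldings, noisefree_pair):
    wt, mut, _ = noisefree_pair
    calls, regions, _ = tc.detect(true_model, small_design, wt, mut,
                                  theta_L=np.inf, folding=small_foldings)
    assert calls == []
    assert len(regions) >= 1


def test_threshold_is_strict(small_design, true_model, small_foldings,
                             noisefree_pair):
    """A region whose maximum LLR equals theta_L exactly is not called."""
    wt, mut, truth = noisefree_pair
    calls, regions, profile = tc.detect(true_model, small_design, wt, mut,
                                        theta_L=-np.inf,
                                        folding=small_foldings)
    assert len(calls) == 1
    max_llr = calls[0].llr
    again = tc.call_substitutions(true_model, small_design, wt, mut,
                                  regions, theta_L=max_llr,
                                  folding=small_foldings)
    assert again == []


def test_deletion_flagged_structural_without_calls(true_model):
    """A 150-bp deletion yields one structural region and no substitution
    call inside it."""
    genome = tc.random_genome(4000, 0.5, seed=71)
    design = tc.build_tiling_design(genome, 1, circular=True)
    folding = tc.folding_energies(design.probe_codes())
    deletion = [(2000, 2149)]
    wt = tc.simulate_intensities(true_model, design, genome, folding,
                                 0.02, 72, sample_id="wt")
    mut = tc.simulate_intensities(true_model, design, genome, folding,
                                  0.02, 73, deletions=deletion,
                                  sample_id="mut")
    calls, regions, _ = tc.detect(true_model, design, wt, mut, theta_L=0.0,
                                  folding=folding)
    struct = [r for r in regions if r.structural]
    assert len(struct) == 1
    assert struct[0].start <= 2000 and struct[0].end >= 2149
    assert not any(2000 <= c.position <= 2149 for c in calls)


def test_intensity_table_validation():
    with pytest.raises(ValueError):
        tc.IntensityTable("bad", pd.Series([1.0, 0.0], index=["a", "b"]))
    with pytest.raises(ValueError):
        tc.IntensityTable("bad", pd.Series([1.0, -2.0], index=["a", "b"]))
    with pytest.raises(ValueError):
        tc.IntensityTable("bad", pd.Series([np.inf], index=["a"]))


def test_intensity_table_tsv_round_trip(tmp_path, noisefree_pair):
    wt, _, _ = noisefree_pair
    path = tmp_path / "wt.tsv"
    wt.to_tsv(path)
    back = tc.IntensityTable.from_tsv(path, "wt")
    assert np.allclose(back.values.to_numpy(), wt.values.to_numpy())
    assert list(back.values.index) == list(wt.values.index)
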