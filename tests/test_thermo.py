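import json
import math

import numpy as np
import pytest

import tilecall as tc
from tilecall.thermo import (DEFAULT_STACK_TABLE, Hypothesis, REFERENCE,
                             log_intensity_from_energies)

import helpers_oracle as oracle


@pytest.fixture()
def rng():
    return np.random.default_rng(99)


def random_21mer(rng):
    return "".join(rng.choice(list("ACGT"), 21))


# ---------------------------------------------------------------------
# triplet indexing and weighted energies
# ---------------------------------------------------------------------
@pytest.mark.parametrize("trip,expected", [
    (("A", "A", "A"), 0), (("T", "T", "T"), 63), (("A", "C", "G"), 6),
])
def test_triplet_index(trip, expected):
    assert tc.triplet_index(*trip) == expected


def test_triplet_index_rejects_non_base():
    with pytest.raises(ValueError):
        tc.triplet_index("A", "N", "G")


def test_specific_energy_uniform_closed_forms():
    m = tc.sample_true_model(seed=1)
    m.eps_specific = np.ones(64)
    m.weights = np.ones(19)
    seq = "ACGTACGTACGTACGTACGTA"
    assert tc.specific_energy(m, seq) == pytest.approx(19.0)
    m.weights = np.zeros(19)
    assert tc.specific_energy(m, seq) == 0.0
    m.eps_nonspecific = np.full(64, 0.3)
    m.weights = np.full(19, 0.5)
    assert tc.nonspecific_energy(m, seq) == pytest.approx(19 * 0.3 * 0.5)


def test_weighted_energies_match_naive_loop(rng):
    """Vectorized triplet sums equal an independent per-position loop."""
    from conftest import random_energy_model
    for _ in range(50):
        m = random_energy_model(rng)
        seq = random_21mer(rng)
        assert tc.specific_energy(m, seq) == pytest.approx(
            oracle.weighted_sum(m.eps_specific, m.weights, seq), rel=1e-12)
        assert tc.nonspecific_energy(m, seq) == pytest.approx(
            oracle.weighted_sum(m.eps_nonspecific, m.weights, seq),
            rel=1e-12)


# ---------------------------------------------------------------------
# mismatch accounting
# ---------------------------------------------------------------------
def test_mismatch_rules(small_genome, small_design, true_model):
    m = true_model
    pm = small_design[400]  # PM probe
    assert pm.kind == "PM"
    # PM under the reference hypothesis: no penalty at all
    assert tc.mismatch_adjusted_energy(m, pm, small_genome) == \
        pytest.approx(tc.specific_energy(m, pm.sequence))
    # MM under the reference hypothesis: exactly one penalty subtracted
    mm = small_design[401]
    g_mm = tc.mismatch_adjusted_energy(m, mm, small_genome)
    assert g_mm < tc.specific_energy(m, pm.sequence)
    # an MM probe whose central alt equals the mutant base becomes a
    # perfect match to the mutant target: zero penalties
    pos = mm.position
    alt = mm.central_alt if mm.strand == "+" else \
        oracle.COMP[mm.central_alt]
    hyp = Hypothesis(pos, alt)
    assert tc.mismatch_adjusted_energy(m, mm, small_genome, hyp) == \
        pytest.approx(tc.specific_energy(m, pm.sequence))


def test_mismatch_adjusted_matches_oracle(small_genome, small_design, rng):
    from conftest import random_energy_model
    m = random_energy_model(rng)
    genome = small_genome
    for idx in rng.choice(len(small_design), 40, replace=False):
        probe = small_design[int(idx)]
        # substitution somewhere inside (or outside) the probe span
        pos = int(rng.integers(1, len(genome) + 1))
        ref = genome[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        got = tc.mismatch_adjusted_energy(m, probe, genome,
                                          Hypothesis(pos, str(alt)))
        mut_genome = genome[:pos - 1] + str(alt) + genome[pos:]
        pm = oracle.pm_seq(genome, probe.position, probe.strand)
        target = oracle.pm_seq(mut_genome, probe.position, probe.strand)
        want = oracle.adjusted_energy(m, pm, probe.sequence, target)
        assert got == pytest.approx(want, rel=1e-12, abs=1e-12)


# ---------------------------------------------------------------------
# folding
# ---------------------------------------------------------------------
def test_folding_no_stem_is_zero():
    assert tc.folding_energy("A" * 21) == 0.0


def test_folding_designed_hairpin_closed_form():
    seq = "GGGGG" + "A" * 11 + "CCCCC"
    s, p = 1.3, 3.5
    uniform = np.full(16, s)
    assert tc.folding_energy(seq, uniform, p) == pytest.approx(
        max(0.0, 4 * s - p))
    # loop penalty exceeding the stem score clips at zero
    assert tc.folding_energy(seq, uniform, 10.0) == 0.0


def test_folding_scalar_vector_and_oracle_agree(rng):
    from tilecall._codes import encode
    seqs = [random_21mer(rng) for _ in range(60)]
    enc = np.stack([encode(s) for s in seqs])
    vec = tc.folding_energies(enc)
    for i, s in enumerate(seqs):
        scalar = tc.folding_energy(s)
        want = oracle.folding_energy(s, DEFAULT_STACK_TABLE, 3.5, 3)
        assert scalar == pytest.approx(want, abs=1e-12)
        assert vec[i] == pytest.approx(want, abs=1e-12)


# ---------------------------------------------------------------------
# predicted intensity
# ---------------------------------------------------------------------
def test_predicted_intensity_limits(small_genome, small_design, true_model):
    probe = small_design[100]
    m = tc.EnergyModel.from_vector(true_model.to_vector())
    # vanishing optical scale leaves only the background
    m.intensity_scale = 1e-300
    assert tc.predict_log_intensity(m, probe, small_genome) == \
        pytest.approx(math.log(m.background))
    # a fully folded probe binds nothing
    m2 = tc.EnergyModel.from_vector(true_model.to_vector())
    assert tc.predict_log_intensity(m2, probe, small_genome,
                                    folding=1e4) == \
        pytest.approx(math.log(m2.background))


def test_predicted_intensity_matches_hand_evaluation():
    """Small hand-set model: the closed form evaluated by hand."""
    m = tc.sample_true_model(seed=3)
    m.eps_specific = np.full(64, 0.5)
    m.eps_nonspecific = np.full(64, 0.2)
    m.weights = np.ones(19)
    m.alpha = 1.0
    m.intensity_scale = 1000.0
    m.background = 50.0
    m.conc_nonspecific = 0.02
    g_s, g_ns, g_f = 19 * 0.5, 19 * 0.2, 1.0
    ks, kns, kf = math.exp(g_s), math.exp(g_ns) * 0.02, math.exp(g_f)
    want = math.log(1000.0 * (ks + kns) / (1 + kf + ks + kns) + 50.0)
    got = log_intensity_from_energies(m, np.array([g_s]), np.array([g_ns]),
                                      np.array([g_f]))[0]
    assert got == pytest.approx(want, abs=1e-12)


def test_predicted_intensity_saturation_bounds(rng):
    from conftest import random_energy_model
    m = random_energy_model(rng)
    # g_s capped where the saturating fraction is still resolvable in
    # double precision; beyond that the bound is approached to rounding
    g_s = rng.uniform(-5, 12, 200)
    g_ns = rng.uniform(0, 10, 200)
    g_f = rng.uniform(0, 20, 200)
    log_i = log_intensity_from_energies(m, g_s, g_ns, g_f)
    assert (log_i > np.log(m.background)).all()
    assert (log_i < np.log(m.intensity_scale + m.background)).all()


def test_penalty_monotonicity(small_genome, small_design, true_model):
    """Raising any mismatch penalty never increases predicted intensity."""
    mm = small_design[401]
    base = tc.predict_log_intensity(true_model, mm, small_genome)
    bumped = tc.EnergyModel.from_vector(true_model.to_vector())
    bumped.penalty = bumped.penalty + 0.5
    assert tc.predict_log_intensity(bumped, mm, small_genome) < base


def test_log_ratio_signs(small_genome, small_design, true_model):
    """A substitution weakens spanning PM probes and can convert the
    matching MM probe into a perfect match (ratio > 0)."""
    pm = small_design[800]
    pos = pm.position + 4
    ref = small_genome[pos - 1]
    alt = [b for b in "ACGT" if b != ref][0]
    hyp = Hypothesis(pos, alt)
    assert tc.predict_log_ratio(true_model, pm, small_genome, hyp) < 0
    assert tc.predict_log_ratio(true_model, pm, small_genome, REFERENCE) \
        == 0.0
    # probe not spanning the substitution is untouched
    far = small_design[80]
    assert tc.predict_log_ratio(true_model, far, small_genome, hyp) == 0.0
    # the MM probe turned into a PM by the substitution gains signal
    mm = small_design[401]
    alt_genome_space = mm.central_alt if mm.strand == "+" else \
        oracle.COMP[mm.central_alt]
    hyp2 = Hypothesis(mm.position, alt_genome_space)
    assert tc.predict_log_ratio(true_model, mm, small_genome, hyp2) > 0


# ---------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------
def test_parameter_count_and_vector_round_trip(true_model):
    v = true_model.to_vector()
    assert v.shape == (343,)
    back = tc.EnergyModel.from_vector(v)
    assert np.array_equal(back.to_vector(), v)


def test_json_round_trip(tmp_path, true_model):
    path = tmp_path / "model.json"
    true_model.to_json(path)
    back = tc.EnergyModel.from_json(path)
    assert np.allclose(back.to_vector(), true_model.to_vector())
    doc = json.loads(path.read_text())
    assert doc["schema_version"] == 1


def test_model_validation():
    with pytest.raises(ValueError):
        tc.EnergyModel(np.ones(63), np.ones(64), np.ones((64, 3)),
                       np.ones(19), 1, 1, 1, 1)
    with pytest.raises(ValueError):
        tc.EnergyModel(np.ones(64), np.ones(64), np.ones((64, 3)),
                       np.ones(19), -1, 1, 1, 1)
    with pytest.raises(ValueError):
        Hypothesis(10, None)
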