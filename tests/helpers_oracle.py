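"""Independent brute-force reimplementations used as test oracles.

Everything here is deliberately naive (pure-Python loops over string
sequences, direct formula evaluation) and shares no code with the
package's vectorized paths.
"""
import math

BASES = "ACGT"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq):
    return "".join(COMP[b] for b in reversed(seq))


def window(genome, center, circular):
    """Forward-strand 21-mer centered on a 1-based position."""
    L = len(genome)
    out = []
    for off in range(-10, 11):
        i = center - 1 + off
        if circular:
            i %= L
        elif not 0 <= i < L:
            raise IndexError("window outside linear genome")
        out.append(genome[i])
    return "".join(out)


def pm_seq(genome, center, strand, circular=True):
    w = window(genome, center, circular)
    return w if strand == "+" else revcomp(w)


def triplet(seq3):
    return 16 * BASES.index(seq3[0]) + 4 * BASES.index(seq3[1]) \
        + BASES.index(seq3[2])


def weighted_sum(eps, weights, seq):
    """Sum over triplet centers k = 2..20 (1-based) of w_k * eps[triplet]."""
    total = 0.0
    for k in range(1, 20):  # 0-based centers 1..19
        total += weights[k - 1] * eps[triplet(seq[k - 1:k + 2])]
    return total


def adjusted_energy(model, pm, probe, target):
    """Specific energy of the PM locus minus one penalty per probe-target
    mismatch; terminal (first/last base) mismatches carry no penalty."""
    g = weighted_sum(model.eps_specific, model.weights, pm)
    for k in range(21):
        if probe[k] != target[k]:
            if k in (0, 20):
                continue
            trip = triplet(pm[k - 1:k + 2])
            sub = probe[k] if probe[k] != pm[k] else target[k]
            others = [b for b in BASES if b != pm[k]]
            g -= model.penalty[trip][others.index(sub)]
    return g


def log_intensity(model, g_s, g_ns, g_f, specific=True):
    ks = math.exp(model.alpha * g_s) if specific else 0.0
    kns = math.exp(model.alpha * g_ns) * model.conc_nonspecific
    kf = math.exp(model.alpha * g_f)
    frac = (ks + kns) / (1.0 + kf + ks + kns)
    return math.log(model.intensity_scale * frac + model.background)


def predict_log_intensity(model, probe, genome, hyp_pos, hyp_alt, folding,
                          circular=True):
    """hyp_pos/hyp_alt None for the reference hypothesis."""
    target_genome = genome
    if hyp_pos is not None:
        target_genome = genome[:hyp_pos - 1] + hyp_alt + genome[hyp_pos:]
    pm = pm_seq(genome, probe.position, probe.strand, circular)
    target = pm_seq(target_genome, probe.position, probe.strand, circular)
    g_s = adjusted_energy(model, pm, probe.sequence, target)
    g_ns = weighted_sum(model.eps_nonspecific, model.weights, probe.sequence)
    return log_intensity(model, g_s, g_ns, folding)


def folding_energy(seq, stack, loop_penalty, min_loop):
    """Exhaustive single-stem hairpin enumeration on the string."""
    n = len(seq)
    best = 0.0
    for l in range(2, n):
        for i in range(0, n - l + 1):
            for j in range(i + l + min_loop, n - l + 1):
                if seq[i:i + l] == revcomp(seq[j:j + l]):
                    score = sum(
                        stack[4 * BASES.index(seq[i + k])
                              + BASES.index(seq[i + k + 1])]
                        for k in range(l - 1)) - loop_penalty
                    best = max(best, score)
    return best


def position_residual(model, design, wt_vals, mut_vals, foldings, i, b,
                      genome, circular=True):
    """E_i(b) from the definitions: sum over covering probes of
    (observed log ratio - predicted log ratio under i -> b)^2.

    ``b`` equal to the reference base (or None) gives D_i.
    wt_vals/mut_vals/foldings are dicts keyed by probe_id.
    """
    L = len(genome)
    total = 0.0
    for probe in design:
        d = abs(probe.position - i)
        if circular:
            d = min(d, L - d)
        if d > 10:
            continue
        obs = math.log(mut_vals[probe.probe_id]) \
            - math.log(wt_vals[probe.probe_id])
        if b is None or b == genome[i - 1]:
            pred = 0.0
        else:
            pred = predict_log_intensity(
                model, probe, genome, i, b, foldings[probe.probe_id],
                circular) - predict_log_intensity(
                model, probe, genome, None, None, foldings[probe.probe_id],
                circular)
        total += (obs - pred) ** 2
    return total


def likelihood_ratio(model, design, wt_vals, mut_vals, foldings, i, b,
                     genome, circular=True):
    return position_residual(model, design, wt_vals, mut_vals, foldings,
                             i, None, genome, circular) \
        - position_residual(model, design, wt_vals, mut_vals, foldings,
                            i, b, genome, circular)
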