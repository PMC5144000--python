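"""Maximum-entropy splice-site model: trainer, scorer, window extraction."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from backsplice.formats import revcomp
from backsplice.maxent import (
    MaxEntDistribution,
    SpliceSiteModel,
    build_constraints,
    empirical_marginals,
    encode,
    extract_window,
    score_site,
    train_maxent,
    train_splice_model,
    UNSCORABLE,
)

BASES = "ACGT"


def all_kmers(k):
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def random_kmers(rng, k, n):
    return ["".join(BASES[i] for i in rng.integers(0, 4, size=k)) for _ in range(n)]


def maxent_oracle(seqs, length, constraints, pseudocount=0.5):
    """Brute-force maximum-entropy fit by convex optimization on the dual.

    Maximizing entropy subject to marginal constraints is equivalent to
    minimizing log Z(theta) - theta . mu over log-linear parameters theta
    (one per constraint cell); solved here with scipy over the full 4**length
    outcome table, independent of the iterative-scaling code path.
    """
    from scipy.optimize import minimize

    emp = empirical_marginals([encode(s) for s in seqs], constraints, pseudocount)
    outcomes = np.array(list(itertools.product(range(4), repeat=length)))
    feats = []  # indicator feature matrix: outcomes x constraint-cells
    mu = []
    for c in constraints:
        table = emp[tuple(c)]
        if len(c) == 1:
            for v in range(4):
                feats.append(outcomes[:, c[0]] == v)
                mu.append(table[v])
        else:
            for v in range(4):
                for w in range(4):
                    feats.append((outcomes[:, c[0]] == v) & (outcomes[:, c[1]] == w))
                    mu.append(table[v, w])
    F = np.array(feats, dtype=float).T
    mu = np.array(mu)

    def dual(theta):
        a = F @ theta
        amax = a.max()
        logz = amax + np.log(np.exp(a - amax).sum())
        return logz - theta @ mu

    def grad(theta):
        a = F @ theta
        p = np.exp(a - a.max())
        p /= p.sum()
        return F.T @ p - mu

    res = minimize(dual, np.zeros(F.shape[1]), jac=grad, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    a = F @ res.x
    p = np.exp(a - a.max())
    return p / p.sum()


# ---------------------------------------------------------------------------
# training


def test_uniform_training_set_gives_uniform_distribution():
    dist = train_maxent(all_kmers(3), 3, "independent")
    assert np.allclose(dist.all_probs(), 1 / 64, atol=1e-9)


def test_singleton_constraints_equal_product_of_marginals(rng):
    seqs = random_kmers(rng, 4, 80)
    cons = build_constraints(4, "independent")
    dist = train_maxent(seqs, 4, "independent")
    emp = empirical_marginals([encode(s) for s in seqs], cons)
    for s in random_kmers(rng, 4, 20):
        idx = encode(s)
        expected = math.prod(emp[(i,)][idx[i]] for i in range(4))
        assert dist.prob(s) == pytest.approx(expected, rel=1e-6)


@pytest.mark.parametrize("order", ["independent", "adjacent"])
def test_trainer_matches_convex_oracle(rng, order):
    seqs = random_kmers(rng, 3, 50)
    cons = build_constraints(3, order)
    dist = train_maxent(seqs, 3, order)
    oracle = maxent_oracle(seqs, 3, cons)
    assert np.abs(dist.all_probs() - oracle).max() < 1e-4


def test_trainer_matches_oracle_nonadjacent_pairs(rng):
    seqs = random_kmers(rng, 4, 60)
    cons = tuple([(i,) for i in range(4)] + [(0, 2), (1, 3)])
    dist = train_maxent(seqs, 4, cons)
    oracle = maxent_oracle(seqs, 4, cons)
    assert np.abs(dist.all_probs() - oracle).max() < 1e-4


def test_training_validates_inputs():
    with pytest.raises(ValueError, match="length"):
        train_maxent(["ACGT"], 3)
    with pytest.warns(UserWarning, match="dropped"):
        dist = train_maxent(["ACN", "ACG"], 3)
    assert dist.length == 3
    with pytest.raises(ValueError, match="empty"):
        with pytest.warns(UserWarning):
            train_maxent(["NNN"], 3)


def test_training_is_deterministic(rng):
    seqs = random_kmers(rng, 3, 30)
    d1 = train_maxent(seqs, 3)
    d2 = train_maxent(list(seqs), 3)
    assert np.array_equal(d1.all_probs(), d2.all_probs())


def test_marginal_recovery_on_model_samples(model):
    """Retraining on samples from a fitted model recovers its marginals."""
    rng = np.random.default_rng(11)
    samples = model.donor.sample(rng, 4000)
    refit = train_maxent(samples, model.donor.length)
    for c in model.donor.constraints:
        assert np.abs(refit.marginal(c) - model.donor.marginal(c)).max() < 0.05


# ---------------------------------------------------------------------------
# normalization


def test_donor_distribution_sums_to_one_exhaustively(model):
    """Exhaustive 4^9 sum against the chain-DP normalizer."""
    assert model.donor.total_probability() == pytest.approx(1.0, abs=1e-6)


def test_acceptor_normalization_monte_carlo(model):
    assert model.acceptor.total_probability(mc_samples=4000) == pytest.approx(1.0, abs=0.1)


# ---------------------------------------------------------------------------
# scoring


def test_model_equal_background_scores_zero(rng):
    dist = train_maxent(all_kmers(3), 3, "independent")  # uniform
    bg = np.full(4, 0.25)
    for s in random_kmers(rng, 3, 10):
        assert score_site(dist, bg, s) == pytest.approx(0.0, abs=1e-9)


def test_score_is_log2_ratio_toy():
    # hand-set model: P("GTA") = 0.5; uniform background P = 0.125 over 3-mers?
    # use a singleton model with P(G)=1, P(T)=1, P(A)=0.5 -> P(GTA)=0.5
    dist = MaxEntDistribution(3, [(0,), (1,), (2,)])
    dist.factors[(0,)] = np.array([1e-12, 1e-12, 1.0, 1e-12])
    dist.factors[(1,)] = np.array([1e-12, 1e-12, 1e-12, 1.0])
    dist.factors[(2,)] = np.array([0.5, 1e-12, 1e-12, 0.5])
    bg = np.full(4, 0.5)  # P_bg(any 3-mer) = 0.125
    assert score_site(dist, bg, "GTA") == pytest.approx(2.0, abs=1e-6)


def test_scores_agree_with_exhaustive_table_oracle(rng):
    seqs = random_kmers(rng, 3, 40)
    dist = train_maxent(seqs, 3)
    bg = np.array([0.3, 0.2, 0.3, 0.2])
    table = dist.all_probs()
    for s in random_kmers(rng, 3, 25):
        idx = encode(s)
        flat = idx[0] * 16 + idx[1] * 4 + idx[2]
        expected = math.log2(table[flat]) - sum(math.log2(bg[i]) for i in idx)
        assert score_site(dist, bg, s) == pytest.approx(expected, abs=1e-9)


def test_sequence_with_n_is_unscorable(model):
    assert model.score_donor("ACGNTACGT") == UNSCORABLE


# ---------------------------------------------------------------------------
# genomic windows and strand symmetry


def test_window_extraction_breakpoint_conventions():
    genome = {"c": "AAACCCGGGTTTAAACCCGGGTTTAAA"}
    # '+' donor at breakpoint 6: 3 exonic left + 6 intronic right
    assert extract_window(genome, "c", "+", 6, 3, 6) == "CCCGGGTTT"
    # '-' at the same breakpoint reads the reverse complement rightward
    assert extract_window(genome, "c", "-", 6, 3, 6) == revcomp(genome["c"][0:9])
    assert extract_window(genome, "c", "+", 1, 3, 6) is None  # off chromosome
    assert extract_window(genome, "c", "-", 25, 3, 6) is None


def test_strand_symmetric_scoring(model, rng):
    seq = "".join(BASES[i] for i in rng.integers(0, 4, size=400))
    genome_f = {"c": seq}
    genome_r = {"c": revcomp(seq)}
    L = len(seq)
    for bp in (50, 100, 213):
        fwd = model.splice_strength(genome_f, ("c", "+", bp), ("c", "+", bp + 60))
        rev = model.splice_strength(genome_r, ("c", "-", L - bp), ("c", "-", L - bp - 60))
        assert fwd.donor_score == pytest.approx(rev.donor_score, abs=1e-9)
        assert fwd.acceptor_score == pytest.approx(rev.acceptor_score, abs=1e-9)
        assert fwd.total == fwd.donor_score + fwd.acceptor_score


def test_random_positions_score_low_in_random_genome(model, rng):
    """Background positions rarely reach the calling threshold."""
    seq = "".join(BASES[i] for i in rng.integers(0, 4, size=30000))
    genome = {"c": seq}
    totals = []
    for _ in range(1000):
        d = int(rng.integers(30, 29000))
        a = int(rng.integers(30, 29000))
        ss = model.splice_strength(genome, ("c", "+", d), ("c", "+", a))
        totals.append(ss.total)
    totals = np.array(totals)
    assert np.median(totals) < 0
    assert (totals >= 10.0).mean() < 0.01


# ---------------------------------------------------------------------------
# serialization


def test_model_json_roundtrip(model, tmp_path, rng):
    p = tmp_path / "model.json"
    model.to_json(p)
    back = SpliceSiteModel.from_json(p)
    for s in random_kmers(rng, 9, 10):
        assert back.score_donor(s) == pytest.approx(model.score_donor(s), abs=1e-12)
    for s in random_kmers(rng, 23, 10):
        assert back.score_acceptor(s) == pytest.approx(model.score_acceptor(s), abs=1e-12)


def test_train_splice_model_window_lengths(rng):
    with pytest.raises(ValueError):
        train_splice_model(random_kmers(rng, 8, 5), random_kmers(rng, 23, 5))
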