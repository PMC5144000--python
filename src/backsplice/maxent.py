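"""Trainable maximum-entropy splice-site model and splice-strength scoring.

A splice site is modelled as a fixed-width window: 9 nt for donors (last 3
exonic + first 6 intronic bases) and 23 nt for acceptors (last 20 intronic +
first 3 exonic bases), both in transcript orientation.  The sequence
distribution over a window is the maximum-entropy distribution subject to
empirical marginal constraints (position singletons, adjacent position pairs,
and optionally arbitrary position pairs), fitted by iterative proportional
scaling.  Splice strength is the log-odds, in bits, of a window under the
site model versus a 0th-order background; the strength of a candidate
junction is the sum of its donor and acceptor scores.

The acceptor 23-mer is never materialized: with singleton and adjacent-pair
constraints the model is chain-factorized and all quantities (normalizer,
marginals, probabilities, samples) are computed by transfer-matrix dynamic
programming.  Models with non-adjacent pair constraints are supported for
short windows by exhaustive enumeration.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(BASES)}

UNSCORABLE = float("-inf")

DONOR_WINDOW = (3, 6)  # (exonic, intronic) bases around the exon|intron boundary
ACCEPTOR_WINDOW = (20, 3)  # (intronic, exonic) bases around the intron|exon boundary

DEFAULT_THRESHOLD = 10.0  # bits, on the donor+acceptor total


def encode(seq: str) -> np.ndarray | None:
    """Map an ACGT string to integer indices; None if unscorable (N etc.)."""
    try:
        return np.array([_B2I[b] for b in seq], dtype=np.int64)
    except KeyError:
        return None


def _categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Row-wise categorical draws from an (n, 4) probability matrix."""
    cdf = np.cumsum(probs, axis=1)
    u = rng.random(len(probs))
    return np.minimum((u[:, None] > cdf).sum(axis=1), probs.shape[1] - 1)


def build_constraints(length: int, order: str = "adjacent") -> tuple[tuple[int, ...], ...]:
    """Constraint sets: 'independent' = singletons, 'adjacent' adds (i, i+1) pairs."""
    singles = [(i,) for i in range(length)]
    if order == "independent":
        return tuple(singles)
    if order == "adjacent":
        return tuple(singles + [(i, i + 1) for i in range(length - 1)])
    raise ValueError(f"unknown constraint order {order!r}")


class MaxEntDistribution:
    """Maximum-entropy distribution over ACGT^length as a product of factors.

    One multiplicative factor per imposed marginal constraint.  If every pair
    constraint is adjacent the distribution is a chain and is handled by
    transfer-matrix DP; otherwise the window must be short enough (<= 10 nt)
    to enumerate.
    """

    MAX_ENUM_LENGTH = 10

    def __init__(self, length: int, constraints: Sequence[tuple[int, ...]], factors=None):
        self.length = int(length)
        self.constraints = tuple(tuple(c) for c in constraints)
        for c in self.constraints:
            if len(c) not in (1, 2) or any(not 0 <= p < length for p in c):
                raise ValueError(f"bad constraint {c}")
        if factors is None:
            factors = {c: np.ones((4,) * len(c)) for c in self.constraints}
        self.factors = {tuple(c): np.asarray(f, dtype=float) for c, f in factors.items()}
        self._chain = all(len(c) == 1 or c[1] - c[0] == 1 for c in self.constraints)
        if not self._chain and self.length > self.MAX_ENUM_LENGTH:
            raise ValueError(
                "non-adjacent pair constraints require window length "
                f"<= {self.MAX_ENUM_LENGTH}"
            )
        self._cache = None

    # -- internal engines ---------------------------------------------------

    def _invalidate(self):
        self._cache = None

    def _chain_params(self):
        h = [np.ones(4) for _ in range(self.length)]
        J = [np.ones((4, 4)) for _ in range(max(self.length - 1, 0))]
        for c, f in self.factors.items():
            if len(c) == 1:
                h[c[0]] = h[c[0]] * f
            else:
                J[c[0]] = J[c[0]] * f
        return h, J

    def _messages(self):
        """Forward/backward messages for the chain; cached until factors change."""
        if self._cache is not None:
            return self._cache
        h, J = self._chain_params()
        L = self.length
        v = [None] * L
        v[0] = h[0].copy()
        for i in range(1, L):
            v[i] = (v[i - 1] @ J[i - 1]) * h[i]
        b = [None] * L
        b[L - 1] = np.ones(4)
        for i in range(L - 2, -1, -1):
            b[i] = J[i] @ (h[i + 1] * b[i + 1])
        self._cache = (h, J, v, b, float(v[L - 1].sum()))
        return self._cache

    def _digits(self):
        n = 4**self.length
        powers = 4 ** np.arange(self.length - 1, -1, -1, dtype=np.int64)
        return (np.arange(n, dtype=np.int64)[:, None] // powers) % 4

    def _enum_weights(self):
        d = self._digits()
        w = np.ones(len(d))
        for c, f in self.factors.items():
            if len(c) == 1:
                w *= f[d[:, c[0]]]
            else:
                w *= f[d[:, c[0]], d[:, c[1]]]
        return d, w

    # -- public API ---------------------------------------------------------

    @property
    def log2_z(self) -> float:
        if self._chain:
            return math.log2(self._messages()[4])
        return math.log2(self._enum_weights()[1].sum())

    def prob(self, seq: str | np.ndarray) -> float:
        idx = encode(seq) if isinstance(seq, str) else np.asarray(seq)
        if idx is None or len(idx) != self.length:
            raise ValueError("sequence does not match window length")
        logw = 0.0
        for c, f in self.factors.items():
            logw += math.log(f[tuple(idx[list(c)])])
        if self._chain:
            z = self._messages()[4]
        else:
            z = self._enum_weights()[1].sum()
        return math.exp(logw) / z

    def marginal(self, c: tuple[int, ...]) -> np.ndarray:
        c = tuple(c)
        if self._chain:
            h, J, v, b, z = self._messages()
            if len(c) == 1:
                i = c[0]
                return v[i] * b[i] / z
            i = c[0]
            p = v[i][:, None] * J[i] * (h[i + 1] * b[i + 1])[None, :]
            return p / z
        d, w = self._enum_weights()
        w = w / w.sum()
        if len(c) == 1:
            return np.bincount(d[:, c[0]], weights=w, minlength=4)
        flat = d[:, c[0]] * 4 + d[:, c[1]]
        return np.bincount(flat, weights=w, minlength=16).reshape(4, 4)

    def all_probs(self) -> np.ndarray:
        """Full probability table, shape (4**length,); short windows only."""
        if self.length > self.MAX_ENUM_LENGTH:
            raise ValueError("window too long to materialize")
        _, w = self._enum_weights()
        return w / w.sum()

    def total_probability(self, mc_samples: int = 0, rng=None) -> float:
        """Sum of P over the full outcome space.

        For windows short enough to enumerate, the exhaustive sum of outcome
        weights is divided by the chain-DP normalizer, so the two computation
        routes check each other.  Longer chain windows are checked by
        importance sampling from the positionwise marginals when
        ``mc_samples`` is given.
        """
        if self.length <= self.MAX_ENUM_LENGTH:
            num = float(self._enum_weights()[1].sum())
            z = self._messages()[4] if self._chain else num
            return num / z
        if not mc_samples:
            raise ValueError("window too long to enumerate; pass mc_samples")
        rng = np.random.default_rng(0) if rng is None else rng
        q = np.stack([self.marginal((i,)) for i in range(self.length)])
        draws = np.stack([rng.choice(4, size=mc_samples, p=q[i]) for i in range(self.length)], axis=1)
        log_q = np.log([q[i][draws[:, i]] for i in range(self.length)]).sum(axis=0)
        log_p = np.array([math.log(max(self.prob(x), 1e-300)) for x in draws])
        return float(np.exp(log_p - log_q).mean())

    def sample_array(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw n sequences as an (n, length) index array.

        Chain models use forward filtering / backward sampling; enumerable
        models draw from the full table.
        """
        if not self._chain:
            probs = self.all_probs()
            draws = rng.choice(len(probs), size=n, p=probs)
            return self._digits()[draws]
        h, J, v, b, z = self._messages()
        L = self.length
        x = np.empty((n, L), dtype=np.int64)
        p_last = v[L - 1] / v[L - 1].sum()
        x[:, L - 1] = _categorical(rng, np.tile(p_last, (n, 1)))
        for i in range(L - 2, -1, -1):
            cond = v[i][None, :] * J[i].T  # rows: value of x_{i+1}
            cond = cond / cond.sum(axis=1, keepdims=True)
            x[:, i] = _categorical(rng, cond[x[:, i + 1]])
        return x

    def sample(self, rng: np.random.Generator, n: int = 1) -> list[str]:
        return ["".join(BASES[k] for k in row) for row in self.sample_array(rng, n)]

    def log2_prob_array(self, x: np.ndarray) -> np.ndarray:
        """log2 P for an (n, length) index array (chain or enumerable)."""
        x = np.atleast_2d(x)
        logw = np.zeros(len(x))
        for c, f in self.factors.items():
            if len(c) == 1:
                logw += np.log2(f[x[:, c[0]]])
            else:
                logw += np.log2(f[x[:, c[0]], x[:, c[1]]])
        return logw - self.log2_z

    def to_dict(self) -> dict:
        return {
            "length": self.length,
            "constraints": [list(c) for c in self.constraints],
            "factors": {",".join(map(str, c)): f.tolist() for c, f in self.factors.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaxEntDistribution":
        factors = {
            tuple(int(x) for x in k.split(",")): np.array(v)
            for k, v in d["factors"].items()
        }
        return cls(d["length"], [tuple(c) for c in d["constraints"]], factors)


def empirical_marginals(
    seqs: Sequence[np.ndarray], constraints, pseudocount: float = 0.5
) -> dict[tuple[int, ...], np.ndarray]:
    """Pseudocount-smoothed marginals, mutually consistent across constraints.

    Smoothing mixes the empirical distribution with the uniform distribution
    at a single rate equivalent to ``pseudocount`` observations per cell of
    the largest constraint table; applying per-table pseudocounts directly
    would make singleton and pair marginals incompatible (no joint
    distribution has both), and iterative scaling would never converge.
    """
    mat = np.stack(seqs)
    n = len(mat)
    max_cells = 4 ** max(len(c) for c in constraints)
    lam = pseudocount * max_cells / (n + pseudocount * max_cells)
    out = {}
    for c in constraints:
        if len(c) == 1:
            counts = np.bincount(mat[:, c[0]], minlength=4).astype(float)
            uniform = 0.25
        else:
            flat = mat[:, c[0]] * 4 + mat[:, c[1]]
            counts = np.bincount(flat, minlength=16).astype(float).reshape(4, 4)
            uniform = 1.0 / 16.0
        out[tuple(c)] = (1 - lam) * counts / n + lam * uniform
    return out


def train_maxent(
    training_seqs: Iterable[str],
    length: int,
    constraints: Sequence[tuple[int, ...]] | str = "adjacent",
    pseudocount: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MaxEntDistribution:
    """Fit a maximum-entropy distribution by iterative proportional scaling.

    Training sequences must all have the window length; sequences with
    non-ACGT characters are dropped with a warning.  Convergence is declared
    when the maximum absolute deviation between model and (pseudocount-
    smoothed) empirical marginals falls below ``tol``.
    """
    if isinstance(constraints, str):
        constraints = build_constraints(length, constraints)
    encoded = []
    dropped = 0
    for s in training_seqs:
        if len(s) != length:
            raise ValueError(f"training sequence length {len(s)} != window {length}")
        idx = encode(s.upper())
        if idx is None:
            dropped += 1
        else:
            encoded.append(idx)
    if dropped:
        warnings.warn(f"dropped {dropped} training sequences with non-ACGT characters")
    if not encoded:
        raise ValueError("empty effective training set")
    emp = empirical_marginals(encoded, constraints, pseudocount)
    dist = MaxEntDistribution(length, constraints)
    for _ in range(max_iter):
        for c in constraints:
            m = dist.marginal(c)
            dist.factors[tuple(c)] = dist.factors[tuple(c)] * (emp[tuple(c)] / m)
            dist._invalidate()
        dev = max(float(np.abs(dist.marginal(c) - emp[tuple(c)]).max()) for c in constraints)
        if dev < tol:
            break
    return dist


# ---------------------------------------------------------------------------
# Scoring

def score_site(model_dist: MaxEntDistribution, background: np.ndarray, seq: str) -> float:
    """log2( P_model(seq) / P_background(seq) ) in bits; -inf if unscorable."""
    idx = encode(seq.upper()) if isinstance(seq, str) else seq
    if idx is None:
        return UNSCORABLE
    if len(idx) != model_dist.length:
        raise ValueError("sequence does not match window length")
    p_bg = float(np.log2(background[idx]).sum())
    return math.log2(model_dist.prob(idx)) - p_bg


def extract_window(
    genome: dict[str, str], chrom: str, strand: str, breakpoint: int, up: int, down: int
) -> str | None:
    """Window of `up` transcript-upstream + `down` downstream bases at a breakpoint.

    A breakpoint is a 0-based inter-base genomic coordinate (between bases
    breakpoint-1 and breakpoint).  Returns None if the window runs off the
    chromosome.
    """
    seq = genome.get(chrom)
    if seq is None:
        return None
    if strand == "+":
        s, e = breakpoint - up, breakpoint + down
        if s < 0 or e > len(seq):
            return None
        return seq[s:e]
    s, e = breakpoint - down, breakpoint + up
    if s < 0 or e > len(seq):
        return None
    from .formats import revcomp

    return revcomp(seq[s:e])


@dataclass(frozen=True)
class SpliceStrength:
    donor_score: float
    acceptor_score: float

    @property
    def total(self) -> float:
        return self.donor_score + self.acceptor_score


class SpliceSiteModel:
    """Donor + acceptor maximum-entropy models with a shared 0th-order background."""

    FORMAT_VERSION = 1

    def __init__(
        self,
        donor: MaxEntDistribution,
        acceptor: MaxEntDistribution,
        background: np.ndarray | None = None,
        donor_window: tuple[int, int] = DONOR_WINDOW,
        acceptor_window: tuple[int, int] = ACCEPTOR_WINDOW,
    ):
        if donor.length != sum(donor_window):
            raise ValueError("donor model length does not match window")
        if acceptor.length != sum(acceptor_window):
            raise ValueError("acceptor model length does not match window")
        self.donor = donor
        self.acceptor = acceptor
        self.background = (
            np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        )
        if not math.isclose(self.background.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")
        self.donor_window = donor_window
        self.acceptor_window = acceptor_window

    def score_donor(self, seq: str) -> float:
        return score_site(self.donor, self.background, seq)

    def score_acceptor(self, seq: str) -> float:
        return score_site(self.acceptor, self.background, seq)

    def donor_site_score(self, genome, chrom: str, strand: str, breakpoint: int) -> float:
        w = extract_window(genome, chrom, strand, breakpoint, *self.donor_window)
        return UNSCORABLE if w is None else self.score_donor(w)

    def acceptor_site_score(self, genome, chrom: str, strand: str, breakpoint: int) -> float:
        w = extract_window(genome, chrom, strand, breakpoint, *self.acceptor_window)
        return UNSCORABLE if w is None else self.score_acceptor(w)

    def splice_strength(
        self,
        genome: dict[str, str],
        donor: tuple[str, str, int],
        acceptor: tuple[str, str, int],
    ) -> SpliceStrength:
        """Total splice strength of a (donor breakpoint, acceptor breakpoint) pair."""
        return SpliceStrength(
            self.donor_site_score(genome, *donor),
            self.acceptor_site_score(genome, *acceptor),
        )

    # -- serialization ------------------------------------------------------

    def to_json(self, path) -> None:
        d = {
            "format_version": self.FORMAT_VERSION,
            "donor_window": list(self.donor_window),
            "acceptor_window": list(self.acceptor_window),
            "background": self.background.tolist(),
            "donor": self.donor.to_dict(),
            "acceptor": self.acceptor.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path) -> "SpliceSiteModel":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("format_version") != cls.FORMAT_VERSION:
            raise ValueError("unsupported model file version")
        return cls(
            MaxEntDistribution.from_dict(d["donor"]),
            MaxEntDistribution.from_dict(d["acceptor"]),
            np.array(d["background"]),
            tuple(d["donor_window"]),
            tuple(d["acceptor_window"]),
        )


def train_splice_model(
    donor_seqs: Iterable[str],
    acceptor_seqs: Iterable[str],
    constraints: str = "adjacent",
    background: np.ndarray | None = None,
    pseudocount: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> SpliceSiteModel:
    donor = train_maxent(donor_seqs, sum(DONOR_WINDOW), constraints, pseudocount, tol, max_iter)
    acceptor = train_maxent(
        acceptor_seqs, sum(ACCEPTOR_WINDOW), constraints, pseudocount, tol, max_iter
    )
    return SpliceSiteModel(donor, acceptor, background)


# ---------------------------------------------------------------------------
# Annotation-based site extraction and threshold calibration

def annotated_intron_boundaries(transcripts) -> list[tuple[str, str, int, int]]:
    """(chrom, strand, donor_breakpoint, acceptor_breakpoint) per annotated intron."""
    out = []
    for t in transcripts:
        for (s1, e1), (s2, e2) in zip(t.exons, t.exons[1:]):
            if t.strand == "+":
                out.append((t.chrom, "+", e1, s2))
            else:
                out.append((t.chrom, "-", s2, e1))
    return out


def extract_annotated_sites(genome, transcripts) -> tuple[list[str], list[str]]:
    """Donor and acceptor training windows from annotated intron boundaries."""
    donors, acceptors = [], []
    for chrom, strand, dbp, abp in annotated_intron_boundaries(transcripts):
        dw = extract_window(genome, chrom, strand, dbp, *DONOR_WINDOW)
        aw = extract_window(genome, chrom, strand, abp, *ACCEPTOR_WINDOW)
        if dw is not None:
            donors.append(dw)
        if aw is not None:
            acceptors.append(aw)
    return donors, acceptors


def calibration_fraction(
    model: SpliceSiteModel, genome, transcripts, threshold: float = DEFAULT_THRESHOLD
) -> float:
    """Fraction of annotated donor/acceptor pairs whose total score reaches threshold."""
    pairs = annotated_intron_boundaries(transcripts)
    if not pairs:
        raise ValueError("no annotated introns")
    n_pass = 0
    for chrom, strand, dbp, abp in pairs:
        ss = model.splice_strength(genome, (chrom, strand, dbp), (chrom, strand, abp))
        if ss.total >= threshold:
            n_pass += 1
    return n_pass / len(pairs)
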