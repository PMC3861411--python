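"""Position frequency matrix algebra and SVR-driven motif transfer.

This module implements the motif-inference core of the workflow:

* PFM containers with TRANSFAC-like and JASPAR dialect input/output;
* the Smax log-odds PFM similarity: hits of a PFM are windows whose
  log-odds score against an iid background clears a per-PFM significance
  threshold; gamma_{X,Y}(k) is the exact probability that a hit of X and a
  hit of Y co-occur at offset k in random DNA; s(k) = log2 of the ratio of
  gamma to the product of marginal hit probabilities; Smax maximizes s(k)
  over offsets, motif orders and strand orientations.  The normalized
  similarity divides Smax by the geometric mean of the self-similarities
  and maps to a distance on [0, 1];
* DNA-binding-domain pair features (global alignment identity, normalized
  local alignment score, mismatch kernel, local alignment kernel) feeding
  per-superclass support vector regression models that predict PFM
  similarity from domain similarity;
* best-match selection with a dynamic or static threshold, relative
  average-distance outlier filtering, and guide-tree (UPGMA) progressive
  merging of the selected PFMs into a consensus motif.

Hit probabilities and gamma are computed exactly: per-position log-odds
scores are quantized to integer units of 1e-6 bits, window-score
distributions are enumerated by convolution over positions, and the joint
distribution at an overlap factorizes into shared positions (enumerated
jointly) and offset-exclusive positions (independent tails).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from sklearn.base import BaseEstimator
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from Bio import motifs as bio_motifs
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import AMINO_ACIDS

logger = logging.getLogger(__name__)

DNA = "ACGT"
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G under ACGT order
#: integer score quantum: scores are stored in units of 1e-6 bits
SCORE_SCALE = 1_000_000


class PfmError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PFM container and IO

@dataclass
class Pfm:
    """A position frequency matrix over (A, C, G, T)."""

    id: str
    counts: np.ndarray  # L x 4, nonnegative
    source: Optional[str] = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise PfmError(f"{self.id}: counts must be L x 4")
        if self.counts.shape[0] < 1:
            raise PfmError(f"{self.id}: empty matrix")
        if (self.counts < 0).any():
            raise PfmError(f"{self.id}: negative counts")
        if (self.counts.sum(axis=1) == 0).any():
            raise PfmError(f"{self.id}: zero count column")

    def __len__(self):
        return self.counts.shape[0]

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=1, keepdims=True)

    def reverse_complement(self) -> "Pfm":
        return Pfm(id=self.id + "_rc",
                   counts=self.counts[::-1, _COMPLEMENT].copy(),
                   source=self.source)

    def key(self) -> bytes:
        """Hashable identity of the matrix content."""
        return np.ascontiguousarray(self.counts).tobytes()


def _counts_dict(pfm: Pfm) -> dict:
    return {b: [float(x) for x in pfm.counts[:, i]]
            for i, b in enumerate(DNA)}


def read_pfm(path, dialect: str) -> list[Pfm]:
    """Read PFMs from a JASPAR or TRANSFAC-like file."""
    if dialect not in ("jaspar", "transfac"):
        raise ValueError(f"unknown PFM dialect {dialect!r}")
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, dialect)
    out = []
    for i, m in enumerate(parsed):
        if dialect == "jaspar":
            ident = m.matrix_id or m.name or f"pfm_{i + 1}"
        else:
            ident = m.get("ID") or m.get("AC") or f"pfm_{i + 1}"
        counts = np.column_stack([m.counts[b] for b in DNA])
        out.append(Pfm(id=ident, counts=counts))
    return out


def write_pfm(pfms: Sequence[Pfm], path, dialect: str) -> None:
    """Write PFMs in the JASPAR or TRANSFAC-like dialect (counts preserved)."""
    if dialect == "jaspar":
        from Bio.motifs import jaspar
        ms = [jaspar.Motif(matrix_id=p.id, name=p.id,
                           counts=_counts_dict(p)) for p in pfms]
    elif dialect == "transfac":
        from Bio.motifs import transfac
        ms = []
        for p in pfms:
            m = transfac.Motif(alphabet="ACGT", counts=_counts_dict(p))
            m["ID"] = p.id
            ms.append(m)
    else:
        raise ValueError(f"unknown PFM dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write(bio_motifs.write(ms, dialect))


# ---------------------------------------------------------------------------
# hit probabilities and the Smax log-odds similarity

@dataclass
class TransferConfig:
    """Parameters of motif transfer and the Smax machinery."""

    bmt_min: float = 0.5
    bmt_max: float = 0.95
    dynamic: bool = True
    outlier_factor: float = 1.5          # tau: relative mean-distance cutoff
    alpha_hit: float = 0.01              # per-window hit significance
    pseudocount: float = 0.01            # added to probability columns
    background: tuple = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        if not 0 < self.bmt_min <= self.bmt_max < 1:
            raise ValueError("need 0 < bmt_min <= bmt_max < 1")
        if self.outlier_factor <= 1:
            raise ValueError("outlier factor must exceed 1")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must be a distribution over ACGT")


DEFAULT_CONFIG = TransferConfig()


def _log_odds_scores(pfm: Pfm, config: TransferConfig) -> np.ndarray:
    """Integer-quantized per-position log2-odds scores (L x 4)."""
    bg = np.asarray(config.background)
    probs = (pfm.probabilities + config.pseudocount)
    probs /= probs.sum(axis=1, keepdims=True)
    return np.rint(np.log2(probs / bg) * SCORE_SCALE).astype(np.int64)


def _enumerate_scores(rows: np.ndarray, bg: np.ndarray):
    """Enumerate per-assignment summed scores and probabilities.

    ``rows`` is m x 4 integer scores; returns (scores[4^m], probs[4^m])
    aligned over all letter assignments of the m positions.
    """
    vals = np.zeros(1, dtype=np.int64)
    probs = np.ones(1)
    for row in rows:
        vals = (vals[:, None] + row[None, :]).ravel()
        probs = (probs[:, None] * bg[None, :]).ravel()
    return vals, probs


def _collapse(vals, probs):
    uniq, inv = np.unique(vals, return_inverse=True)
    return uniq, np.bincount(inv, weights=probs)


#: support cap beyond which score distributions are re-quantized to a
#: coarser grid (only reachable for wide profiles, e.g. merged consensus
#: matrices with overhangs; short motifs stay exact)
_SUPPORT_CAP = 1 << 12


def _cap_support(vals, probs, cap=_SUPPORT_CAP):
    vals, probs = _collapse(vals, probs)
    if len(vals) > cap:
        span = int(vals.max() - vals.min())
        q = span // cap + 1
        vals = (np.rint(vals / q) * q).astype(np.int64)
        vals, probs = _collapse(vals, probs)
    return vals, probs


def _score_distribution(rows: np.ndarray, bg: np.ndarray):
    """Distribution of the summed window score (values sorted ascending).

    Exact while the support stays below :data:`_SUPPORT_CAP`; beyond that
    the values are re-quantized to a coarser integer grid.
    """
    vals = np.zeros(1, dtype=np.int64)
    probs = np.ones(1)
    for row in rows:
        vals = (vals[:, None] + row[None, :]).ravel()
        probs = (probs[:, None] * bg[None, :]).ravel()
        if len(vals) > _SUPPORT_CAP:
            vals, probs = _cap_support(vals, probs)
    return _collapse(vals, probs)


@dataclass
class _TailTable:
    """P(S >= x) lookup for a discrete integer-score distribution."""

    vals: np.ndarray  # sorted ascending
    tail: np.ndarray  # tail[i] = P(S >= vals[i]); extra trailing 0

    @classmethod
    def from_distribution(cls, vals, probs):
        tail = np.concatenate([np.cumsum(probs[::-1])[::-1], [0.0]])
        return cls(vals=vals, tail=tail)

    def __call__(self, x) -> np.ndarray:
        idx = np.searchsorted(self.vals, x, side="left")
        return self.tail[idx]


def hit_probability(pfm: Pfm, config: TransferConfig = DEFAULT_CONFIG):
    """Hit threshold and exact per-window hit probability of a PFM.

    Windows of length L are scored by summed log2-odds against the
    background; the threshold is the smallest achievable score whose
    exceedance probability under the background is <= ``config.alpha_hit``,
    and alpha the exact exceedance at that threshold.  When no achievable
    score is that rare (e.g. an uninformative PFM where all windows tie)
    the threshold is unattainable and alpha = 0.

    Returns ``(threshold_bits, alpha)`` with the threshold in bits (float).
    """
    profile = _PfmProfile.build(pfm, config)
    if profile.threshold is None:
        return math.inf, 0.0
    return profile.threshold / SCORE_SCALE, profile.alpha


@dataclass
class _PfmProfile:
    """Cached per-PFM scoring state for Smax computations."""

    scores: np.ndarray          # L x 4 integer log-odds
    threshold: Optional[int]    # integer score threshold; None if unattainable
    alpha: float
    bg: np.ndarray

    @classmethod
    def build(cls, pfm: Pfm, config: TransferConfig) -> "_PfmProfile":
        scores = _log_odds_scores(pfm, config)
        bg = np.asarray(config.background)
        vals, probs = _score_distribution(scores, bg)
        tail = np.cumsum(probs[::-1])[::-1]
        ok = np.flatnonzero(tail <= config.alpha_hit + 1e-12)
        if len(ok) == 0:
            return cls(scores=scores, threshold=None, alpha=0.0, bg=bg)
        i = ok[0]
        return cls(scores=scores, threshold=int(vals[i]),
                   alpha=float(tail[i]), bg=bg)

    def __len__(self):
        return self.scores.shape[0]

    def reverse_complement(self) -> "_PfmProfile":
        return _PfmProfile(scores=self.scores[::-1][:, _COMPLEMENT],
                           threshold=self.threshold, alpha=self.alpha,
                           bg=self.bg)

    def tail_table(self, positions) -> _TailTable:
        key = tuple(positions)
        cache = self.__dict__.setdefault("_tails", {})
        if key not in cache:
            rows = self.scores[list(key)]
            vals, probs = _score_distribution(rows, self.bg)
            cache[key] = _TailTable.from_distribution(vals, probs)
        return cache[key]


def _gamma(px: _PfmProfile, py: _PfmProfile, k: int) -> float:
    """Exact P(hit of X at 0 and hit of Y at offset k) on random DNA.

    Positions covered by only one window contribute independent tails;
    positions shared by both windows are enumerated jointly.
    """
    if px.threshold is None or py.threshold is None:
        return 0.0
    lx, ly = len(px), len(py)
    shared = [i for i in range(lx) if 0 <= i - k < ly]
    if not shared:
        raise ValueError("windows do not overlap at this offset")
    x_excl = [i for i in range(lx) if not (0 <= i - k < ly)]
    y_excl = [j for j in range(ly) if not (0 <= j + k < lx)]
    tail_x = px.tail_table(x_excl)
    tail_y = py.tail_table(y_excl)
    sx = np.zeros(1, dtype=np.int64)
    sy = np.zeros(1, dtype=np.int64)
    p = np.ones(1)
    for i in shared:
        rx = px.scores[i]
        ry = py.scores[i - k]
        sx = (sx[:, None] + rx[None, :]).ravel()
        sy = (sy[:, None] + ry[None, :]).ravel()
        p = (p[:, None] * px.bg[None, :]).ravel()
        if len(sx) > 1 << 16:
            # bound memory and time: collapse identical (sx, sy) pairs,
            # coarsening each margin's grid if exact duplicates are rare
            for arr in (sx, sy):
                span = int(arr.max() - arr.min())
                q = span // 192 + 1
                if q > 1:
                    np.copyto(arr, (np.rint(arr / q) * q).astype(np.int64))
            key = np.stack([sx, sy], axis=1)
            uniq, inv = np.unique(key, axis=0, return_inverse=True)
            p = np.bincount(inv, weights=p)
            sx, sy = uniq[:, 0].copy(), uniq[:, 1].copy()
    return float(np.sum(p * tail_x(px.threshold - sx)
                        * tail_y(py.threshold - sy)))


def gamma_overlap(x: Pfm, y: Pfm, k: int,
                  config: TransferConfig = DEFAULT_CONFIG) -> float:
    """Public wrapper around the exact overlap-hit probability gamma."""
    return _gamma(_PfmProfile.build(x, config), _PfmProfile.build(y, config),
                  k)


@dataclass
class PfmSimilarity:
    """Smax similarity between two PFMs and its normalized forms."""

    smax: float
    self_x: float
    self_y: float
    alpha_x: float
    alpha_y: float
    s_norm: float
    distance: float
    best: Optional[tuple] = None  # (orientation tag, offset) of the maximum


def _smax_oriented(px: _PfmProfile, py: _PfmProfile):
    """Max of s(k) = log2(gamma / (alpha_x alpha_y)) over overlap offsets."""
    if px.alpha <= 0 or py.alpha <= 0:
        return None, None
    best = None
    best_k = None
    denom = px.alpha * py.alpha
    for k in range(-(len(py) - 1), len(px)):
        g = _gamma(px, py, k)
        if g <= 0:
            continue
        s = math.log2(g / denom)
        if best is None or s > best:
            best, best_k = s, k
    return best, best_k


class SmaxCache:
    """Memoizes per-PFM profiles, self-similarities and pairwise Smax."""

    def __init__(self, config: TransferConfig = DEFAULT_CONFIG):
        self.config = config
        self._profiles: dict = {}
        self._self: dict = {}
        self._pair: dict = {}

    def profile(self, pfm: Pfm) -> _PfmProfile:
        key = pfm.key()
        if key not in self._profiles:
            self._profiles[key] = _PfmProfile.build(pfm, self.config)
        return self._profiles[key]

    def smax_self(self, pfm: Pfm) -> Optional[float]:
        # gamma(k) <= alpha for any offset/orientation pair drawn from
        # {X, rc(X)}, with equality at offset 0, so the self-similarity is
        # exactly log2(alpha/alpha^2) = -log2(alpha)
        key = pfm.key()
        if key not in self._self:
            alpha = self.profile(pfm).alpha
            self._self[key] = -math.log2(alpha) if alpha > 0 else None
        return self._self[key]

    def _smax_pair(self, x: Pfm, y: Pfm):
        px = self.profile(x)
        bg = np.asarray(self.config.background)
        orientations = [("ff", px, self.profile(y)),
                        ("fr", px, self.profile(y.reverse_complement()))]
        if not (bg[0] == bg[3] and bg[1] == bg[2]):
            # under a complement-asymmetric background, reverse-complementing
            # the first motif is not redundant with the two cases above
            orientations += [
                ("rf", self.profile(x.reverse_complement()),
                 self.profile(y)),
                ("rr", self.profile(x.reverse_complement()),
                 self.profile(y.reverse_complement()))]
        best = None
        best_tag = None
        for tag, pa, pb in orientations:
            s, k = _smax_oriented(pa, pb)
            if s is not None and (best is None or s > best):
                best, best_tag = s, (tag, k)
        return best, best_tag

    def smax(self, x: Pfm, y: Pfm):
        key = tuple(sorted((x.key(), y.key())))
        if key not in self._pair:
            self._pair[key] = self._smax_pair(x, y)
        return self._pair[key]


def smax_similarity(x: Pfm, y: Pfm, config: TransferConfig = DEFAULT_CONFIG,
                    cache: Optional[SmaxCache] = None) -> PfmSimilarity:
    """Smax log-odds similarity of two PFMs.

    The maximum ranges over all overlap offsets, both motif orders and both
    strand orientations.  The normalized similarity is
    smax(X,Y) / sqrt(smax(X,X) smax(Y,Y)), clipped below at 0, and the
    distance is min(1, max(0, 1 - s_norm)).  PFM pairs with no possible
    co-occurring hits (gamma = 0 everywhere, or a degenerate hit threshold)
    get s_norm = 0, distance 1.
    """
    cache = cache or SmaxCache(config)
    px = cache.profile(x)
    py = cache.profile(y)
    smax, best = cache.smax(x, y)
    self_x = cache.smax_self(x)
    self_y = cache.smax_self(y)
    if smax is None or self_x is None or self_y is None \
            or self_x <= 0 or self_y <= 0:
        s_norm = 0.0
    else:
        s_norm = max(0.0, smax / math.sqrt(self_x * self_y))
    distance = min(1.0, max(0.0, 1.0 - s_norm))
    return PfmSimilarity(smax=smax if smax is not None else -math.inf,
                         self_x=self_x if self_x is not None else 0.0,
                         self_y=self_y if self_y is not None else 0.0,
                         alpha_x=px.alpha, alpha_y=py.alpha,
                         s_norm=s_norm, distance=distance, best=best)


def smax_distance(x: Pfm, y: Pfm, config: TransferConfig = DEFAULT_CONFIG,
                  cache: Optional[SmaxCache] = None) -> float:
    """The [0, 1] Smax distance, 1 - normalized similarity."""
    return smax_similarity(x, y, config=config, cache=cache).distance


# ---------------------------------------------------------------------------
# DNA-binding-domain pair features

@dataclass
class DbdPairFeatures:
    """Sequence-similarity features of a DBD pair used for SVR prediction."""

    global_identity: float
    local_score: float     # self-normalized Smith-Waterman score
    mismatch_kernel: float  # (k, m) = (3, 1), self-normalized
    local_alignment_kernel: float  # beta-weighted sum over alignments

    def vector(self, include_kernels: bool = True) -> np.ndarray:
        if include_kernels:
            return np.array([self.global_identity, self.local_score,
                             self.mismatch_kernel,
                             self.local_alignment_kernel])
        return np.array([self.global_identity, self.local_score])


_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_B62_INDEX = {aa: i for i, aa in enumerate(_BLOSUM62.alphabet)}


def _local_aligner():
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = _BLOSUM62
    a.open_gap_score = -12.0
    a.extend_gap_score = -1.0
    return a


def _global_aligner():
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = _BLOSUM62
    a.open_gap_score = -12.0
    a.extend_gap_score = -1.0
    return a


def global_identity(a: str, b: str) -> float:
    """Fraction of identical positions in the optimal global alignment."""
    aligner = _global_aligner()
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def local_score_normalized(a: str, b: str) -> float:
    """sw(a,b) / sqrt(sw(a,a) sw(b,b)) under BLOSUM62 affine gaps."""
    aligner = _local_aligner()
    sab = aligner.score(a, b)
    saa = aligner.score(a, a)
    sbb = aligner.score(b, b)
    if saa <= 0 or sbb <= 0:
        return 0.0
    return float(max(0.0, sab) / math.sqrt(saa * sbb))


def _kmer_neighborhood(kmer: str, m: int) -> Iterable[str]:
    """All k-mers within Hamming distance <= m of ``kmer``."""
    if m == 0:
        yield kmer
        return
    k = len(kmer)
    for n_sub in range(m + 1):
        for positions in itertools.combinations(range(k), n_sub):
            for subs in itertools.product(AMINO_ACIDS, repeat=n_sub):
                if any(kmer[p] == s for p, s in zip(positions, subs)):
                    continue
                chars = list(kmer)
                for p, s in zip(positions, subs):
                    chars[p] = s
                yield "".join(chars)


def _mismatch_counts(seq: str, k: int, m: int) -> dict:
    counts: dict = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if any(c not in _B62_INDEX for c in kmer):
            continue
        for neighbor in _kmer_neighborhood(kmer, m):
            counts[neighbor] = counts.get(neighbor, 0) + 1
    return counts


def mismatch_kernel(a: str, b: str, k: int = 3, m: int = 1,
                    normalized: bool = True) -> float:
    """(k, m)-mismatch string kernel by explicit neighborhood counting."""
    ca = _mismatch_counts(a, k, m)
    cb = _mismatch_counts(b, k, m)
    small, large = (ca, cb) if len(ca) <= len(cb) else (cb, ca)
    kab = float(sum(v * large.get(u, 0) for u, v in small.items()))
    if not normalized:
        return kab
    kaa = float(sum(v * v for v in ca.values()))
    kbb = float(sum(v * v for v in cb.values()))
    if kaa == 0 or kbb == 0:
        return 0.0
    return kab / math.sqrt(kaa * kbb)


def local_alignment_kernel(a: str, b: str, beta: float = 0.5,
                           gap_open: float = 12.0, gap_extend: float = 1.0,
                           normalized: bool = True) -> float:
    """Local alignment kernel: beta-weighted sum over all local alignments.

    As beta grows, log(K)/beta approaches the optimal Smith-Waterman score
    under the same gap scheme.  Returned self-normalized by default
    (k(a,b)/sqrt(k(a,a) k(b,b))).
    """
    if normalized:
        kab = local_alignment_kernel(a, b, beta, gap_open, gap_extend, False)
        kaa = local_alignment_kernel(a, a, beta, gap_open, gap_extend, False)
        kbb = local_alignment_kernel(b, b, beta, gap_open, gap_extend, False)
        if not (np.isfinite(kaa) and np.isfinite(kbb)) or kaa <= 0 or kbb <= 0:
            return 0.0
        return float(kab / math.sqrt(kaa * kbb))
    n, m = len(a), len(b)
    eg_open = math.exp(-beta * gap_open)
    eg_ext = math.exp(-beta * gap_extend)
    ia = [_B62_INDEX[c] for c in a]
    ib = [_B62_INDEX[c] for c in b]
    sub = np.exp(beta * np.array(_BLOSUM62))
    M = np.zeros((n + 1, m + 1))
    X = np.zeros((n + 1, m + 1))
    Y = np.zeros((n + 1, m + 1))
    X2 = np.zeros((n + 1, m + 1))
    Y2 = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        srow = sub[ia[i - 1]]
        for j in range(1, m + 1):
            M[i, j] = srow[ib[j - 1]] * (1.0 + X[i - 1, j - 1]
                                         + Y[i - 1, j - 1] + M[i - 1, j - 1])
            X[i, j] = eg_open * M[i - 1, j] + eg_ext * X[i - 1, j]
            Y[i, j] = eg_open * (M[i, j - 1] + X[i, j - 1]) \
                + eg_ext * Y[i, j - 1]
            X2[i, j] = M[i - 1, j] + X2[i - 1, j]
            Y2[i, j] = M[i, j - 1] + X2[i, j - 1] + Y2[i, j - 1]
    return float(1.0 + X2[n, m] + Y2[n, m] + M[n, m])


def dbd_pair_features(a: str, b: str,
                      include_kernels: bool = True) -> DbdPairFeatures:
    """The four DBD sequence-similarity features of a pair."""
    if not a or not b:
        raise ValueError("empty DBD sequence")
    mmk = mismatch_kernel(a, b) if include_kernels else 0.0
    lak = local_alignment_kernel(a, b) if include_kernels else 0.0
    return DbdPairFeatures(global_identity=global_identity(a, b),
                           local_score=local_score_normalized(a, b),
                           mismatch_kernel=mmk,
                           local_alignment_kernel=lak)


# ---------------------------------------------------------------------------
# SVR models for PFM similarity prediction

SVR_GRID = {"svr__C": [1.0, 10.0, 100.0],
            "svr__gamma": ["scale", 0.1, 1.0]}


def train_pfm_svr(features: np.ndarray, targets: np.ndarray,
                  min_pairs: int = 20, seed: int = 42, cv: int = 3):
    """Fit an epsilon-SVR (RBF) predicting normalized PFM similarity.

    ``features`` are DBD pair feature vectors, ``targets`` the observed
    normalized Smax similarities.  C and gamma are tuned by inner
    cross-validation.  Raises when fewer than ``min_pairs`` pairs are
    available (callers may then pool pairs across superclasses).
    """
    features = np.asarray(features)
    targets = np.asarray(targets)
    if len(features) < min_pairs:
        raise ValueError(
            f"only {len(features)} training pairs (< {min_pairs}); "
            f"pool pairs across superclasses instead")
    pipe = make_pipeline(StandardScaler(), SVR(kernel="rbf", epsilon=0.01))
    gs = GridSearchCV(pipe, SVR_GRID,
                      cv=KFold(cv, shuffle=True, random_state=seed),
                      scoring="neg_mean_squared_error")
    gs.fit(features, targets)
    return gs.best_estimator_


def predict_pfm_similarity(model, features: np.ndarray) -> np.ndarray:
    """Predict normalized PFM similarities, clipped to [0, 1]."""
    return np.clip(model.predict(np.atleast_2d(features)), 0.0, 1.0)


# ---------------------------------------------------------------------------
# best-match selection, outlier filtering, progressive merging

@dataclass
class TfEntry:
    """A training/query transcription factor for motif transfer."""

    id: str
    superclass: str
    dbd_sequence: str
    pfm: Optional[Pfm] = None


@dataclass
class TransferResult:
    query_id: str
    best_matches: list           # (TfEntry, predicted similarity), selected
    threshold: Optional[float]   # realized threshold; None if no prediction
    confidence: Optional[float]  # mean predicted similarity of the selection
    pfm: Optional[Pfm]           # merged consensus, None if no prediction
    n_outliers_removed: int = 0


def select_best_matches(candidates, config: TransferConfig = DEFAULT_CONFIG,
                        threshold="dynamic"):
    """Select candidate best matches against a static or dynamic threshold.

    ``candidates`` is a list of (entry, predicted similarity).  In dynamic
    mode the threshold is the largest value in [bmt_min, bmt_max] still
    admitting at least one candidate, i.e. min(best similarity, bmt_max);
    with no candidate reaching bmt_min there is no prediction.  In static
    mode candidates must reach the fixed threshold.  The confidence is the
    mean predicted similarity of the selected set.
    """
    if not candidates:
        return [], None, None
    sims = np.array([s for _, s in candidates])
    if threshold == "dynamic":
        best = sims.max()
        if best < config.bmt_min:
            return [], None, None
        t = min(float(best), config.bmt_max)
    else:
        t = float(threshold)
    selected = [(e, float(s)) for (e, s) in candidates if s >= t]
    if not selected:
        return [], None, None
    confidence = float(np.mean([s for _, s in selected]))
    return selected, t, confidence


def outlier_filter(pfms: Sequence[Pfm],
                   factor: float = DEFAULT_CONFIG.outlier_factor,
                   config: TransferConfig = DEFAULT_CONFIG,
                   cache: Optional[SmaxCache] = None) -> list[Pfm]:
    """Drop PFMs with high relative average Smax distance to the rest.

    Each matrix's mean distance to the others is compared against
    ``factor`` times the grand mean of those values; a single pass removes
    the offenders but never the last matrix (with identical inputs nothing
    is removed).
    """
    pfms = list(pfms)
    if len(pfms) < 2:
        return pfms
    cache = cache or SmaxCache(config)
    n = len(pfms)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = smax_distance(pfms[i], pfms[j], config=config, cache=cache)
            dmat[i, j] = dmat[j, i] = d
    means = dmat.sum(axis=1) / (n - 1)
    grand = means.mean()
    if grand == 0:
        return pfms
    # inclusive cutoff: saturated distances (capped at 1) can make an
    # outlier's mean land exactly on the boundary
    keep = [p for p, m in zip(pfms, means) if m < factor * grand - 1e-12]
    if not keep:
        keep = [pfms[int(np.argmin(means))]]
    return keep


def _column_correlation(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.dot(a - a.mean(), b - b.mean()) / (4 * sa * sb))


def _align_profiles(ma, wa, mb, wb):
    """Best ungapped sliding-offset alignment of two probability profiles.

    Both orientations of the second profile are tried; the offset
    maximizing the summed Pearson correlation of overlapping probability
    columns wins (ties: first encountered).  Returns the merged
    (matrix, weights).
    """
    la, lb = len(ma), len(mb)
    best = None
    for flipped in (False, True):
        mb_o = mb[::-1, _COMPLEMENT] if flipped else mb
        wb_o = wb[::-1] if flipped else wb
        for k in range(-(lb - 1), la):
            lo, hi = max(0, k), min(la, k + lb)
            if hi <= lo:
                continue
            score = sum(_column_correlation(ma[i], mb_o[i - k])
                        for i in range(lo, hi))
            if best is None or score > best[0]:
                best = (score, mb_o, wb_o, k)
    _, mb_o, wb_o, k = best
    start, end = min(0, k), max(la, k + lb)
    length = end - start
    merged = np.zeros((length, 4))
    weights = np.zeros(length)
    for pos in range(start, end):
        out_i = pos - start
        w = 0.0
        col = np.zeros(4)
        if 0 <= pos < la:
            col += wa[pos] * ma[pos]
            w += wa[pos]
        if 0 <= pos - k < lb:
            col += wb_o[pos - k] * mb_o[pos - k]
            w += wb_o[pos - k]
        merged[out_i] = col / w
        weights[out_i] = w
    merged /= merged.sum(axis=1, keepdims=True)
    return merged, weights


def merge_pfms(pfms: Sequence[Pfm], config: TransferConfig = DEFAULT_CONFIG,
               cache: Optional[SmaxCache] = None,
               merged_id: str = "merged") -> Pfm:
    """Progressively merge PFMs into a consensus along a UPGMA guide tree.

    Pairwise Smax distances define the guide tree; at each internal node
    the two child profiles are aligned by ungapped sliding-offset alignment
    over both orientations (summed Pearson correlation of probability
    columns), aligned columns are averaged weighted by the number of source
    matrices, overhangs are kept, and columns renormalized.
    """
    pfms = list(pfms)
    if not pfms:
        raise ValueError("no PFMs to merge")
    if len(pfms) == 1:
        p = pfms[0]
        return Pfm(id=merged_id, counts=p.probabilities.copy())
    cache = cache or SmaxCache(config)
    n = len(pfms)
    condensed = []
    for i in range(n):
        for j in range(i + 1, n):
            condensed.append(smax_distance(pfms[i], pfms[j], config=config,
                                           cache=cache))
    tree = linkage(np.asarray(condensed), method="average")
    profiles = {i: (p.probabilities.copy(), np.ones(len(p)))
                for i, p in enumerate(pfms)}
    next_id = n
    for a, b, _, _ in tree:
        ma, wa = profiles.pop(int(a))
        mb, wb = profiles.pop(int(b))
        profiles[next_id] = _align_profiles(ma, wa, mb, wb)
        next_id += 1
    (matrix, _), = profiles.values()
    return Pfm(id=merged_id, counts=matrix)


# ---------------------------------------------------------------------------
# the transfer model

class PfmTransferModel(BaseEstimator):
    """Motif transfer by predicted PFM similarity.

    ``fit`` takes training factors (id, superclass, DNA-binding-domain
    sequence, annotated PFM), computes DBD pair features and observed
    normalized Smax similarities for within-superclass pairs whose
    normalized local-alignment similarity exceeds ``min_dbd_similarity``,
    and trains one epsilon-SVR per superclass (pooling across superclasses
    when a class has too few pairs).  ``predict`` scores a query DBD
    against the training factors of its superclass, selects best matches
    by the (dynamic or static) threshold, outlier-filters their PFMs and
    merges the survivors into the predicted motif.
    """

    def __init__(self, bmt="dynamic", config: TransferConfig = None,
                 min_dbd_similarity: float = 0.3, min_pairs: int = 20,
                 include_kernels: bool = True, random_state: int = 42,
                 sim_cache: Optional[SmaxCache] = None):
        self.bmt = bmt
        self.config = config
        self.min_dbd_similarity = min_dbd_similarity
        self.min_pairs = min_pairs
        self.include_kernels = include_kernels
        self.random_state = random_state
        self.sim_cache = sim_cache

    def _features(self, a: str, b: str) -> np.ndarray:
        return dbd_pair_features(
            a, b, include_kernels=self.include_kernels).vector(
                self.include_kernels)

    def fit(self, entries: Sequence[TfEntry], y=None):
        self.config_ = self.config or DEFAULT_CONFIG
        self.cache_ = self.sim_cache or SmaxCache(self.config_)
        self.entries_ = [e for e in entries if e.pfm is not None]
        if not self.entries_:
            raise ValueError("no training factors with annotated PFMs")
        by_class: dict = {}
        for e in self.entries_:
            by_class.setdefault(e.superclass, []).append(e)
        pair_features: dict = {c: [] for c in by_class}
        pair_targets: dict = {c: [] for c in by_class}
        n_features = 4 if self.include_kernels else 2
        for c, members in by_class.items():
            # self-pairs anchor the regression at its fixed point: an
            # identical DBD pair has all similarity features at 1 and PFM
            # similarity exactly 1
            for _ in members:
                pair_features[c].append(np.ones(n_features))
                pair_targets[c].append(1.0)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    a, b = members[i], members[j]
                    if local_score_normalized(
                            a.dbd_sequence,
                            b.dbd_sequence) <= self.min_dbd_similarity:
                        continue
                    pair_features[c].append(
                        self._features(a.dbd_sequence, b.dbd_sequence))
                    pair_targets[c].append(
                        smax_similarity(a.pfm, b.pfm, config=self.config_,
                                        cache=self.cache_).s_norm)
        self.models_ = {}
        pooled_X = [f for c in pair_features for f in pair_features[c]]
        pooled_y = [t for c in pair_targets for t in pair_targets[c]]
        self.pooled_model_ = None
        for c in by_class:
            try:
                self.models_[c] = train_pfm_svr(
                    np.asarray(pair_features[c]),
                    np.asarray(pair_targets[c]),
                    min_pairs=self.min_pairs, seed=self.random_state)
            except ValueError:
                if self.pooled_model_ is None:
                    if len(pooled_X) < 2:
                        raise ValueError(
                            "too few training pairs even when pooled")
                    self.pooled_model_ = train_pfm_svr(
                        np.asarray(pooled_X), np.asarray(pooled_y),
                        min_pairs=min(self.min_pairs, len(pooled_X)),
                        seed=self.random_state)
                self.models_[c] = self.pooled_model_
                logger.info("superclass %r: pooled SVR fallback", c)
        return self

    def candidate_similarities(self, dbd_sequence: str, superclass: str,
                               exclude_id: Optional[str] = None):
        """Predicted similarity of the query to each eligible training TF."""
        model = self.models_.get(superclass, self.pooled_model_)
        candidates = [e for e in self.entries_
                      if e.superclass == superclass and e.id != exclude_id]
        if model is None or not candidates:
            return []
        feats = np.vstack([self._features(dbd_sequence, e.dbd_sequence)
                           for e in candidates])
        sims = predict_pfm_similarity(model, feats)
        return list(zip(candidates, sims))

    def transfer_from_similarities(self, candidates, threshold=None,
                                   query_id: str = "query") -> TransferResult:
        if threshold is None:
            threshold = self.bmt
        selected, t, confidence = select_best_matches(
            candidates, config=self.config_, threshold=threshold)
        if not selected:
            return TransferResult(query_id=query_id, best_matches=[],
                                  threshold=None, confidence=None, pfm=None)
        pfms = [e.pfm for e, _ in selected]
        kept = outlier_filter(pfms, factor=self.config_.outlier_factor,
                              config=self.config_, cache=self.cache_)
        merged = merge_pfms(kept, config=self.config_, cache=self.cache_,
                            merged_id=f"{query_id}_pred")
        return TransferResult(query_id=query_id, best_matches=selected,
                              threshold=t, confidence=confidence, pfm=merged,
                              n_outliers_removed=len(pfms) - len(kept))

    def predict(self, dbd_sequence: str, superclass: str,
                query_id: str = "query",
                exclude_id: Optional[str] = None) -> TransferResult:
        candidates = self.candidate_similarities(dbd_sequence, superclass,
                                                 exclude_id=exclude_id)
        return self.transfer_from_similarities(candidates,
                                               query_id=query_id)
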