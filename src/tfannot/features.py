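"""Numeric feature encodings for protein sequences.

Five encodings are provided, each as a plain function plus (where it has
state to learn) a scikit-learn transformer:

* bit-score percentile features — per-class five-number summaries
  (min, lower quartile, median, upper quartile, max) of homology-hit bit
  scores, concatenated over classes (10 dims for TF/non-TF, 25 for the
  five superclasses);
* PSSM profile features — an n x 20 position-specific scoring matrix
  compressed to 20 x 20 by summing rows of identical query residue, scaled
  to a 400-dim vector;
* k-mer occurrence counts (20^k dims);
* pseudo amino-acid composition (20 + lambda dims);
* binary functional-domain composition over a training vocabulary.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .seqio import AMINO_ACIDS, ProteinRecord
from .homology import HitList, ScoringScheme, search

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Robinson–Robinson style background amino-acid frequencies (the BLOSUM62
#: target marginals), indexed like AMINO_ACIDS
BLOSUM62_BACKGROUND = np.array([
    0.074, 0.025, 0.054, 0.054, 0.047, 0.074, 0.026, 0.068, 0.058, 0.099,
    0.025, 0.045, 0.039, 0.034, 0.052, 0.057, 0.051, 0.073, 0.013, 0.032,
])
BLOSUM62_BACKGROUND = BLOSUM62_BACKGROUND / BLOSUM62_BACKGROUND.sum()


# ---------------------------------------------------------------------------
# bit-score percentile features

@dataclass
class PercentileFeatures:
    """Concatenated per-class (p0, p25, p50, p75, p100) bit-score summaries."""

    classes: tuple
    values: np.ndarray
    missing: tuple  # classes with no hits (their block is all zeros)

    def __post_init__(self):
        assert len(self.values) == 5 * len(self.classes)


def bitscore_percentiles(hits: HitList, classes: Sequence[str],
                         key: Optional[str] = None) -> PercentileFeatures:
    """Five-number summary of hit bit scores per class, concatenated.

    ``key`` selects which hit attribute carries the class ("label" or
    "superclass"); by default it is inferred from ``classes``.  A class with
    no hits contributes a zero block and is reported in ``missing``.
    Quantiles use linear interpolation between order statistics.
    """
    if key is None:
        key = "label" if set(classes) <= {"TF", "non-TF"} else "superclass"
    by_class: dict = {c: [] for c in classes}
    for hit in hits:
        c = getattr(hit, key)
        if c in by_class:
            by_class[c].append(hit.bits)
    blocks = []
    missing = []
    for c in classes:
        scores = by_class[c]
        if not scores:
            blocks.append(np.zeros(5))
            missing.append(c)
        else:
            blocks.append(np.percentile(scores, [0, 25, 50, 75, 100]))
    return PercentileFeatures(classes=tuple(classes),
                              values=np.concatenate(blocks),
                              missing=tuple(missing))


class PercentileEncoder(BaseEstimator, TransformerMixin):
    """Transformer mapping sequences to bit-score percentile features.

    ``fit`` stores the labeled database; ``transform`` runs a local-alignment
    search of each input record against it (self-hits excluded by id) and
    summarizes the per-class bit-score distributions.

    Parameters
    ----------
    classes : class order for the concatenated blocks; default TF/non-TF.
    min_bits : bit-score threshold a hit must reach.
    key : hit attribute carrying the class (inferred when None).
    """

    def __init__(self, classes=("TF", "non-TF"), min_bits=15.0, key=None,
                 scheme=None, exclude_self=True):
        self.classes = classes
        self.min_bits = min_bits
        self.key = key
        self.scheme = scheme
        self.exclude_self = exclude_self

    def fit(self, X: Sequence[ProteinRecord], y=None):
        self.db_ = list(X)
        self.scheme_ = self.scheme or ScoringScheme()
        return self

    def transform(self, X: Sequence[ProteinRecord]) -> np.ndarray:
        out = np.empty((len(X), 5 * len(self.classes)))
        for i, rec in enumerate(X):
            hits = search(rec, self.db_, scheme=self.scheme_,
                          min_bits=self.min_bits,
                          exclude_self=self.exclude_self)
            out[i] = bitscore_percentiles(hits, self.classes,
                                          key=self.key).values
        return out


# ---------------------------------------------------------------------------
# PSSM profile features

@dataclass
class PssmProfile:
    matrix: np.ndarray      # n x 20 log-odds scores
    compressed: np.ndarray  # 20 x 20 after query-residue row summation
    vector: np.ndarray      # 400 values after scaling
    from_query_only: bool = False


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def pssm_features(query: ProteinRecord, hits: Optional[HitList],
                  pseudocount: float = 1.0) -> PssmProfile:
    """PSSM profile features from a query and its aligned homology hits.

    Builds an n x 20 log-odds PSSM from the residues the hits align to each
    query position (plus the query itself and ``pseudocount`` smoothing over
    the background), compresses it to 20 x 20 by summing rows of identical
    query residue, divides by the sequence length, applies the sigmoid
    g(x) = 1/(1+e^-x) entrywise and flattens row-major to 400 values.

    With no hits the PSSM degenerates to the query's own composition prior
    and the result is flagged ``from_query_only``.
    """
    seq = query.canonical_sequence()
    n = len(seq)
    counts = np.zeros((n, 20))
    for i, aa in enumerate(seq):
        j = _AA_INDEX.get(aa)
        if j is not None:
            counts[i, j] += 1.0
    n_aligned = 0
    if hits is not None:
        for hit in hits:
            if not hit.aligned_pairs:
                continue
            for pos, residue in hit.aligned_pairs:
                j = _AA_INDEX.get(residue)
                if j is not None and 0 <= pos < n:
                    counts[pos, j] += 1.0
                    n_aligned += 1
    probs = counts + pseudocount * BLOSUM62_BACKGROUND
    probs /= probs.sum(axis=1, keepdims=True)
    matrix = np.log2(probs / BLOSUM62_BACKGROUND)
    compressed = np.zeros((20, 20))
    for i, aa in enumerate(seq):
        j = _AA_INDEX.get(aa)
        if j is not None:
            compressed[j] += matrix[i]
    vector = _sigmoid(compressed / n).ravel()
    return PssmProfile(matrix=matrix, compressed=compressed, vector=vector,
                       from_query_only=(n_aligned == 0))


class PssmEncoder(BaseEstimator, TransformerMixin):
    """Transformer mapping sequences to 400-dim PSSM profile features.

    The database search is run with residue-level alignments retained
    (single pass; no iterative profile refinement).
    """

    def __init__(self, min_bits=15.0, scheme=None, exclude_self=True):
        self.min_bits = min_bits
        self.scheme = scheme
        self.exclude_self = exclude_self

    def fit(self, X: Sequence[ProteinRecord], y=None):
        self.db_ = list(X)
        self.scheme_ = self.scheme or ScoringScheme()
        return self

    def transform(self, X: Sequence[ProteinRecord]) -> np.ndarray:
        out = np.empty((len(X), 400))
        for i, rec in enumerate(X):
            hits = search(rec, self.db_, scheme=self.scheme_,
                          min_bits=self.min_bits,
                          exclude_self=self.exclude_self,
                          keep_alignments=True)
            out[i] = pssm_features(rec, hits).vector
        return out


# ---------------------------------------------------------------------------
# k-mer features

@dataclass
class KmerFeatures:
    k: int
    counts: np.ndarray  # 20^k, lexicographic over AMINO_ACIDS


def kmer_index(kmer: str) -> int:
    """Lexicographic index of a k-mer over the amino-acid alphabet."""
    idx = 0
    for c in kmer:
        idx = idx * 20 + _AA_INDEX[c]
    return idx


def kmer_features(seq: str, k: int = 2) -> KmerFeatures:
    """Occurrence counts of all overlapping k-mers (20^k dims).

    Windows containing a non-canonical residue are skipped.  ``k`` longer
    than the sequence yields an all-zero vector (warning logged).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = np.zeros(20 ** k)
    if k > len(seq):
        logger.warning("kmer_features: k=%d exceeds sequence length %d",
                       k, len(seq))
        return KmerFeatures(k=k, counts=counts)
    for i in range(len(seq) - k + 1):
        window = seq[i:i + k]
        if all(c in _AA_INDEX for c in window):
            counts[kmer_index(window)] += 1
    return KmerFeatures(k=k, counts=counts)


class KmerEncoder(BaseEstimator, TransformerMixin):
    """Transformer mapping sequences to k-mer count vectors (default k=2)."""

    def __init__(self, k=2):
        self.k = k

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        seqs = [x.canonical_sequence() if isinstance(x, ProteinRecord) else x
                for x in X]
        return np.vstack([kmer_features(s, self.k).counts for s in seqs])


# ---------------------------------------------------------------------------
# pseudo amino-acid features

# Chou's original property triple: hydrophobicity, hydrophilicity and
# side-chain mass, indexed like AMINO_ACIDS.
_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}
_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
    "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
    "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
    "W": -3.4, "Y": -2.3,
}
_SIDECHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0,
}


def _standardized_properties() -> np.ndarray:
    """3 x 20 property table, each scale standardized over the 20 residues."""
    rows = []
    for table in (_HYDROPHOBICITY, _HYDROPHILICITY, _SIDECHAIN_MASS):
        v = np.array([table[aa] for aa in AMINO_ACIDS])
        rows.append((v - v.mean()) / v.std())
    return np.vstack(rows)


_PROPERTIES = _standardized_properties()


def residue_correlation(a: str, b: str) -> float:
    """Theta(Ri, Rj): mean squared difference of the standardized properties."""
    ia, ib = _AA_INDEX[a], _AA_INDEX[b]
    diff = _PROPERTIES[:, ib] - _PROPERTIES[:, ia]
    return float(np.mean(diff ** 2))


@dataclass
class PseudoAAFeatures:
    composition: np.ndarray  # first 20 entries
    tiers: np.ndarray        # lambda sequence-order factors
    vector: np.ndarray       # length 20 + lambda, Chou-normalized


def pseudo_aa_features(seq: str, n_tiers: int = 4,
                       weight: float = 0.05) -> PseudoAAFeatures:
    """Chou-style pseudo amino-acid composition.

    The i-th tier factor theta_i is the mean physicochemical correlation
    Theta over residue pairs i positions apart.  The final vector is

        x_u = f_u / (sum f + w * sum theta)          for u = 1..20
        x_{20+i} = w * theta_i / (sum f + w * sum theta)

    with f the relative residue frequencies.  ``n_tiers`` = 0 reduces to the
    plain composition.  Non-canonical residues are excluded from both blocks.
    """
    canonical = [c for c in seq if c in _AA_INDEX]
    if n_tiers >= len(seq):
        raise ValueError("n_tiers must be smaller than the sequence length")
    freqs = np.zeros(20)
    for c in canonical:
        freqs[_AA_INDEX[c]] += 1
    if freqs.sum() > 0:
        freqs /= freqs.sum()
    thetas = np.zeros(n_tiers)
    for i in range(1, n_tiers + 1):
        pairs = [(canonical[j], canonical[j + i])
                 for j in range(len(canonical) - i)]
        if pairs:
            thetas[i - 1] = float(np.mean([residue_correlation(a, b)
                                           for a, b in pairs]))
    denom = freqs.sum() + weight * thetas.sum()
    if denom == 0:
        denom = 1.0
    vector = np.concatenate([freqs, weight * thetas]) / denom
    return PseudoAAFeatures(composition=freqs, tiers=thetas, vector=vector)


class PseudoAAEncoder(BaseEstimator, TransformerMixin):
    """Transformer mapping sequences to pseudo amino-acid features."""

    def __init__(self, n_tiers=4, weight=0.05):
        self.n_tiers = n_tiers
        self.weight = weight

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        seqs = [x.canonical_sequence() if isinstance(x, ProteinRecord) else x
                for x in X]
        return np.vstack([pseudo_aa_features(s, self.n_tiers,
                                             self.weight).vector
                          for s in seqs])


# ---------------------------------------------------------------------------
# functional domain composition features

@dataclass
class DomainFeatures:
    vocabulary: tuple
    bits: np.ndarray


def domain_features(domains: Iterable[str],
                    vocabulary: Sequence[str]) -> DomainFeatures:
    """Binary presence vector of annotated domains over a fixed vocabulary.

    Domains outside the vocabulary are ignored (count logged).
    """
    index = {d: i for i, d in enumerate(vocabulary)}
    bits = np.zeros(len(vocabulary))
    unknown = 0
    for d in set(domains):
        i = index.get(d)
        if i is None:
            unknown += 1
        else:
            bits[i] = 1.0
    if unknown:
        logger.info("domain_features: %d out-of-vocabulary domains ignored",
                    unknown)
    return DomainFeatures(vocabulary=tuple(vocabulary), bits=bits)


class DomainEncoder(BaseEstimator, TransformerMixin):
    """Transformer over per-protein domain-id lists.

    ``fit`` collects the vocabulary: every domain identifier seen at least
    once in the training lists, in sorted order.
    """

    def fit(self, X: Sequence[Iterable[str]], y=None):
        vocab = set()
        for domains in X:
            vocab.update(domains)
        self.vocabulary_ = tuple(sorted(vocab))
        return self

    def transform(self, X: Sequence[Iterable[str]]) -> np.ndarray:
        return np.vstack([domain_features(d, self.vocabulary_).bits
                          for d in X])

    def save_vocabulary(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.vocabulary_) + "\n")

    def load_vocabulary(self, path) -> "DomainEncoder":
        with open(path) as fh:
            self.vocabulary_ = tuple(line.strip() for line in fh
                                     if line.strip())
        return self


def save_features_tsv(X: np.ndarray, names: Sequence[str], path,
                      row_ids: Optional[Sequence[str]] = None) -> None:
    """Write a feature matrix as TSV with a header row of feature names."""
    X = np.asarray(X)
    if X.shape[1] != len(names):
        raise ValueError("one name per feature column required")
    with open(path, "w") as fh:
        prefix = ["id"] if row_ids is not None else []
        fh.write("\t".join(list(prefix) + list(names)) + "\n")
        for i, row in enumerate(X):
            lead = [str(row_ids[i])] if row_ids is not None else []
            fh.write("\t".join(lead + [f"{v:.6g}" for v in row]) + "\n")
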