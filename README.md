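# tfannot

Sequence-based annotation of transcription factors (TFs): given amino-acid
sequences, `tfannot` (1) discriminates TFs from other proteins, (2) assigns
TFs to one of the five structural superclasses of DNA-binding domains
(Basic domain, Zinc finger, Helix-turn-helix, Beta scaffold, Other),
(3) locates the DNA-binding domains (DBDs) by GO-subtree filtering of
domain-scan output, and (4) infers the factor's DNA-binding motif by
transferring position frequency matrices (PFMs) from training factors with
similar DBDs.

It is aimed at regulatory-genomics researchers who need motif annotations
for factors that lack experimentally determined binding data, and at
method developers who want the individual stages (homology features,
multiclass codes, motif similarity) as tested library components.

## The methods in brief

**Bit-score percentile features.** A query is aligned (Smith–Waterman,
BLOSUM62, affine gaps 11/1) against a labeled database; raw scores S become
bit scores (λS − ln K)/ln 2 (λ = 0.267, K = 0.041). Per class c the hit
bit-score distribution is summarized by its five-number summary
(p0, p25, p50, p75, p100); concatenation over classes gives a
10-dimensional vector for TF/non-TF and a 25-dimensional vector for the
five superclasses. Comparison encodings (PSSM profile 400-dim, k-mer
20^k, pseudo amino-acid 20+λ, binary domain composition) are implemented
behind the same transformer interface.

**Multiclass strategies.** One-versus-rest classifiers, or the exhaustive
error-correcting output code: for k classes, 2^(k−1) − 1 binary
classifiers whose columns enumerate all non-degenerate bipartitions
(15 classifiers for the five superclasses, minimum codeword distance 8).
Predictions are decoded by minimum Hamming distance; ties share
probability equally.

**Smax motif similarity.** A hit of PFM X is a window whose log2-odds
score against the background clears a significance threshold
(per-window α ≤ 0.01). With γ_{X,Y}(k) the exact probability that hits of
X and Y co-occur at offset k on random DNA,

    s(k)   = log2( γ_{X,Y}(k) / (α_X α_Y) )
    Smax   = max over offsets, orders and orientations of s(k)
    s_norm = Smax(X,Y) / sqrt( Smax(X,X) · Smax(Y,Y) )
    d      = min(1, max(0, 1 − s_norm))   ∈ [0, 1]

**Motif transfer.** Per superclass, an ε-SVR predicts s_norm of a TF pair
from four DBD similarity features (global identity, normalized local
score, mismatch kernel (3,1), local alignment kernel). Training factors
scoring above the best-match threshold — fixed, or chosen dynamically as
the largest value in [0.5, 0.95] retaining a match — contribute their
PFMs, which pass a relative-average-distance outlier filter and are merged
progressively along a UPGMA guide tree into the predicted motif. If no
candidate reaches 0.5 the result is an explicit NO-PREDICTION.

A synthetic-data module generates labeled proteomes, domain/GO tables and
PFM families with controlled statistical structure, so the entire pipeline
runs and is tested without any downloads. See `docs/methods.md` for
models, parameters and limitations.

## Worked example

Generate a synthetic workspace and run the four-step pipeline on two
queries (one TF, one non-TF):

```bash
tfannot synth --out-dir data --n-tf 6 --n-nontf 30 --seed 11
tfannot pipeline --db data/proteome.fasta --query queries.fasta \
    --domains data/domains.tsv --go data/go_subtree.obo \
    --pfms data/pfms.jaspar --seed 11
```

```json
[
  {
    "query": "TF_1_1_1",
    "tf_probability": 0.7537,
    "call": "TF",
    "superclass": "Basic domain",
    "dbd": {"start": 30, "end": 59},
    "motif": {
      "status": "OK",
      "threshold": 0.6003,
      "confidence": 0.6003,
      "best_matches": [{"id": "TF_1_1_2", "similarity": 0.6003}],
      "n_outliers_removed": 0,
      "pfm": [[0.4486, 0.1189, 0.1638, 0.2687],
              [0.2102, 0.0772, 0.2154, 0.4973], "..."]
    }
  },
  {
    "query": "NT_30",
    "tf_probability": 0.2541,
    "call": "non-TF"
  }
]
```

Reading the output: `TF_1_1_1` is called a TF (probability 0.75 from the
percentile-feature classifier), assigned the Basic domain superclass, its
DBD spans residues 30–59, and its motif is predicted by transferring the
PFM of its family member `TF_1_1_2`, whose predicted PFM similarity 0.6003
set the dynamic threshold and the confidence. The non-TF query is
dismissed after step 1 and skips the remaining steps. Each `pfm` row gives
the (A, C, G, T) probabilities of one motif position.

The same stages are available as a library — `PercentileEncoder`,
`ECOCClassifier`, `OvRClassifier` and `PfmTransferModel` follow
scikit-learn's fit/transform/predict conventions, with module functions
(`smax_similarity`, `merge_pfms`, `nested_cv`, …) underneath.

### FASTA header dialect

Class labels travel in pipe-delimited headers,
`>accession|label|superclass|source`, e.g.
`>P12345|TF|Basic domain|TRANSFAC`; trailing fields may be omitted, and
headers not following the dialect are kept whole as the record id with no
label.

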