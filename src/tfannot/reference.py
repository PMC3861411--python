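"""Composition of the published reference validation set.

The classifiers in this package were designed around a curated validation
set of 1,485 transcription factors (after homology reduction) spanning the
five structural superclasses, plus roughly ten times as many non-TFs.
The per-superclass stratum sizes of that set are recorded here; they are
used for documentation and consistency checks, not as training data.
"""

#: TF counts per structural superclass in the reference validation set
VALIDATION_SUPERCLASS_COUNTS = {
    "Basic domain": 271,
    "Zinc finger": 228,
    "Helix-turn-helix": 787,
    "Beta scaffold": 101,
    "Other": 98,
}

#: total number of TFs in the reference validation set
VALIDATION_TF_TOTAL = 1485


def superclass_total() -> int:
    """Sum of the per-superclass stratum counts."""
    return sum(VALIDATION_SUPERCLASS_COUNTS.values())
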