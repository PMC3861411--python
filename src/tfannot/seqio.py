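"""FASTA input/output with the labeled-header dialect used throughout the package.

Headers carry up to four pipe-delimited fields::

    >accession|label|superclass|source

where ``label`` is ``TF`` or ``non-TF``, ``superclass`` is one of the five
structural superclasses of transcription-factor DNA-binding domains, and
``source`` is a free-form provenance tag.  Absent trailing fields are simply
omitted.  Headers that do not follow the dialect are kept verbatim as the
record id with no label, so a malformed header can never silently mislabel
a sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio.SeqIO.FastaIO import SimpleFastaParser

#: the 20 canonical amino-acid one-letter codes
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
#: ambiguity / non-canonical codes optionally mapped to X
AMBIGUOUS = frozenset("XBZUO*")

LABELS = ("TF", "non-TF")

#: TRANSFAC structural superclasses of TF DNA-binding domains
SUPERCLASSES = (
    "Basic domain",
    "Zinc finger",
    "Helix-turn-helix",
    "Beta scaffold",
    "Other",
)


class FastaError(ValueError):
    """Raised for malformed FASTA input or invalid records."""


@dataclass
class ProteinRecord:
    """An amino-acid sequence with optional TF class annotations."""

    id: str
    sequence: str
    label: Optional[str] = None
    superclass: Optional[str] = None
    source: Optional[str] = None

    def validate(self, allow_ambiguous: bool = False) -> "ProteinRecord":
        """Check the record invariants, returning ``self``.

        Raises :class:`FastaError` on an empty sequence, residues outside the
        canonical 20-letter alphabet (unless ``allow_ambiguous``), an unknown
        label or superclass, or a superclass given for a non-TF record.
        """
        if not self.sequence:
            raise FastaError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            if allow_ambiguous and bad <= AMBIGUOUS:
                pass
            else:
                raise FastaError(
                    f"record {self.id!r}: non-canonical residues {sorted(bad)}"
                )
        if self.label is not None and self.label not in LABELS:
            raise FastaError(f"record {self.id!r}: unknown label {self.label!r}")
        if self.superclass is not None:
            if self.superclass not in SUPERCLASSES:
                raise FastaError(
                    f"record {self.id!r}: unknown superclass {self.superclass!r}"
                )
            if self.label != "TF":
                raise FastaError(
                    f"record {self.id!r}: superclass set but label is not TF"
                )
        return self

    def canonical_sequence(self) -> str:
        """Sequence with any ambiguity codes mapped to ``X``."""
        return "".join(c if c in _AA_SET else "X" for c in self.sequence)

    def header(self) -> str:
        fields = [self.id]
        if self.label is not None:
            fields.append(self.label)
            # superclass and source are distinguished on parse by the closed
            # superclass vocabulary, so a missing superclass is simply omitted
            if self.superclass is not None:
                fields.append(self.superclass)
            if self.source is not None:
                fields.append(self.source)
        return "|".join(fields)


def _parse_header(header: str) -> ProteinRecord:
    parts = header.split("|")
    if len(parts) == 1:
        return ProteinRecord(id=header, sequence="")
    ident, rest = parts[0], parts[1:]
    if rest[0] not in LABELS:
        # not our dialect: keep everything as the id
        return ProteinRecord(id=header, sequence="")
    label = rest[0]
    superclass = None
    source = None
    rest = rest[1:]
    if rest and rest[0] in SUPERCLASSES:
        superclass = rest[0]
        rest = rest[1:]
    if rest:
        source = "|".join(rest)
    return ProteinRecord(id=ident, sequence="", label=label,
                         superclass=superclass, source=source)


def read_fasta(path, allow_ambiguous: bool = False) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, order preserved.

    Headers are parsed per the pipe-delimited dialect; unparseable headers
    are retained whole as the record id.  Each record is validated; with
    ``allow_ambiguous`` the codes X/B/Z/U/O/* are accepted (and mapped to X
    by downstream composition features).
    """
    records: list[ProteinRecord] = []
    with open(path) as fh:
        for i, (header, seq) in enumerate(SimpleFastaParser(fh)):
            header = header.strip()
            if not header:
                raise FastaError(f"entry {i + 1}: empty header")
            rec = _parse_header(header)
            rec.sequence = seq.replace(" ", "").upper()
            if not rec.sequence:
                raise FastaError(f"entry {i + 1} ({header!r}): empty sequence")
            rec.validate(allow_ambiguous=allow_ambiguous)
            records.append(rec)
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    """Write records as canonical FASTA (60-column wrapped, dialect headers)."""
    with open(path, "w") as fh:
        for rec in records:
            rec.validate(allow_ambiguous=True)
            fh.write(f">{rec.header()}\n")
            seq = rec.sequence
            for start in range(0, len(seq), width):
                fh.write(seq[start:start + width] + "\n")
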