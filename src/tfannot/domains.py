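"""Domain-scan parsing and GO-based identification of DNA-binding domains.

Domain annotations arrive as InterProScan-style TSV rows carrying a GO
column; DNA-binding domains are those whose GO terms fall inside the
subtree rooted at the molecular function "DNA binding" (GO:0003677 by
default), i.e. the root term or any transitive descendant.  A separate
post-filter removes putative non-TF records that are either present in a
TF database or annotated with the TF-specific molecular function
"sequence-specific DNA binding transcription factor activity" (GO:0003700).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: molecular function "DNA binding" — root of the domain filter subtree
GO_DNA_BINDING = "GO:0003677"
#: "sequence-specific DNA binding transcription factor activity" — used only
#: by the non-TF label post-filter
GO_TF_ACTIVITY = "GO:0003700"


@dataclass
class DomainAnnotation:
    """One domain call on a protein (1-based inclusive coordinates)."""

    protein_id: str
    domain_id: str
    start: int
    end: int
    go_terms: frozenset = frozenset()

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.protein_id}/{self.domain_id}: invalid interval "
                f"[{self.start}, {self.end}]")
        self.go_terms = frozenset(self.go_terms)


def parse_domain_tsv(path) -> list[DomainAnnotation]:
    """Parse an InterProScan-style TSV.

    Expected columns: protein id, domain id, start, end, GO terms
    (pipe-separated; may be empty).  Rows without usable coordinates are a
    parse error naming the line.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ValueError(f"{path}: line {lineno}: expected at least "
                                 f"4 columns, got {len(cols)}")
            try:
                start, end = int(cols[2]), int(cols[3])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: bad coordinates "
                                 f"{cols[2]!r}..{cols[3]!r}") from exc
            go = frozenset(t for t in (cols[4].split("|") if len(cols) > 4
                                       else []) if t)
            try:
                out.append(DomainAnnotation(cols[0], cols[1], start, end, go))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_domain_tsv(annotations: Iterable[DomainAnnotation], path) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            go = "|".join(sorted(a.go_terms))
            fh.write(f"{a.protein_id}\t{a.domain_id}\t{a.start}\t{a.end}"
                     f"\t{go}\n")


@dataclass
class GoSubtree:
    """A GO term and its transitive descendants."""

    root: str
    members: frozenset

    def __contains__(self, term: str) -> bool:
        return term in self.members


def go_descendants(ontology, root: str = GO_DNA_BINDING,
                   include_part_of: bool = False) -> GoSubtree:
    """Subtree of ``root``: the root plus all transitive descendants.

    ``ontology`` is an OBO file path/handle or a pre-built networkx graph as
    returned by :func:`obonet.read_obo` (edges point child -> parent, keyed
    by relation).  Only ``is_a`` edges are followed unless
    ``include_part_of``.
    """
    graph = ontology if isinstance(ontology, nx.MultiDiGraph) \
        else obonet.read_obo(ontology)
    if root not in graph:
        raise KeyError(f"root term {root} not in ontology")
    relations = {"is_a"} | ({"part_of"} if include_part_of else set())
    sub = nx.MultiDiGraph(
        (u, v, k) for u, v, k in graph.edges(keys=True) if k in relations)
    sub.add_nodes_from(graph.nodes)
    # edges run child -> parent, so descendants are the graph ancestors
    members = frozenset(nx.ancestors(sub, root)) | {root}
    return GoSubtree(root=root, members=members)


def filter_dna_binding(annotations: Sequence[DomainAnnotation],
                       subtree: GoSubtree) -> list[DomainAnnotation]:
    """Keep annotations whose GO set intersects the DNA-binding subtree."""
    return [a for a in annotations if a.go_terms & subtree.members]


def dbd_intervals(annotations: Sequence[DomainAnnotation],
                  merge_overlaps: bool = True) -> dict:
    """Per-protein DNA-binding-domain intervals for motif inference.

    Overlapping or adjacent annotations on a protein are merged into
    maximal intervals (so duplicated overlapping segments cannot
    double-weight residues).  Returns protein id -> list of (start, end),
    1-based inclusive.
    """
    by_protein: dict = {}
    for a in annotations:
        by_protein.setdefault(a.protein_id, []).append((a.start, a.end))
    out = {}
    for pid, ivs in by_protein.items():
        ivs.sort()
        if not merge_overlaps:
            out[pid] = ivs
            continue
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[pid] = [tuple(iv) for iv in merged]
    return out


def label_postfilter(records, go_annotations: dict, tf_ids: set,
                     tf_go_term: str = GO_TF_ACTIVITY):
    """Remove mislabeled candidate non-TFs.

    Drops records whose id appears in ``tf_ids`` (entries in TF databases)
    and records annotated with the TF-specific GO term.  Returns the
    surviving records and the number removed.
    """
    kept = []
    removed = 0
    for rec in records:
        if rec.id in tf_ids:
            removed += 1
            continue
        if tf_go_term in go_annotations.get(rec.id, ()):
            removed += 1
            continue
        kept.append(rec)
    return kept, removed
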