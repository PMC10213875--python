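"""Hierarchical biotype annotation of distinct small-RNA sequences.

A distinct clean sequence is searched against the biotype databases in
cascade order (miRNA, rRNA, tRNA, piRNA, other ncRNA) at zero mismatches;
the first database with a hit terminates the cascade.  rRNA hits become
rsRNA calls with the parent assigned to the smallest Svedberg class among
the hit records (so a read inside 18S, which is embedded in 45S, is an
18S-derived rsRNA).  tRNA hits become tsRNA calls subtyped by their origin
on the mature tRNA: 5' fragment, 3' fragment ending just before the CCA
tail, 3' fragment including the CCA end, or internal fragment.

A rescue pass then takes the piRNA and unannotated sequences that are not
found in the genome (either strand, exact) and re-matches them with one
mismatch allowed against rRNA then tRNA; hits are re-annotated as rsRNA or
tsRNA with ``rescued=True``.  The single mismatch tolerates RNA base
modifications that are read through as apparent substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .refdb import SVEDBERG_ORDER, AnnotationIndex, Hit, ReferenceValidationError

TSRNA_5P = "tsRNA_5p"
TSRNA_3P = "tsRNA_3p"
TSRNA_3P_CCA = "tsRNA_3p_CCA"
TSRNA_INTERNAL = "tsRNA_internal"

#: Subtype precedence when a fragment (or several parents) satisfies more
#: than one boundary rule.
TSRNA_PRECEDENCE = (TSRNA_5P, TSRNA_3P_CCA, TSRNA_3P, TSRNA_INTERNAL)

NO_ANNOTATION = "no_annotation"


@dataclass
class Annotation:
    """Biotype call for one distinct sequence."""

    sequence: str
    biotype: str
    parent_ids: list[str] = field(default_factory=list)
    primary_parent: Optional[str] = None
    subtype: Optional[str] = None
    parent_class: Optional[str] = None
    mismatches_used: int = 0
    rescued: bool = False
    match_offset: Optional[int] = None
    genome_checked: bool = True

    def __post_init__(self) -> None:
        if self.rescued and self.mismatches_used != 1:
            raise ValueError("rescued calls use exactly one mismatch")
        if self.rescued and self.biotype not in ("rsRNA", "tsRNA"):
            raise ValueError("rescue can only produce rsRNA or tsRNA")
        if (self.subtype is not None) != (self.biotype == "tsRNA"):
            raise ValueError("subtype present iff biotype is tsRNA")
        if (self.parent_class is not None) != (self.biotype == "rsRNA"):
            raise ValueError("parent_class present iff biotype is rsRNA")
        if self.biotype == NO_ANNOTATION and self.parent_ids:
            raise ValueError("no_annotation implies empty parent_ids")


def match_sequence(
    seq: str, index: AnnotationIndex, biotype: str, max_mismatch: int = 0
) -> list[Hit]:
    """End-to-end Hamming matches of ``seq`` in one biotype database."""
    return index.match(seq, biotype, max_mismatch=max_mismatch)


def classify_tsrna_position(offset: int, length: int, parent_length: int) -> str:
    """Subtype a tRNA fragment from its 1-based start and its parent length.

    The parent must be a mature (CCA-ended) tRNA.  A fragment starting at
    base 1 is a 5' tsRNA; one ending on the final base carries the CCA end;
    one ending exactly three bases before the final base abuts (but excludes)
    the CCA; anything else is internal.  Precedence: 5' > 3'-CCA > 3'.
    """
    end = offset + length - 1
    if offset == 1:
        return TSRNA_5P
    if end == parent_length:
        return TSRNA_3P_CCA
    if end == parent_length - 3:
        return TSRNA_3P
    return TSRNA_INTERNAL


def classify_tsrna(hit: Hit, seq: str, index: AnnotationIndex) -> str:
    """Subtype one tRNA hit; errors on an unprocessed parent record."""
    rec = index.by_id[hit.ref_id]
    if rec.biotype != "tRNA" or not rec.processed:
        raise ReferenceValidationError(
            f"{hit.ref_id}: tsRNA classification requires a processed tRNA parent"
        )
    return classify_tsrna_position(hit.offset, len(seq), len(rec.sequence))


def assign_rsrna_parent(hits: Sequence[Hit], index: AnnotationIndex) -> tuple[str, str]:
    """Pick the Svedberg parent class for a set of rRNA hits.

    Hits are restricted to the fewest mismatches; among those, the smallest
    Svedberg class wins (small-to-large precedence), then the
    lexicographically smallest ref_id within that class.
    Returns ``(parent_class, primary_parent)``.
    """
    if not hits:
        raise ValueError("assign_rsrna_parent requires at least one rRNA hit")
    best_mm = min(h.mismatches for h in hits)
    candidates = [h for h in hits if h.mismatches == best_mm]
    ranked = []
    for h in candidates:
        rec = index.by_id[h.ref_id]
        if rec.svedberg_class is None:
            raise ReferenceValidationError(f"{h.ref_id}: rRNA record lacks a Svedberg class")
        ranked.append((SVEDBERG_ORDER.index(rec.svedberg_class), h.ref_id, h))
    ranked.sort(key=lambda t: (t[0], t[1]))
    best = ranked[0]
    return SVEDBERG_ORDER[best[0]], best[1]


def _subtype_across_parents(hits: Sequence[Hit], seq: str, index: AnnotationIndex) -> str:
    subtypes = {classify_tsrna(h, seq, index) for h in hits}
    for s in TSRNA_PRECEDENCE:
        if s in subtypes:
            return s
    raise AssertionError("unreachable")


def _best_hits(hits: Sequence[Hit]) -> list[Hit]:
    best = min(h.mismatches for h in hits)
    return [h for h in hits if h.mismatches == best]


def _annotation_from_hits(
    seq: str,
    biotype: str,
    hits: Sequence[Hit],
    index: AnnotationIndex,
    rescued: bool = False,
    genome_checked: bool = True,
) -> Annotation:
    best = _best_hits(hits)
    mm = best[0].mismatches
    parent_ids = sorted({h.ref_id for h in hits})
    if biotype == "rRNA":
        parent_class, primary = assign_rsrna_parent(best, index)
        offset = min(h.offset for h in best if h.ref_id == primary)
        return Annotation(
            sequence=seq,
            biotype="rsRNA",
            parent_ids=parent_ids,
            primary_parent=primary,
            parent_class=parent_class,
            mismatches_used=mm,
            rescued=rescued,
            match_offset=offset,
            genome_checked=genome_checked,
        )
    if biotype == "tRNA":
        subtype = _subtype_across_parents(best, seq, index)
        primary = min(h.ref_id for h in best)
        offset = min(h.offset for h in best if h.ref_id == primary)
        return Annotation(
            sequence=seq,
            biotype="tsRNA",
            parent_ids=parent_ids,
            primary_parent=primary,
            subtype=subtype,
            mismatches_used=mm,
            rescued=rescued,
            match_offset=offset,
            genome_checked=genome_checked,
        )
    primary = min(h.ref_id for h in best)
    offset = min(h.offset for h in best if h.ref_id == primary)
    return Annotation(
        sequence=seq,
        biotype=biotype,
        parent_ids=parent_ids,
        primary_parent=primary,
        mismatches_used=mm,
        rescued=rescued,
        match_offset=offset,
        genome_checked=genome_checked,
    )


def annotate_sequence(seq: str, index: AnnotationIndex) -> Annotation:
    """First-pass cascade annotation at zero mismatches.

    Databases are queried in cascade order; the first with a hit terminates
    the search, so an exact miRNA match shadows any rRNA occurrence.
    """
    for biotype in index.biotype_order:
        hits = index.match(seq, biotype, max_mismatch=0)
        if hits:
            return _annotation_from_hits(seq, biotype, hits, index)
    return Annotation(sequence=seq, biotype=NO_ANNOTATION)


def rescue_reannotate(
    annotations: Sequence[Annotation], index: AnnotationIndex
) -> list[Annotation]:
    """One-mismatch rescue of off-genome piRNA / unannotated sequences.

    Candidates are first-pass piRNA or no_annotation calls whose sequence is
    absent from the genome (exact, either strand).  Without a genome index
    every such call is a candidate and the output is flagged
    ``genome_checked=False``.  Candidates are re-matched at <= 1 mismatch
    against rRNA first, then tRNA (mirroring the cascade order); other calls
    pass through unchanged.
    """
    out: list[Annotation] = []
    for ann in annotations:
        if ann.biotype not in ("piRNA", NO_ANNOTATION):
            out.append(ann)
            continue
        if index.has_genome:
            if index.genome_contains(ann.sequence):
                out.append(ann)
                continue
            genome_checked = True
        else:
            genome_checked = False
        rescued = None
        for biotype in ("rRNA", "tRNA"):
            hits = index.match(ann.sequence, biotype, max_mismatch=1)
            if hits:
                rescued = _annotation_from_hits(
                    ann.sequence,
                    biotype,
                    hits,
                    index,
                    rescued=True,
                    genome_checked=genome_checked,
                )
                break
        if rescued is not None:
            out.append(rescued)
        else:
            out.append(
                Annotation(
                    sequence=ann.sequence,
                    biotype=ann.biotype,
                    parent_ids=list(ann.parent_ids),
                    primary_parent=ann.primary_parent,
                    mismatches_used=ann.mismatches_used,
                    match_offset=ann.match_offset,
                    genome_checked=genome_checked,
                )
            )
    return out


def annotate_sequences(seqs: Sequence[str], index: AnnotationIndex) -> list[Annotation]:
    """Cascade plus rescue for a collection of distinct sequences."""
    first_pass = [annotate_sequence(s, index) for s in seqs]
    return rescue_reannotate(first_pass, index)


def annotations_to_frame(annotations: Sequence[Annotation]) -> pd.DataFrame:
    """Flatten annotations into the tabular (TSV-ready) report."""
    rows = []
    for a in annotations:
        rows.append(
            {
                "sequence": a.sequence,
                "biotype": a.biotype,
                "subtype": a.subtype or "",
                "primary_parent": a.primary_parent or "",
                "parent_class": a.parent_class or "",
                "parents": ",".join(a.parent_ids),
                "mismatches": a.mismatches_used,
                "rescued": a.rescued,
                "offset": a.match_offset if a.match_offset is not None else -1,
                "genome_checked": a.genome_checked,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sequence",
            "biotype",
            "subtype",
            "primary_parent",
            "parent_class",
            "parents",
            "mismatches",
            "rescued",
            "offset",
            "genome_checked",
        ],
    )
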