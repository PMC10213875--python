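"""Reference databases for small-RNA biotype annotation.

The annotation cascade searches a set of per-biotype reference databases
(mature miRNA, rRNA with Svedberg-class labels, mature tRNA, piRNA and other
non-coding RNA) plus an optional genome used only for presence checks.  tRNA
references are preprocessed the way mature tRNAs are produced in the cell:
predicted introns are spliced out, the 3' CCA tail is appended, and histidine
tRNAs get the extra 5' guanosine.  All sequences are normalised to the DNA
alphabet (U -> T) at load time so a single alphabet is used for matching.
"""

from __future__ import annotations

import re
from collections import namedtuple
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Fixed small-to-large ordering of rRNA species by sedimentation coefficient.
SVEDBERG_ORDER = ("4.5S", "5S", "5.8S", "12S", "16S", "18S", "28S", "45S")

#: Default cascade order of the biotype databases.
BIOTYPE_ORDER = ("miRNA", "rRNA", "tRNA", "piRNA", "other_ncRNA")

BIOTYPES = set(BIOTYPE_ORDER) | {"genome"}

_VALID_SEQ = re.compile(r"^[ACGTN]+$")

#: A single end-to-end match of a query inside a reference.  ``offset`` is the
#: 1-based start of the match on the reference sequence.
Hit = namedtuple("Hit", ["ref_id", "offset", "mismatches"])


class ReferenceValidationError(ValueError):
    """Raised when a reference record violates its contract."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and map RNA U to DNA T."""
    return seq.upper().replace("U", "T")


@dataclass
class ReferenceRecord:
    """One reference sequence with its biotype and preprocessing metadata.

    Parameters
    ----------
    ref_id : str
        Unique identifier within its biotype database.
    biotype : str
        One of ``miRNA, rRNA, tRNA, piRNA, other_ncRNA, genome``.
    sequence : str
        DNA-alphabet sequence (U is mapped to T on construction).
    svedberg_class : str, optional
        rRNA species label; required iff ``biotype == "rRNA"``.
    amino_acid : str, optional
        tRNA isoacceptor (e.g. ``"Glu"``, ``"His"``, ``"mt-Val"``); required
        iff ``biotype == "tRNA"``.
    intron_intervals : list of (start, end), optional
        1-based inclusive intron coordinates on the *raw* gene sequence.
    processed : bool
        For tRNA: introns spliced, CCA appended (and His G prepended).
    splice_junctions : list of int
        1-based positions (on the processed sequence) immediately preceding an
        excised intron; retained for provenance after preprocessing.
    """

    ref_id: str
    biotype: str
    sequence: str
    svedberg_class: Optional[str] = None
    amino_acid: Optional[str] = None
    intron_intervals: Optional[list[tuple[int, int]]] = None
    processed: bool = False
    splice_junctions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        if self.biotype not in BIOTYPES:
            raise ReferenceValidationError(
                f"{self.ref_id}: unknown biotype {self.biotype!r}"
            )
        if not _VALID_SEQ.match(self.sequence):
            raise ReferenceValidationError(
                f"{self.ref_id}: sequence contains characters outside ACGTN"
            )
        if len(self.sequence) < 15:
            raise ReferenceValidationError(
                f"{self.ref_id}: reference shorter than 15 nt"
            )
        if (self.svedberg_class is not None) != (self.biotype == "rRNA"):
            raise ReferenceValidationError(
                f"{self.ref_id}: svedberg_class must be present iff biotype is rRNA"
            )
        if self.svedberg_class is not None and self.svedberg_class not in SVEDBERG_ORDER:
            raise ReferenceValidationError(
                f"{self.ref_id}: unknown Svedberg class {self.svedberg_class!r}"
            )
        if (self.amino_acid is not None) != (self.biotype == "tRNA"):
            raise ReferenceValidationError(
                f"{self.ref_id}: amino_acid must be present iff biotype is tRNA"
            )

    @property
    def is_histidine(self) -> bool:
        """True when the isoacceptor is histidine (``His``, any case, with or
        without a ``mt-`` prefix)."""
        if self.amino_acid is None:
            return False
        aa = self.amino_acid.lower()
        return aa.removeprefix("mt-") == "his"


def preprocess_trna(record: ReferenceRecord) -> ReferenceRecord:
    """Produce the mature tRNA reference from a raw tRNA gene.

    Predicted introns are excised, ``CCA`` is appended to the 3' end, and a
    single ``G`` is prepended to the 5' end of histidine tRNAs.  The splice
    junction positions on the processed sequence are retained in metadata.
    """
    if record.biotype != "tRNA":
        raise ReferenceValidationError(f"{record.ref_id}: not a tRNA record")
    if record.processed:
        raise ReferenceValidationError(f"{record.ref_id}: already processed")

    seq = record.sequence
    introns = sorted(record.intron_intervals or [])
    prev_end = 0
    for start, end in introns:
        if start < 1 or end > len(seq) or start > end:
            raise ReferenceValidationError(
                f"{record.ref_id}: intron [{start},{end}] outside sequence 1..{len(seq)}"
            )
        if start <= prev_end:
            raise ReferenceValidationError(
                f"{record.ref_id}: overlapping intron intervals"
            )
        prev_end = end

    pieces: list[str] = []
    junctions: list[int] = []
    cursor = 1
    kept = 0
    for start, end in introns:
        pieces.append(seq[cursor - 1 : start - 1])
        kept += start - cursor
        junctions.append(kept)  # exonic position preceding the excised intron
        cursor = end + 1
    pieces.append(seq[cursor - 1 :])
    spliced = "".join(pieces)

    mature = spliced + "CCA"
    if record.is_histidine:
        mature = "G" + mature
        junctions = [j + 1 for j in junctions]

    return replace(
        record,
        sequence=mature,
        processed=True,
        splice_junctions=junctions,
    )


# Byte encoding used for Hamming scans.  N never matches anything, including
# another N: references encode it as 254 and queries as 255.
_REF_LUT = np.full(256, 254, dtype=np.uint8)
_QRY_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _REF_LUT[_b] = _i
    _QRY_LUT[_b] = _i


def _encode_ref(seq: str) -> np.ndarray:
    return _REF_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _encode_query(seq: str) -> np.ndarray:
    return _QRY_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


class AnnotationIndex:
    """Per-biotype substring index over processed reference records.

    Queries are end-to-end alignments of a short read inside a reference on
    the sense strand, scored by Hamming distance (no indels).  The optional
    genome index answers exact presence queries on both strands.
    """

    def __init__(
        self,
        records: Sequence[ReferenceRecord],
        biotype_order: Sequence[str] = BIOTYPE_ORDER,
        genome: Optional[str] = None,
    ) -> None:
        present = {r.biotype for r in records} - {"genome"}
        if not present <= set(biotype_order):
            raise ReferenceValidationError(
                "biotype_order must cover every biotype present in the records"
            )
        self.biotype_order = tuple(biotype_order)
        self.records: dict[str, list[ReferenceRecord]] = {b: [] for b in self.biotype_order}
        self.by_id: dict[str, ReferenceRecord] = {}
        self._encoded: dict[str, list[np.ndarray]] = {b: [] for b in self.biotype_order}
        seen: dict[str, set[str]] = {b: set() for b in self.biotype_order}
        for rec in records:
            if rec.biotype == "genome":
                continue
            if rec.biotype == "tRNA" and not rec.processed:
                raise ReferenceValidationError(
                    f"{rec.ref_id}: tRNA records must be preprocessed before indexing"
                )
            if rec.ref_id in seen[rec.biotype]:
                raise ReferenceValidationError(
                    f"duplicate ref_id {rec.ref_id!r} within biotype {rec.biotype}"
                )
            seen[rec.biotype].add(rec.ref_id)
            self.records[rec.biotype].append(rec)
            self._encoded[rec.biotype].append(_encode_ref(rec.sequence))
            self.by_id[rec.ref_id] = rec
        for b in self.records:
            order = np.argsort([r.ref_id for r in self.records[b]], kind="stable")
            self.records[b] = [self.records[b][i] for i in order]
            self._encoded[b] = [self._encoded[b][i] for i in order]

        self.genome: Optional[str] = None
        self._genome_rc: Optional[str] = None
        if genome is not None:
            self.genome = normalize_sequence(genome)
            self._genome_rc = reverse_complement(self.genome)

    @property
    def has_genome(self) -> bool:
        return self.genome is not None

    def match(self, seq: str, biotype: str, max_mismatch: int = 0) -> list[Hit]:
        """All end-to-end Hamming matches of ``seq`` in one biotype database.

        Hits are sorted by (mismatches, ref_id, offset); offsets are 1-based.
        """
        q = _encode_query(normalize_sequence(seq))
        L = q.size
        hits: list[Hit] = []
        for rec, enc in zip(self.records[biotype], self._encoded[biotype]):
            if enc.size < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(enc, L)
            mm = (windows != q).sum(axis=1)
            for pos in np.nonzero(mm <= max_mismatch)[0]:
                hits.append(Hit(rec.ref_id, int(pos) + 1, int(mm[pos])))
        hits.sort(key=lambda h: (h.mismatches, h.ref_id, h.offset))
        return hits

    def genome_contains(self, seq: str) -> bool:
        """Exact presence of ``seq`` in the genome on either strand."""
        if self.genome is None:
            raise ReferenceValidationError("no genome index available")
        s = normalize_sequence(seq)
        if "N" in s:
            return False
        return s in self.genome or s in self._genome_rc


def build_index(
    records: Sequence[ReferenceRecord],
    biotype_order: Sequence[str] = BIOTYPE_ORDER,
    genome: Optional[str] = None,
) -> AnnotationIndex:
    """Build the cascade index from processed reference records."""
    return AnnotationIndex(records, biotype_order=biotype_order, genome=genome)


# ---------------------------------------------------------------------------
# FASTA round trip.  Record metadata is carried in the description as
# whitespace-separated key=value pairs so that re-reading reproduces records.
# ---------------------------------------------------------------------------

def _format_intervals(intervals: Optional[list[tuple[int, int]]]) -> Optional[str]:
    if not intervals:
        return None
    return ",".join(f"{s}-{e}" for s, e in intervals)


def _parse_intervals(text: str) -> list[tuple[int, int]]:
    out = []
    for chunk in text.split(","):
        s, e = chunk.split("-")
        out.append((int(s), int(e)))
    return out


def write_fasta(records: Iterable[ReferenceRecord], path: str | Path) -> None:
    """Write reference records (with metadata) to FASTA."""
    out = []
    for rec in records:
        tags = [f"biotype={rec.biotype}", f"processed={str(rec.processed).lower()}"]
        if rec.svedberg_class is not None:
            tags.append(f"svedberg={rec.svedberg_class}")
        if rec.amino_acid is not None:
            tags.append(f"amino_acid={rec.amino_acid}")
        iv = _format_intervals(rec.intron_intervals)
        if iv:
            tags.append(f"introns={iv}")
        if rec.splice_junctions:
            tags.append("junctions=" + ",".join(map(str, rec.splice_junctions)))
        out.append(SeqRecord(Seq(rec.sequence), id=rec.ref_id, description=" ".join(tags)))
    SeqIO.write(out, str(path), "fasta")


def read_fasta(path: str | Path, biotype: Optional[str] = None) -> list[ReferenceRecord]:
    """Read reference records from FASTA written by :func:`write_fasta`.

    Plain FASTA (no key=value tags) is accepted when ``biotype`` is given.
    """
    records = []
    for sr in SeqIO.parse(str(path), "fasta"):
        tags: dict[str, str] = {}
        for token in sr.description.split()[1:]:
            if "=" in token:
                k, v = token.split("=", 1)
                tags[k] = v
        bt = tags.get("biotype", biotype)
        if bt is None:
            raise ReferenceValidationError(
                f"{sr.id}: no biotype tag in FASTA and none supplied"
            )
        records.append(
            ReferenceRecord(
                ref_id=sr.id,
                biotype=bt,
                sequence=str(sr.seq),
                svedberg_class=tags.get("svedberg"),
                amino_acid=tags.get("amino_acid"),
                intron_intervals=_parse_intervals(tags["introns"]) if "introns" in tags else None,
                processed=tags.get("processed", "false") == "true",
                splice_junctions=[int(x) for x in tags["junctions"].split(",")]
                if "junctions" in tags
                else [],
            )
        )
    return records


def load_intron_table(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read a tRNA intron side table (TSV: ref_id, start, end, amino_acid)."""
    table: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            ref_id = parts[idx["ref_id"]]
            table.setdefault(ref_id, []).append(
                (int(parts[idx["start"]]), int(parts[idx["end"]]))
            )
    return table
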