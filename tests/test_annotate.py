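"""Cascade annotation, tsRNA subtyping, Svedberg precedence and rescue."""

import numpy as np
import pytest

from sncpipe.annotate import (
    Annotation,
    annotate_sequence,
    annotate_sequences,
    annotations_to_frame,
    assign_rsrna_parent,
    classify_tsrna_position,
    rescue_reannotate,
)
from sncpipe.refdb import (
    SVEDBERG_ORDER,
    BIOTYPE_ORDER,
    Hit,
    ReferenceValidationError,
    build_index,
    reverse_complement,
)

# ---------------------------------------------------------------------------
# Brute-force oracle: nested loops over all references and offsets,
# independent of the index implementation.
# ---------------------------------------------------------------------------

def hamming(a, b):
    return sum(x != y or x == "N" or y == "N" for x, y in zip(a, b))


def brute_hits(seq, records, biotype, max_mm):
    hits = []
    for rec in records:
        if rec.biotype != biotype:
            continue
        for off in range(len(rec.sequence) - len(seq) + 1):
            mm = hamming(seq, rec.sequence[off : off + len(seq)])
            if mm <= max_mm:
                hits.append((rec.ref_id, off + 1, mm))
    return sorted(hits)


def brute_annotate(seq, records, genome):
    """Independent cascade + rescue re-implementation."""
    first = None
    for biotype in BIOTYPE_ORDER:
        hits = brute_hits(seq, records, biotype, 0)
        if hits:
            first = (biotype, hits)
            break
    if first is None:
        biotype = "no_annotation"
    else:
        biotype = {"rRNA": "rsRNA", "tRNA": "tsRNA"}.get(first[0], first[0])
    if biotype in ("piRNA", "no_annotation"):
        in_genome = seq in genome or reverse_complement(seq) in genome
        if not in_genome:
            for db, lab in (("rRNA", "rsRNA"), ("tRNA", "tsRNA")):
                hits = brute_hits(seq, records, db, 1)
                if hits:
                    return lab, sorted({h[0] for h in hits}), True
    if first is None:
        return "no_annotation", [], False
    return biotype, sorted({h[0] for h in first[1]}), False


def random_query(rng, records, genome):
    """Random sequences biased toward near-reference windows so every
    cascade branch is exercised."""
    kind = rng.integers(0, 4)
    if kind == 0:  # pure random
        n = int(rng.integers(15, 46))
        return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
    rec = records[rng.integers(0, len(records))]
    L = int(rng.integers(15, min(46, len(rec.sequence) + 1)))
    start = int(rng.integers(0, len(rec.sequence) - L + 1))
    window = rec.sequence[start : start + L]
    if kind == 1:  # exact window
        return window
    pos = int(rng.integers(0, L))
    alt = "ACGT"[("ACGT".index(window[pos]) + 1 + rng.integers(0, 3)) % 4]
    mutated = window[:pos] + alt + window[pos + 1 :]
    if kind == 2:  # one substitution
        return mutated
    pos2 = int(rng.integers(0, L))  # kind == 3: up to two substitutions
    alt2 = "ACGT"[("ACGT".index(mutated[pos2]) + 1 + rng.integers(0, 3)) % 4]
    return mutated[:pos2] + alt2 + mutated[pos2 + 1 :]


class TestCascade:
    def test_mirna_shadows_rrna(self, toy_refset):
        """A sequence present verbatim in both the miRNA set and an rRNA
        record is called miRNA (cascade precedence)."""
        records = list(toy_refset.records)
        mirna = next(r for r in records if r.biotype == "miRNA")
        r18 = next(r for r in records if r.ref_id == "rRNA-18S")
        # craft an rRNA record embedding the mature miRNA
        from sncpipe.refdb import ReferenceRecord

        chimera = ReferenceRecord(
            ref_id="rRNA-16S-chimera",
            biotype="rRNA",
            sequence=r18.sequence[:60] + mirna.sequence + r18.sequence[60:120],
            svedberg_class="16S",
        )
        index = build_index(records + [chimera])
        ann = annotate_sequence(mirna.sequence, index)
        assert ann.biotype == "miRNA"
        assert ann.primary_parent == mirna.ref_id

    def test_cascade_short_circuits(self, toy_refset, monkeypatch):
        records = list(toy_refset.records)
        index = build_index(records)
        mirna = next(r for r in records if r.biotype == "miRNA")
        queried = []
        orig = index.match

        def spy(seq, biotype, max_mismatch=0):
            queried.append(biotype)
            return orig(seq, biotype, max_mismatch=max_mismatch)

        monkeypatch.setattr(index, "match", spy)
        annotate_sequence(mirna.sequence, index)
        assert queried == ["miRNA"]

    def test_random_sequence_unannotated(self, toy_index):
        rng = np.random.default_rng(1)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 25))
        ann = annotate_sequence(seq, toy_index)
        assert ann.biotype in ("no_annotation", "piRNA")  # collision-free seed
        assert ann.biotype == "no_annotation"
        assert ann.parent_ids == []

    def test_18s_window_labelled_18s_not_45s(self, toy_refset, toy_index):
        r18 = next(r for r in toy_refset.records if r.ref_id == "rRNA-18S")
        seq = r18.sequence[40:70]
        ann = annotate_sequence(seq, toy_index)
        assert ann.biotype == "rsRNA"
        assert ann.parent_class == "18S"
        assert set(ann.parent_ids) == {"rRNA-18S", "rRNA-45S"}


class TestTsrnaSubtype:
    @pytest.mark.parametrize(
        "offset,length,parent_len,expected",
        [
            (1, 18, 76, "tsRNA_5p"),
            (55, 22, 76, "tsRNA_3p_CCA"),  # ends on final base
            (46, 28, 76, "tsRNA_3p"),  # ends at parent_len - 3
            (5, 26, 75, "tsRNA_internal"),
            (1, 76, 76, "tsRNA_5p"),  # full-length: 5' precedence over 3'-CCA
            (1, 73, 76, "tsRNA_5p"),  # start 1 and ends at L-3: 5' precedence
        ],
    )
    def test_boundary_rules(self, offset, length, parent_len, expected):
        assert classify_tsrna_position(offset, length, parent_len) == expected

    def test_unprocessed_parent_rejected(self, raw_his_trna):
        from sncpipe.annotate import classify_tsrna

        class FakeIndex:
            by_id = {raw_his_trna.ref_id: raw_his_trna}

        with pytest.raises(ReferenceValidationError, match="processed"):
            classify_tsrna(Hit(raw_his_trna.ref_id, 1, 0), "A" * 18, FakeIndex())


class TestRsrnaParent:
    def test_smallest_svedberg_wins(self, toy_index):
        hits = [Hit("rRNA-45S", 51, 0), Hit("rRNA-18S", 1, 0)]
        cls, parent = assign_rsrna_parent(hits, toy_index)
        assert cls == "18S" and parent == "rRNA-18S"

    def test_58s_before_28s(self, toy_index):
        hits = [Hit("rRNA-28S", 5, 0), Hit("rRNA-5.8S", 9, 0)]
        cls, _ = assign_rsrna_parent(hits, toy_index)
        assert cls == "5.8S"

    def test_single_mitochondrial_hit(self, toy_index):
        cls, parent = assign_rsrna_parent([Hit("rRNA-12S", 3, 0)], toy_index)
        assert cls == "12S" and parent == "rRNA-12S"

    def test_order_is_small_to_large(self):
        assert SVEDBERG_ORDER == ("4.5S", "5S", "5.8S", "12S", "16S", "18S", "28S", "45S")


class TestRescue:
    def test_off_genome_pirna_rescued_as_rsrna(self, toy_refset, toy_index):
        decoy = next(
            r for r in toy_refset.records if r.ref_id == "piR-m-offgenome"
        )
        anns = annotate_sequences([decoy.sequence], toy_index)
        assert anns[0].biotype == "rsRNA"
        assert anns[0].rescued and anns[0].mismatches_used == 1
        assert anns[0].parent_class == "18S"

    def test_genomic_pirna_untouched(self, toy_refset, toy_index):
        pirna = next(r for r in toy_refset.records if r.ref_id == "piR-m-000")
        anns = annotate_sequences([pirna.sequence], toy_index)
        assert anns[0].biotype == "piRNA" and not anns[0].rescued

    def test_hamming2_sequence_stays_unannotated(self, toy_refset, toy_index):
        r18 = next(r for r in toy_refset.records if r.ref_id == "rRNA-18S")
        window = r18.sequence[150:180]
        mutated = "".join(
            ("ACGT"[("ACGT".index(c) + 1) % 4] if i in (5, 20) else c)
            for i, c in enumerate(window)
        )
        anns = annotate_sequences([mutated], toy_index)
        assert anns[0].biotype == "no_annotation" and not anns[0].rescued

    def test_rescue_never_touches_other_first_pass_calls(self, toy_refset, toy_index):
        mirna = next(r for r in toy_refset.records if r.biotype == "miRNA")
        first = [annotate_sequence(mirna.sequence, toy_index)]
        assert rescue_reannotate(first, toy_index)[0] == first[0]

    def test_no_genome_flags_output(self, toy_refset):
        index = build_index(toy_refset.records)  # no genome
        pirna = next(r for r in toy_refset.records if r.ref_id == "piR-m-000")
        anns = annotate_sequences([pirna.sequence], index)
        assert anns[0].genome_checked is False


class TestOracleEquivalence:
    def test_cascade_and_rescue_match_brute_force(self, toy_refset, toy_index):
        """500 random/near-reference sequences annotated identically by the
        pipeline and a nested-loop re-implementation."""
        rng = np.random.default_rng(2024)
        records = toy_refset.records
        queries = sorted({random_query(rng, records, toy_refset.genome) for _ in range(500)})
        anns = annotate_sequences(queries, toy_index)
        for ann in anns:
            biotype, parents, rescued = brute_annotate(
                ann.sequence, records, toy_refset.genome
            )
            assert ann.biotype == biotype, ann.sequence
            assert ann.rescued == rescued, ann.sequence
            if biotype not in ("no_annotation",):
                assert ann.parent_ids == parents, ann.sequence

    def test_determinism(self, toy_refset, toy_index):
        rng = np.random.default_rng(7)
        queries = sorted({random_query(rng, toy_refset.records, toy_refset.genome)
                          for _ in range(100)})
        a = annotations_to_frame(annotate_sequences(queries, toy_index))
        b = annotations_to_frame(annotate_sequences(queries, toy_index))
        assert a.equals(b)


class TestAnnotationInvariants:
    def test_invalid_combinations_rejected(self):
        with pytest.raises(ValueError):
            Annotation(sequence="A" * 20, biotype="miRNA", rescued=True,
                       mismatches_used=1, parent_ids=["x"], primary_parent="x")
        with pytest.raises(ValueError):
            Annotation(sequence="A" * 20, biotype="tsRNA", parent_ids=["t"],
                       primary_parent="t", mismatches_used=0)  # missing subtype
        with pytest.raises(ValueError):
            Annotation(sequence="A" * 20, biotype="no_annotation",
                       parent_ids=["ghost"])
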