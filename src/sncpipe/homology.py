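"""Cross-species small-RNA matching under the seed-anchored identity rule.

Argonaute-loaded small RNAs bind their targets through the seed, the run of
bases starting at the second position from the 5' end.  Two differentially
expressed small RNAs from different species are considered homologous when
the block of identical bases starting at base 2 of both sequences covers
strictly more than 90% of each sequence's total length; the first base and
any 3' overhang may differ.  Matching is direct string comparison within
the same biotype (miRNA with miRNA, tsRNA with tsRNA, ...); no aligner, no
indels, and many-to-many pairs are allowed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd


@dataclass(frozen=True)
class HomologyPair:
    query_id: str
    query_species: str
    subject_id: str
    subject_species: str
    matched_length: int
    coverage_query: float
    coverage_subject: float
    biotype: str = ""
    direction_query: str = ""
    direction_subject: str = ""


def seed_match_length(query_seq: str, subject_seq: str) -> int:
    """Length of the identical block anchored at base 2 of both sequences."""
    q, s = query_seq[1:], subject_seq[1:]
    m = 0
    for a, b in zip(q, s):
        if a != b:
            break
        m += 1
    return m


def seed_anchored_match(
    query_seq: str, subject_seq: str, min_coverage: float = 0.9
) -> Optional[tuple[int, float, float]]:
    """Accept or reject a pair of sequences under the seed-anchored rule.

    Returns ``(matched_length, coverage_query, coverage_subject)`` when the
    anchored block covers strictly more than ``min_coverage`` of both
    sequences, else None.  Both sequences must be at least 15 nt.
    """
    if len(query_seq) < 15 or len(subject_seq) < 15:
        raise ValueError("seed-anchored matching requires sequences >= 15 nt")
    m = seed_match_length(query_seq, subject_seq)
    cov_q = m / len(query_seq)
    cov_s = m / len(subject_seq)
    if cov_q > min_coverage and cov_s > min_coverage:
        return m, cov_q, cov_s
    return None


def cross_species_pairs(
    query_features: pd.DataFrame,
    subject_features_by_lineage: Mapping[str, pd.DataFrame],
    query_species: str = "human",
    subject_species: str = "mouse",
    min_coverage: float = 0.9,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-vs-all seed-anchored matching within biotype, per lineage.

    Both feature frames are indexed by feature id and carry ``sequence``,
    ``biotype`` and ``direction`` columns.  Returns the pair list and a
    lineage x biotype count table.
    """
    pair_rows = []
    for lineage, subject in subject_features_by_lineage.items():
        for q_id, q in query_features.iterrows():
            for s_id, s in subject.iterrows():
                if q["biotype"] != s["biotype"]:
                    continue
                hit = seed_anchored_match(q["sequence"], s["sequence"], min_coverage)
                if hit is None:
                    continue
                m, cov_q, cov_s = hit
                pair_rows.append(
                    {
                        "lineage": lineage,
                        "query_id": q_id,
                        "query_species": query_species,
                        "subject_id": s_id,
                        "subject_species": subject_species,
                        "biotype": q["biotype"],
                        "matched_length": m,
                        "coverage_query": cov_q,
                        "coverage_subject": cov_s,
                        "direction_query": q.get("direction", ""),
                        "direction_subject": s.get("direction", ""),
                    }
                )
    pairs = pd.DataFrame(
        pair_rows,
        columns=[
            "lineage",
            "query_id",
            "query_species",
            "subject_id",
            "subject_species",
            "biotype",
            "matched_length",
            "coverage_query",
            "coverage_subject",
            "direction_query",
            "direction_subject",
        ],
    )
    if len(pairs):
        counts = (
            pairs.groupby(["lineage", "biotype"]).size().unstack(fill_value=0)
        )
    else:
        counts = pd.DataFrame()
    return pairs, counts
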