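"""Feature quantification: identical-sequence clusters, miRNA aggregation,
RPM normalisation and composition summaries.

Reads are collapsed into clusters of identical sequences (exact-duplicate
collapse; there is no similarity radius).  miRNA clusters are then summed
per mature miRNA ID, while all other biotypes keep the exact sequence as
the feature identity so that features can be intersected across samples,
generations and species.  Expression is normalised by library depth into
reads per million (RPM), where depth is the number of QC-passed reads.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Mapping, Optional, Sequence

import pandas as pd

from .annotate import Annotation


@dataclass
class SequenceCluster:
    cluster_id: str
    representative_sequence: str
    annotation: Optional[Annotation] = None
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class FeatureCountMatrix:
    """Integer feature x sample counts with sample metadata.

    ``feature_info`` carries one row per feature (sequence, biotype, subtype,
    parent).  ``library_sizes`` is the per-sample count of clean reads, used
    as the RPM denominator; it is always >= the per-sample column sum.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    library_sizes: pd.Series
    feature_info: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("feature_ids must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        colsum = self.counts.sum(axis=0)
        lib = self.library_sizes.reindex(self.counts.columns)
        if lib.isna().any():
            missing = list(lib[lib.isna()].index)
            raise ValueError(f"missing library sizes for samples {missing}")
        if (colsum > lib + 1e-9).any():
            raise ValueError("library sizes must be >= column sums of counts")


def cluster_id_for(sequence: str) -> str:
    """Deterministic cluster identifier (truncated SHA1 of the sequence)."""
    return "c" + hashlib.sha1(sequence.encode()).hexdigest()[:12]


def cluster_identical(
    reads_by_sample: Mapping[str, Mapping[str, int]],
    annotations: Optional[Mapping[str, Annotation]] = None,
) -> list[SequenceCluster]:
    """Collapse reads into one cluster per distinct sequence.

    ``reads_by_sample`` maps sample -> (sequence -> multiplicity), the shape
    produced by :func:`sncpipe.qc.run_qc`.  Clusters are returned sorted by
    representative sequence, so output order is deterministic.
    """
    clusters: dict[str, SequenceCluster] = {}
    for sample_id, seq_counts in reads_by_sample.items():
        for seq, n in seq_counts.items():
            cl = clusters.get(seq)
            if cl is None:
                cl = SequenceCluster(
                    cluster_id=cluster_id_for(seq),
                    representative_sequence=seq,
                    annotation=annotations.get(seq) if annotations else None,
                )
                clusters[seq] = cl
            cl.counts[sample_id] = cl.counts.get(sample_id, 0) + n
    return [clusters[s] for s in sorted(clusters)]


def aggregate_mirna(
    clusters: Sequence[SequenceCluster],
    samples: pd.DataFrame,
    library_sizes: Mapping[str, int],
) -> FeatureCountMatrix:
    """Sum miRNA clusters per mature miRNA ID; key other clusters by sequence.

    Every miRNA cluster must carry a parent miRNA ID from annotation.
    """
    sample_ids = list(samples.index)
    feature_rows: dict[str, dict] = {}
    counts: dict[str, dict[str, int]] = {}
    for cl in clusters:
        ann = cl.annotation
        if ann is not None and ann.biotype == "miRNA":
            if not ann.primary_parent:
                raise ValueError(
                    f"miRNA cluster {cl.cluster_id} lacks a parent miRNA ID"
                )
            fid = ann.primary_parent
        else:
            fid = cl.representative_sequence
        row = counts.setdefault(fid, {})
        for s, n in cl.counts.items():
            row[s] = row.get(s, 0) + n
        if fid not in feature_rows:
            feature_rows[fid] = {
                "feature_id": fid,
                "sequence": cl.representative_sequence,
                "biotype": ann.biotype if ann is not None else "",
                "subtype": (ann.subtype or "") if ann is not None else "",
                "primary_parent": (ann.primary_parent or "") if ann is not None else "",
                "parent_class": (ann.parent_class or "") if ann is not None else "",
                "rescued": ann.rescued if ann is not None else False,
            }
    feature_ids = sorted(counts)
    mat = pd.DataFrame(
        [[counts[f].get(s, 0) for s in sample_ids] for f in feature_ids],
        index=pd.Index(feature_ids, name="feature_id"),
        columns=sample_ids,
        dtype="int64",
    )
    info = pd.DataFrame([feature_rows[f] for f in feature_ids]).set_index("feature_id")
    lib = pd.Series({s: int(library_sizes[s]) for s in sample_ids}, name="library_size")
    return FeatureCountMatrix(counts=mat, samples=samples, library_sizes=lib, feature_info=info)


def rpm_normalize(
    counts: pd.DataFrame, library_sizes: Mapping[str, int] | pd.Series
) -> pd.DataFrame:
    """Reads-per-million: counts * 1e6 / library size, per sample column."""
    lib = pd.Series(library_sizes).reindex(counts.columns)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s) {list(zero.index)}")
    return counts * 1e6 / lib


def composition_summary(category_counts: Mapping[str, float]) -> pd.DataFrame:
    """Percentages per category, rounded half-even to 2 decimals.

    Returns a frame with ``count``, exact ``fraction`` and rounded
    ``percent`` columns; fractions sum to 1 exactly.
    """
    if any(v < 0 for v in category_counts.values()):
        raise ValueError("category counts must be non-negative")
    total = sum(category_counts.values())
    if total <= 0:
        raise ValueError("composition_summary requires a positive total")
    rows = []
    for name, n in category_counts.items():
        frac = n / total
        pct = float(
            Decimal(100 * n).__truediv__(Decimal(total)).quantize(
                Decimal("0.01"), rounding=ROUND_HALF_EVEN
            )
        )
        rows.append({"category": name, "count": n, "fraction": frac, "percent": pct})
    return pd.DataFrame(rows).set_index("category")
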