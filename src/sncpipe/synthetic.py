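"""Synthetic small-RNA study generator with known truth.

Emulates the structure of a transgenerational sperm sncRNA-seq study plus a
human serum case-control comparison: four maternal-exposure lineages
(control, androgenized, obese, obese+androgenized) x three generations
(F1-F3) x replicate sperm samples, with reads drawn from a mixed-biotype
feature panel under negative-binomial counts, and a 9-vs-9 human serum
panel carrying planted cross-species homologs of the mouse
transgenerational features.

Everything is generated from one pseudo-random stream seeded in
``SimConfig``, so identical configurations give byte-identical outputs.
The reference set is built to exercise every annotation rule: the 18S rRNA
is embedded verbatim inside 45S (Svedberg precedence), one tRNA carries an
intron and one is a histidine tRNA (preprocessing), and off-genome decoys
one mismatch away from rRNA/tRNA windows exercise the rescue pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .qc import DEFAULT_ADAPTOR
from .refdb import ReferenceRecord, preprocess_trna, reverse_complement, write_fasta

MOUSE_LINEAGES = ("control", "androgenized", "obese", "obese_androgenized")

#: (treated, comparator) lineage pairs analysed per generation; the combined
#: lineage is compared against the obese lineage, the others against control.
LINEAGE_CONTRASTS = (
    ("androgenized", "control"),
    ("obese", "control"),
    ("obese_androgenized", "obese"),
)

#: Insert-length ranges per biotype (nt).
BIOTYPE_LENGTHS = {
    "miRNA": (22, 24),
    "piRNA": (20, 34),
    "rsRNA": (15, 44),
    "tsRNA": (27, 36),
}


@dataclass(frozen=True)
class PlantedEffect:
    """A multiplicative expression shift planted in one lineage."""

    feature_id: str
    lineage: str
    direction: str  # "up" or "down"
    generations: tuple[str, ...] = ("F1", "F2", "F3")


@dataclass
class SimConfig:
    """Study design and noise model of the synthetic generator.

    Defaults mirror the emulated design: 4 lineages x F1-F3 x 4 samples,
    2e5 reads per sample (a full-depth study would be ~12e6; available via
    ``paper_scale``), NB dispersion 0.1, 8-fold planted effects with
    direction consistent across generations, error-free reads that all
    carry the 3' adaptor, and library sizes jittered +/-20%.
    """

    seed: int = 1
    generations: tuple[str, ...] = ("F1", "F2", "F3")
    lineages: tuple[str, ...] = MOUSE_LINEAGES
    samples_per_group: int = 4
    depth: int = 200_000
    paper_scale: bool = False
    phi: float = 0.1
    fold_change: float = 8.0
    error_rate: float = 0.0
    adaptor_fraction: float = 1.0
    n_decoy_reads: int = 0
    adaptor: str = DEFAULT_ADAPTOR
    library_jitter: float = 0.2
    n_mirna: int = 8
    n_pirna: int = 10
    human_samples_per_group: int = 9
    human_depth: int = 1_000_000
    planted_effects: Optional[tuple[PlantedEffect, ...]] = None

    @property
    def reads_per_sample(self) -> int:
        return 12_000_000 if self.paper_scale else self.depth

    def __post_init__(self) -> None:
        if self.fold_change <= 1:
            raise ValueError("fold_change must exceed 1")


@dataclass
class ReferenceSet:
    records: list[ReferenceRecord]
    genome: str

    def by_id(self, ref_id: str) -> ReferenceRecord:
        for r in self.records:
            if r.ref_id == ref_id:
                return r
        raise KeyError(ref_id)


@dataclass
class TruthTable:
    """Ground truth of one simulated study."""

    panel: pd.DataFrame  # read-species level: feature_id, agg_id, sequence, ...
    samples: pd.DataFrame
    library_sizes: pd.Series
    counts: pd.DataFrame  # read-species x samples
    effects: tuple[PlantedEffect, ...]
    de_truth: pd.DataFrame  # contrast, generation, feature (agg) id, direction
    transgen_truth: dict  # lineage -> {"up": set, "down": set}


_BASES = "ACGT"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


def _mutate(rng: np.random.Generator, seq: str, pos: int) -> str:
    alternatives = [b for b in _BASES if b != seq[pos]]
    return seq[:pos] + alternatives[rng.integers(0, 3)] + seq[pos + 1 :]


# ---------------------------------------------------------------------------
# References
# ---------------------------------------------------------------------------

_RRNA_LENGTHS = {
    "4.5S": 96,
    "5S": 120,
    "5.8S": 150,
    "12S": 240,
    "16S": 300,
    "18S": 340,
    "28S": 420,
}

_TRNA_SPECS = (
    # (amino acid, anticodon, raw body length, intron interval or None)
    ("His", "GTG", 82, (37, 46)),
    ("Glu", "CTC", 72, None),
    ("Gly", "GCC", 84, (40, 51)),
    ("Val", "CAC", 73, None),
)


def generate_references(cfg: SimConfig, rng: np.random.Generator) -> ReferenceSet:
    """Emit the reference FASTA set and mini-genome.

    The 18S sequence is a verbatim substring of the 45S precursor; the
    mini-genome concatenates all gene loci (raw tRNA genes, rRNAs, miRNA
    loci with flanks, piRNAs, other ncRNAs) separated by random spacers.
    """
    records: list[ReferenceRecord] = []
    loci: list[str] = []

    rrna_seqs = {cls: _random_seq(rng, n) for cls, n in _RRNA_LENGTHS.items()}
    spacers = [_random_seq(rng, n) for n in (50, 30, 30, 50)]
    rrna_seqs["45S"] = (
        spacers[0]
        + rrna_seqs["18S"]
        + spacers[1]
        + rrna_seqs["5.8S"]
        + spacers[2]
        + rrna_seqs["28S"]
        + spacers[3]
    )
    for cls, seq in rrna_seqs.items():
        records.append(
            ReferenceRecord(
                ref_id=f"rRNA-{cls}", biotype="rRNA", sequence=seq, svedberg_class=cls
            )
        )
    # nuclear 45S locus covers 18S/5.8S/28S; mitochondrial and small species
    # appear as their own loci.
    loci += [rrna_seqs["45S"], rrna_seqs["12S"], rrna_seqs["16S"],
             rrna_seqs["5S"], rrna_seqs["4.5S"]]

    for aa, anticodon, body_len, intron in _TRNA_SPECS:
        raw = _random_seq(rng, body_len)
        records.append(
            ReferenceRecord(
                ref_id=f"tRNA-{aa}-{anticodon}-1",
                biotype="tRNA",
                sequence=raw,
                amino_acid=aa,
                intron_intervals=[intron] if intron else None,
            )
        )
        loci.append(raw)

    for i in range(cfg.n_mirna):
        seq = _random_seq(rng, int(rng.integers(22, 25)))
        records.append(
            ReferenceRecord(ref_id=f"mmu-miR-{100 + i}-3p", biotype="miRNA", sequence=seq)
        )
        loci.append(_random_seq(rng, 30) + seq + _random_seq(rng, 30))

    for i in range(cfg.n_pirna):
        seq = _random_seq(rng, int(rng.integers(26, 32)))
        records.append(
            ReferenceRecord(ref_id=f"piR-m-{i:03d}", biotype="piRNA", sequence=seq)
        )
        loci.append(seq)

    for i in range(2):
        seq = _random_seq(rng, 90)
        records.append(
            ReferenceRecord(ref_id=f"ncRNA-{i + 1}", biotype="other_ncRNA", sequence=seq)
        )
        loci.append(seq)

    genome_parts = [_random_seq(rng, 200)]
    for locus in loci:
        genome_parts.append(locus)
        genome_parts.append(_random_seq(rng, 50))
    genome = "".join(genome_parts)

    # Off-genome decoy listed in the piRNA database: one mismatch away from
    # an 18S window, absent from the genome, so the rescue pass must
    # re-annotate it as an 18S-derived rsRNA.
    window = rrna_seqs["18S"][100:128]
    decoy_rs = _mutate(rng, window, 14)
    records.append(
        ReferenceRecord(ref_id="piR-m-offgenome", biotype="piRNA", sequence=decoy_rs)
    )

    refset = ReferenceSet(records=[
        r if r.biotype != "tRNA" else preprocess_trna(r) for r in records
    ], genome=genome)
    _verify_references(refset, decoy_rs)
    return refset


def _verify_references(refset: ReferenceSet, decoy_rs: str) -> None:
    recs = refset.records
    r18 = next(r for r in recs if r.ref_id == "rRNA-18S")
    r45 = next(r for r in recs if r.ref_id == "rRNA-45S")
    assert r18.sequence in r45.sequence
    assert decoy_rs not in refset.genome
    assert reverse_complement(decoy_rs) not in refset.genome
    for r in recs:
        if r.biotype == "tRNA":
            assert r.processed and r.sequence.endswith("CCA")


# ---------------------------------------------------------------------------
# Feature panel
# ---------------------------------------------------------------------------

def build_feature_panel(
    cfg: SimConfig, refset: ReferenceSet, rng: np.random.Generator
) -> pd.DataFrame:
    """Choose the expressed read species and their true annotations.

    One row per distinct read sequence.  ``feature_id`` is the
    quantification key (miRNA ID for miRNA species, the sequence itself for
    the rest); the first miRNA also emits a shorter isomiR read species that
    aggregates into the same feature.
    """
    by_id = {r.ref_id: r for r in refset.records}
    rows: list[dict] = []

    def add(seq, biotype, feature_id=None, subtype="", parent="", parent_class="",
            rescued=False, background=False):
        rows.append(
            {
                "species_id": f"sp{len(rows):03d}",
                "feature_id": feature_id or seq,
                "sequence": seq,
                "biotype": biotype,
                "subtype": subtype,
                "parent": parent,
                "parent_class": parent_class,
                "rescued": rescued,
                "background": background,
            }
        )

    for i in range(cfg.n_mirna):
        rid = f"mmu-miR-{100 + i}-3p"
        seq = by_id[rid].sequence
        add(seq, "miRNA", feature_id=rid, parent=rid)
        if i == 0:  # isomiR: 5'-anchored trimmed variant, same miRNA ID
            add(seq[:-2], "miRNA", feature_id=rid, parent=rid)

    def trna_fragment(ref_id, subtype, length):
        mature = by_id[ref_id].sequence
        L = len(mature)
        if subtype == "tsRNA_5p":
            frag = mature[:length]
        elif subtype == "tsRNA_3p_CCA":
            frag = mature[L - length :]
        elif subtype == "tsRNA_3p":
            frag = mature[L - 3 - length : L - 3]
        else:
            frag = mature[7 : 7 + length]
        add(frag, "tsRNA", subtype=subtype, parent=ref_id)

    trna_fragment("tRNA-His-GTG-1", "tsRNA_5p", 30)
    trna_fragment("tRNA-Glu-CTC-1", "tsRNA_5p", 32)
    trna_fragment("tRNA-Glu-CTC-1", "tsRNA_3p_CCA", 30)
    trna_fragment("tRNA-Gly-GCC-1", "tsRNA_internal", 33)
    trna_fragment("tRNA-Val-CAC-1", "tsRNA_5p", 31)
    trna_fragment("tRNA-Val-CAC-1", "tsRNA_3p", 28)

    def rrna_window(cls, offset, length):
        seq = by_id[f"rRNA-{cls}"].sequence[offset : offset + length]
        add(seq, "rsRNA", parent=f"rRNA-{cls}", parent_class=cls)

    rrna_window("18S", 50, 30)   # also inside 45S; precedence says 18S
    rrna_window("18S", 200, 20)
    rrna_window("28S", 100, 36)
    rrna_window("5.8S", 30, 25)
    rrna_window("12S", 60, 33)
    rrna_window("5S", 10, 21)
    rrna_window("45S", 10, 30)   # within the 45S-only external spacer

    for i in range(6):
        rid = f"piR-m-{i:03d}"
        add(by_id[rid].sequence, "piRNA", parent=rid)

    for i in range(2):
        rid = f"ncRNA-{i + 1}"
        seq = by_id[rid].sequence[20:44]
        add(seq, "other_ncRNA", parent=rid)

    # rescue species 1: the off-genome piRNA-database decoy (true rsRNA)
    add(by_id["piR-m-offgenome"].sequence, "rsRNA", parent="rRNA-18S",
        parent_class="18S", rescued=True)
    # rescue species 2: matches nothing at 0 mismatches, one mismatch from an
    # internal window of the mature Glu tRNA, absent from the genome
    glu = by_id["tRNA-Glu-CTC-1"].sequence
    window = glu[9:37]
    decoy_ts = _mutate(rng, window, 13)
    add(decoy_ts, "tsRNA", subtype="tsRNA_internal", parent="tRNA-Glu-CTC-1",
        rescued=True)

    # High-abundance background pool.  Sperm libraries are dominated by a
    # stable core of rRNA- and tRNA-derived fragments; these species absorb
    # the bulk of the per-sample depth so that planted shifts perturb the
    # RPM denominator only marginally.
    def bg_rrna(cls, offset, length):
        seq = by_id[f"rRNA-{cls}"].sequence[offset : offset + length]
        add(seq, "rsRNA", parent=f"rRNA-{cls}", parent_class=cls, background=True)

    bg_rrna("28S", 200, 30)
    bg_rrna("28S", 300, 32)
    bg_rrna("18S", 280, 25)
    bg_rrna("16S", 100, 30)
    gly = by_id["tRNA-Gly-GCC-1"].sequence
    add(gly[:30], "tsRNA", subtype="tsRNA_5p", parent="tRNA-Gly-GCC-1",
        background=True)
    add(glu[19:49], "tsRNA", subtype="tsRNA_internal", parent="tRNA-Glu-CTC-1",
        background=True)
    add(by_id["piR-m-006"].sequence, "piRNA", parent="piR-m-006", background=True)

    panel = pd.DataFrame(rows).set_index("species_id")
    _verify_panel(panel, refset)
    return panel


_CASCADE = ("miRNA", "rRNA", "tRNA", "piRNA", "other_ncRNA")


def _verify_panel(panel: pd.DataFrame, refset: ReferenceSet) -> None:
    """Check every read species truly annotates to its intended biotype under
    the cascade (direct substring scan, independent of the annotator)."""
    db = {b: [] for b in _CASCADE}
    for r in refset.records:
        db[r.biotype].append(r)
    label = {"rRNA": "rsRNA", "tRNA": "tsRNA"}
    rc_genome = reverse_complement(refset.genome)
    for sid, row in panel.iterrows():
        seq = row["sequence"]
        first = None
        for bt in _CASCADE:
            if any(seq in r.sequence for r in db[bt]):
                first = label.get(bt, bt)
                break
        if row["rescued"]:
            in_genome = seq in refset.genome or seq in rc_genome
            ok = (first in (None, "piRNA")) and not in_genome
        else:
            ok = first == row["biotype"]
        if not ok:
            raise ValueError(f"panel species {sid} fails cascade-truth check")


# ---------------------------------------------------------------------------
# Planted effects, counts and truth
# ---------------------------------------------------------------------------

def default_effects(panel: pd.DataFrame) -> tuple[PlantedEffect, ...]:
    """Direction-consistent transgenerational plants in every treated
    lineage, plus F1-only and F1+F2 plants that must be excluded from the
    transgenerational sets."""
    fg = panel[~panel["background"]]
    tsrna = fg[fg["biotype"] == "tsRNA"]
    rsrna = fg[(fg["biotype"] == "rsRNA") & ~fg["rescued"]]
    pirna = fg[fg["biotype"] == "piRNA"]

    glu5 = tsrna[tsrna["parent"] == "tRNA-Glu-CTC-1"].iloc[0]["feature_id"]
    val5 = tsrna[(tsrna["parent"] == "tRNA-Val-CAC-1")
                 & (tsrna["subtype"] == "tsRNA_5p")].iloc[0]["feature_id"]
    rs18 = rsrna[rsrna["parent_class"] == "18S"].iloc[0]["feature_id"]
    rs28 = rsrna[rsrna["parent_class"] == "28S"].iloc[0]["feature_id"]
    rs58 = rsrna[rsrna["parent_class"] == "5.8S"].iloc[0]["feature_id"]
    pi0 = pirna.iloc[0]["feature_id"]
    pi1 = pirna.iloc[1]["feature_id"]

    return (
        PlantedEffect("mmu-miR-101-3p", "androgenized", "up"),
        PlantedEffect(glu5, "androgenized", "down"),
        PlantedEffect(pi0, "androgenized", "up", generations=("F1",)),
        PlantedEffect("mmu-miR-102-3p", "obese", "up"),
        PlantedEffect(rs18, "obese", "up"),
        PlantedEffect(val5, "obese", "down"),
        PlantedEffect(pi1, "obese", "down"),
        PlantedEffect(rs28, "obese", "up", generations=("F1", "F2")),
        PlantedEffect("mmu-miR-103-3p", "obese_androgenized", "down"),
        PlantedEffect(rs58, "obese_androgenized", "up"),
    )


def _effect_multiplier(
    effects: Sequence[PlantedEffect],
    feature_id: str,
    lineage: str,
    generation: str,
    fold: float,
) -> float:
    """The obese+androgenized lineage inherits the obese lineage's plants
    (it carries the same maternal-obesity exposure)."""
    mult = 1.0
    for e in effects:
        if e.feature_id != feature_id or generation not in e.generations:
            continue
        applies = e.lineage == lineage or (
            e.lineage == "obese" and lineage == "obese_androgenized"
        )
        if applies:
            mult *= fold if e.direction == "up" else 1.0 / fold
    return mult


def nb_counts(
    rng: np.random.Generator, mean: np.ndarray, phi: float
) -> np.ndarray:
    """Negative-binomial draws with variance mu + phi * mu^2 (gamma-Poisson);
    phi = 0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    lam = rng.gamma(shape=r, scale=np.maximum(mean, 1e-300) * phi)
    return rng.poisson(lam)


#: Per-sample RPM budget; realised library sizes then match the configured
#: depth because baselines sum to one million RPM.
TOTAL_RPM = 1e6


def _assign_baselines(
    panel: pd.DataFrame, effects: Sequence[PlantedEffect], rng: np.random.Generator
) -> pd.Series:
    """Baseline mean abundance (RPM) per read species.

    Planted features sit at 300-1000 RPM, other foreground species follow a
    clipped lognormal, and the background pool splits the remaining budget
    so the whole panel sums to :data:`TOTAL_RPM`.
    """
    planted = {e.feature_id for e in effects}
    base = pd.Series(index=panel.index, dtype=float)
    bg_weights: dict[str, float] = {}
    for sid, row in panel.iterrows():
        if row.get("background", False):
            base[sid] = 0.0
            bg_weights[sid] = rng.lognormal(0.0, 0.5)
        elif row["feature_id"] in planted:
            base[sid] = rng.uniform(300.0, 1000.0)
        else:
            base[sid] = float(np.clip(rng.lognormal(np.log(120.0), 1.0), 20.0, 2000.0))
    remainder = TOTAL_RPM - base.sum()
    if bg_weights:
        if remainder <= 0:
            raise ValueError("foreground baselines exceed the RPM budget")
        total_w = sum(bg_weights.values())
        for sid, w in bg_weights.items():
            base[sid] = remainder * w / total_w
    return base


def simulate_counts(
    cfg: SimConfig,
    panel: pd.DataFrame,
    rng: np.random.Generator,
    effects: Optional[Sequence[PlantedEffect]] = None,
) -> TruthTable:
    """Draw the true count matrix and derive the DE / transgenerational truth."""
    if effects is None:
        effects = cfg.planted_effects or default_effects(panel)
    effects = tuple(effects)
    for e in effects:
        if e.feature_id not in set(panel["feature_id"]):
            raise ValueError(f"planted effect on unknown feature {e.feature_id}")

    sample_rows = []
    for lineage in cfg.lineages:
        for gen in cfg.generations:
            for i in range(cfg.samples_per_group):
                sample_rows.append(
                    {
                        "sample_id": f"{lineage}_{gen}_s{i + 1}",
                        "lineage": lineage,
                        "generation": gen,
                    }
                )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")

    depth = cfg.reads_per_sample
    jitter = rng.uniform(
        1 - cfg.library_jitter, 1 + cfg.library_jitter, len(samples)
    )
    lib = pd.Series(
        np.round(depth * jitter).astype(int), index=samples.index, name="library_size"
    )

    baseline_rpm = _assign_baselines(panel, effects, rng)

    means = np.empty((len(panel), len(samples)))
    for j, (sid, srow) in enumerate(samples.iterrows()):
        for i, (spid, prow) in enumerate(panel.iterrows()):
            mult = _effect_multiplier(
                effects, prow["feature_id"], srow["lineage"], srow["generation"],
                cfg.fold_change,
            )
            means[i, j] = baseline_rpm[spid] * mult * lib[sid] / 1e6
    counts = pd.DataFrame(
        nb_counts(rng, means, cfg.phi), index=panel.index, columns=samples.index
    )

    de_rows = []
    transgen: dict[str, dict[str, set]] = {}
    agg_features = sorted(set(panel["feature_id"]))
    for treated, comparator in LINEAGE_CONTRASTS:
        contrast = f"{treated}_vs_{comparator}"
        per_gen_dir: dict[str, dict[str, str]] = {}
        for gen in cfg.generations:
            dirs: dict[str, str] = {}
            for fid in agg_features:
                ra = _effect_multiplier(effects, fid, treated, gen, cfg.fold_change)
                rb = _effect_multiplier(effects, fid, comparator, gen, cfg.fold_change)
                if ra != rb:
                    dirs[fid] = "up" if ra > rb else "down"
                    de_rows.append(
                        {
                            "contrast": contrast,
                            "generation": gen,
                            "feature_id": fid,
                            "direction": dirs[fid],
                        }
                    )
            per_gen_dir[gen] = dirs
        up = set.intersection(
            *[{f for f, d in per_gen_dir[g].items() if d == "up"} for g in cfg.generations]
        )
        down = set.intersection(
            *[{f for f, d in per_gen_dir[g].items() if d == "down"} for g in cfg.generations]
        )
        transgen[treated] = {"up": up, "down": down}

    de_truth = pd.DataFrame(
        de_rows, columns=["contrast", "generation", "feature_id", "direction"]
    )
    panel = panel.copy()
    panel["baseline_rpm"] = baseline_rpm
    return TruthTable(
        panel=panel,
        samples=samples,
        library_sizes=lib,
        counts=counts,
        effects=effects,
        de_truth=de_truth,
        transgen_truth=transgen,
    )


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def synthesize_reads(
    truth: TruthTable,
    cfg: SimConfig,
    outdir: str | Path,
    rng: np.random.Generator,
    gzip_fastq: bool = False,
) -> dict[str, Path]:
    """Write one FASTQ per sample plus the sample sheet.

    Each read species emits reads of its exact sequence; the configured
    adaptor is appended to ``adaptor_fraction`` of reads, substitution
    errors are injected at ``error_rate`` per base, and ``n_decoy_reads``
    adaptor-free random reads are spiked per sample (they fail QC and test
    count conservation).  Qualities are Phred+33 Q40.
    """
    import gzip as gzmod

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seqs = truth.panel["sequence"]
    for spid in truth.panel.index:
        if len(seqs[spid]) < 1:
            raise ValueError(f"empty fragment for species {spid}")
    paths: dict[str, Path] = {}
    for sample_id in truth.samples.index:
        reads: list[str] = []
        for spid, n in truth.counts[sample_id].items():
            if n > 0:
                reads.extend([seqs[spid]] * int(n))
        order = rng.permutation(len(reads))
        lines: list[str] = []
        for k, idx in enumerate(order):
            seq = reads[idx]
            if cfg.error_rate > 0:
                n_err = rng.binomial(len(seq), cfg.error_rate)
                for _ in range(n_err):
                    seq = _mutate(rng, seq, int(rng.integers(0, len(seq))))
            if cfg.adaptor_fraction >= 1.0 or rng.random() < cfg.adaptor_fraction:
                seq = seq + cfg.adaptor
            lines.append(f"@{sample_id}_{k}\n{seq}\n+\n{'I' * len(seq)}\n")
        for k in range(cfg.n_decoy_reads):
            seq = _random_seq(rng, 25)
            lines.append(f"@{sample_id}_decoy_{k}\n{seq}\n+\n{'I' * len(seq)}\n")
        suffix = ".fastq.gz" if gzip_fastq else ".fastq"
        path = outdir / f"{sample_id}{suffix}"
        data = "".join(lines)
        if gzip_fastq:
            with gzmod.open(path, "wt") as fh:
                fh.write(data)
        else:
            path.write_text(data)
        paths[sample_id] = path

    sheet = outdir / "samples.tsv"
    truth.samples.to_csv(sheet, sep="\t")
    return paths


def write_reference_fastas(refset: ReferenceSet, outdir: str | Path) -> dict[str, Path]:
    """One FASTA per biotype database plus the mini-genome."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for biotype in ("miRNA", "rRNA", "tRNA", "piRNA", "other_ncRNA"):
        path = outdir / f"{biotype}.fa"
        write_fasta([r for r in refset.records if r.biotype == biotype], path)
        paths[biotype] = path
    gpath = outdir / "genome.fa"
    gpath.write_text(">minigenome\n" + "\n".join(
        refset.genome[i : i + 80] for i in range(0, len(refset.genome), 80)
    ) + "\n")
    paths["genome"] = gpath
    return paths


# ---------------------------------------------------------------------------
# Human serum panel with planted cross-species homologs
# ---------------------------------------------------------------------------

@dataclass
class HumanStudy:
    features: pd.DataFrame  # feature_id, sequence, biotype, direction ("" if none)
    samples: pd.DataFrame
    library_sizes: pd.Series
    counts: pd.DataFrame
    planted_pairs: pd.DataFrame  # lineage, human feature, mouse feature, biotype


def _max_tail_mutations(length: int, min_coverage: float = 0.9) -> int:
    """Largest 3' mutation count that keeps the seed-anchored block covering
    strictly more than ``min_coverage`` of both equal-length sequences."""
    t = 0
    while (length - (t + 1) - 1) / length > min_coverage:
        t += 1
    return t


def make_homolog(seq: str, rng: np.random.Generator) -> str:
    """Copy a sequence, mutating base 1 and as many terminal 3' bases as the
    90%-coverage rule tolerates; the pair is accepted by construction."""
    out = _mutate(rng, seq, 0)
    for k in range(_max_tail_mutations(len(seq))):
        out = _mutate(rng, out, len(seq) - 1 - k)
    return out


def make_near_miss(seq: str, rng: np.random.Generator) -> str:
    """Copy a sequence with an internal mutation; rejected by construction."""
    return _mutate(rng, seq, len(seq) // 2)


def simulate_human_study(
    cfg: SimConfig,
    mouse_truth: TruthTable,
    rng: np.random.Generator,
    n_background: int = 30,
) -> HumanStudy:
    """A 9-vs-9 serum comparison carrying homologs of every mouse
    transgenerational feature, near-miss decoys, and background features."""
    panel = mouse_truth.panel
    info = panel.drop_duplicates("feature_id").set_index("feature_id")

    rows = []
    pair_rows = []
    counter = 0

    def hs_name(biotype):
        nonlocal counter
        counter += 1
        if biotype == "miRNA":
            return f"hsa-miR-{500 + counter}-3p"
        return f"hs-feature-{counter:03d}"

    seen_mouse: dict[str, str] = {}
    for lineage, sets in mouse_truth.transgen_truth.items():
        for direction in ("up", "down"):
            for fid in sorted(sets[direction]):
                if fid not in seen_mouse:
                    seq = info.loc[fid, "sequence"]
                    hs_id = hs_name(info.loc[fid, "biotype"])
                    rows.append(
                        {
                            "feature_id": hs_id,
                            "sequence": make_homolog(seq, rng),
                            "biotype": info.loc[fid, "biotype"],
                            "direction": direction,
                        }
                    )
                    seen_mouse[fid] = hs_id
                pair_rows.append(
                    {
                        "lineage": lineage,
                        "query_id": seen_mouse[fid],
                        "subject_id": fid,
                        "biotype": info.loc[fid, "biotype"],
                        "direction_query": direction,
                        "direction_subject": direction,
                    }
                )

    # near-miss decoys: DE in serum but internally mutated, never paired
    transgen_all = sorted(seen_mouse)
    for fid in transgen_all[:3]:
        rows.append(
            {
                "feature_id": hs_name(info.loc[fid, "biotype"]),
                "sequence": make_near_miss(info.loc[fid, "sequence"], rng),
                "biotype": info.loc[fid, "biotype"],
                "direction": "up",
            }
        )
    # unrelated DE decoys
    for biotype, length in (("miRNA", 22), ("piRNA", 28), ("rsRNA", 30), ("tsRNA", 32)):
        rows.append(
            {
                "feature_id": hs_name(biotype),
                "sequence": _random_seq(rng, length),
                "biotype": biotype,
                "direction": "down",
            }
        )
    # background, not differentially expressed
    for i in range(n_background):
        biotype = ("miRNA", "piRNA", "rsRNA", "tsRNA")[i % 4]
        lo, hi = BIOTYPE_LENGTHS[biotype]
        rows.append(
            {
                "feature_id": hs_name(biotype),
                "sequence": _random_seq(rng, int(rng.integers(max(lo, 18), hi + 1))),
                "biotype": biotype,
                "direction": "",
            }
        )

    features = pd.DataFrame(rows).set_index("feature_id")
    if features["sequence"].duplicated().any():
        raise ValueError("duplicate human feature sequences")

    n = cfg.human_samples_per_group
    sample_rows = [
        {"sample_id": f"hs_pcos_s{i + 1}", "group": "pcos"} for i in range(n)
    ] + [{"sample_id": f"hs_ctrl_s{i + 1}", "group": "control"} for i in range(n)]
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    jitter = rng.uniform(1 - cfg.library_jitter, 1 + cfg.library_jitter, len(samples))
    lib = pd.Series(
        np.round(cfg.human_depth * jitter).astype(int),
        index=samples.index,
        name="library_size",
    )

    baseline = rng.uniform(300.0, 1000.0, len(features))
    means = np.empty((len(features), len(samples)))
    for j, (sid, srow) in enumerate(samples.iterrows()):
        for i, (fid, frow) in enumerate(features.iterrows()):
            mult = 1.0
            if srow["group"] == "pcos" and frow["direction"]:
                mult = cfg.fold_change if frow["direction"] == "up" else 1 / cfg.fold_change
            means[i, j] = baseline[i] * mult * lib[sid] / 1e6
    counts = pd.DataFrame(
        nb_counts(rng, means, cfg.phi), index=features.index, columns=samples.index
    )
    planted_pairs = pd.DataFrame(
        pair_rows,
        columns=[
            "lineage", "query_id", "subject_id", "biotype",
            "direction_query", "direction_subject",
        ],
    )
    return HumanStudy(
        features=features,
        samples=samples,
        library_sizes=lib,
        counts=counts,
        planted_pairs=planted_pairs,
    )
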