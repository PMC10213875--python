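# Methods

This note documents the models, rules and numerical choices behind each
stage of `sncpipe`, the assumptions of the synthetic-data generator, and
what the package's tests do and do not establish about real data.

## Read QC

Trimming follows cutadapt-style 3′ prefix-anchored semantics: an adaptor
occurrence at read position *j* aligns a prefix of the adaptor of length
`overlap = min(len(adaptor), len(read) − j)` and is accepted when
`overlap ≥ min_overlap` (default 3) and the number of mismatches is at most
`floor(error_rate × overlap)` (default rate 0.1). The leftmost accepted
occurrence wins and everything from it onwards is removed. A read is
retained iff an adaptor was found, the insert is 15–45 nt inclusive, and at
least 80% of insert bases have Phred quality strictly above 20 (Q20 itself
does not count). An adaptor at position 0 leaves an empty insert, which
fails as too short. Input is Phred+33; a config flag supports +64 legacy
data. Reads with no adaptor occurrence are discarded rather than trimmed —
the stricter of the two readings of "containing adaptor sequence", exposed
to users in the stats output.

## Reference preprocessing and matching

All sequences are normalised to DNA (U→T, uppercase) at load time. tRNA
genes are matured before indexing: predicted introns (1-based inclusive
intervals, validated non-overlapping and in range) are excised, `CCA` is
appended, and histidine tRNAs receive the extra 5′ `G`; splice-junction
positions are kept as metadata. Matching everywhere is end-to-end
read-in-reference substring alignment under Hamming distance — no indels,
because at an edit budget of ≤1 an indel would blur the tsRNA subtype
boundaries that depend on exact fragment ends. `N` never matches anything,
including another `N` (conservative). Biotype databases are indexed on the
sense strand only (they store mature sense sequences); the genome is used
only for exact presence checks and is searched on both strands.

## Annotation cascade, subtypes, rescue

The cascade queries miRNA, rRNA, tRNA, piRNA, other ncRNA in that order at
zero mismatches and stops at the first database with a hit, so identical
sequences are never double-counted across biotypes. Derived classes:

- **rsRNA**: parent class is the smallest Svedberg label among the hit
  records under the fixed order 4.5S < 5S < 5.8S < 12S < 16S < 18S < 28S
  < 45S. This resolves the redundancy of precursors: a read inside 18S,
  which is itself a block of 45S, is 18S-derived.
- **tsRNA**: subtype from the match coordinates on the mature tRNA of
  length L — start 1 → 5′ fragment; end = L → 3′ fragment with CCA end;
  end = L−3 → 3′ fragment abutting but excluding the CCA; otherwise
  internal. When a fragment satisfies two rules (e.g. a full-length read)
  or multiple parents disagree, precedence is 5′ > 3′-CCA > 3′ > internal.
  The boundary tolerance is 0 bases and is exposed in configuration.

Ties between parents are kept: all parent IDs are reported; the primary
parent is chosen by fewest mismatches, then smallest Svedberg class (rsRNA)
or lexicographic ID. The rescue pass takes first-pass piRNA and unannotated
sequences that are absent from the genome (exact match, either strand) and
re-matches them at ≤1 mismatch against rRNA then tRNA — rRNA first,
mirroring the cascade, since no priority is otherwise defined — producing
rescued rsRNA/tsRNA calls with `rescued=True` and `mismatches_used=1`. The
single mismatch accommodates RNA base modifications that sequencing reads
as substitutions. If no genome is supplied, every piRNA/unannotated call is
treated as a rescue candidate and the output rows are flagged
`genome_checked=False`.

## Quantification

Reads collapse into clusters of *identical* sequences (exact-duplicate
collapse; the OTU-style radius of general-purpose clusterers is
deliberately not used, since small-RNA isoforms one substitution apart are
distinct biological species here). miRNA clusters are summed per mature
miRNA ID; all other biotypes keep the exact sequence as the feature key, so
features can be intersected across generations and species without an ID
system. RPM is counts × 10⁶ / library size, with library size defined as
the number of QC-passed reads of the sample (not the annotated subset);
this is configurable. Composition percentages are rounded half-even to two
decimals; exact fractions are returned alongside.

## Differential expression

Per comparison (two disjoint groups, ≥2 replicates each):

1. **Filter**: keep features with log₂(mean RPM across the comparison's
   samples) ≥ 1, i.e. mean RPM ≥ 2, boundary kept. No pseudocount is needed
   because the filter operates on the mean, which is positive whenever any
   read was seen; log base and threshold are configurable.
2. **Pseudo-counts**: counts are scaled proportionally to the geometric
   mean of the library sizes and rounded to the nearest integer, making
   per-sample libraries equal so that the conditional arguments below hold.
3. **Common dispersion**: one φ for all features, maximising the sum over
   features and groups of the NB conditional log-likelihood given the
   per-feature group totals (the mean parameter conditions out). The
   optimiser works on log φ over [10⁻⁶, 10] (bounded Brent, xatol 1e-4);
   fits indistinguishable from the Poisson boundary return φ = 0. Tagwise
   shrinkage is intentionally out of scope: a single dispersion keeps the
   test fully specified and testable against closed forms. Agreement with
   the Bioconductor reference implementation is verified in the test suite
   (dispersion to ~1e-3, p-values to ~1e-6 on a balanced design).
4. **Exact test**: the group-A total given the grand total follows a
   negative hypergeometric law (beta-binomial form of the NB split); the
   two-sided p sums all splits whose probability does not exceed the
   observed one, with a 1e-10 log-domain tie tolerance so mirror-image
   splits equal up to rounding are counted symmetrically. φ = 0 uses the
   conditional binomial with success probability n_a/(n_a+n_b).
5. **Calls**: up iff log₂FC > 1 and p < 0.05; down symmetric; strict
   inequalities. log₂FC is computed from group mean RPM with a prior of
   0.5 RPM added to each group mean to avoid infinities at zero. BH FDR is
   reported but does not drive calls — the raw-p rule is the convention
   this pipeline reproduces, and users can re-threshold on the FDR column.

## Transgenerational overlap

A feature is transgenerational in a lineage iff it is DE with the same
direction in F1, F2 and F3 against the lineage's parallel-bred comparator;
an F1∩F2 (intergenerational) set is reported too. Direction consistency is
required by default (configurable to presence-only). Features filtered out
in any generation have no call there and therefore cannot be
transgenerational. A long-format (feature × generation, log₂FC) table is
exported for heat-map plotting.

## Cross-species homology

The seed-anchored rule: let m be the length of the identical block starting
at base 2 of both sequences. A pair is accepted iff m strictly exceeds 90%
of *both* lengths. Rationale: Argonaute target recognition is driven by the
seed starting at the second base, so the first base is ignored entirely and
only a short 3′ overhang is tolerated. Coverage of both sequences (rather
than only the shorter) is the adopted reading of "their total lengths" and
is configurable. Matching is plain string comparison restricted to equal
biotypes; no heuristic seeding or external aligner is involved, and
many-to-many pairs are allowed. For tsRNA pairs the parent isoacceptor and
fragment origin are available from the annotation tables.

## Synthetic-data generator

The generator emulates the structure of a transgenerational sperm study
plus a human serum case-control comparison: 4 lineages (control,
androgenized, obese, obese+androgenized) × F1–F3 × 4 samples, analysed as
androgenized vs control, obese vs control, and obese+androgenized vs obese
per generation, plus a 9 vs 9 human panel. Defaults: 2×10⁵ reads per
sample (a full-scale run of ~12×10⁶ is available via `paper_scale`), NB
dispersion φ = 0.1, 8-fold planted effects with direction consistent across
generations, error-free reads all carrying the 3′ adaptor, library sizes
jittered ±20%, Phred+33 Q40 qualities. Counts are gamma–Poisson draws with
variance μ + φμ²; all randomness flows through one seeded stream, so equal
configurations give byte-identical FASTQ and truth tables.

The reference set is built to exercise every annotation rule: 18S is a
verbatim substring of 45S; one tRNA carries an intron and one is a
histidine tRNA; fragment species cover all four tsRNA subtypes and seven
rRNA classes; one piRNA-database entry and one orphan sequence are placed
one mismatch away from rRNA/tRNA windows and left out of the mini-genome to
exercise the rescue path. Read lengths follow the biotype conventions
(miRNA 22–24, piRNA 20–34, rsRNA 15–44, tsRNA 27–36 nt). A
high-abundance background pool of rRNA/tRNA fragments fills the per-sample
RPM budget to 10⁶, mirroring the composition of real sperm libraries where
differential features are a small fraction of depth; without it, planted
shifts would perturb the RPM denominator itself and induce compositional
artefacts (the same artefact affects real RPM-normalised data when
expression shifts are large — a known limitation of RPM shared with the
workflow this package reproduces). Planted features sit at 300–1000
baseline RPM. The obese+androgenized lineage inherits the obese lineage's
planted effects (it shares the maternal-obesity exposure), which keeps its
own comparison against the obese lineage clean. Human homologs of every
mouse transgenerational feature are generated by mutating base 1 and as
many terminal 3′ bases as the >90% rule tolerates (accepted by
construction); near-miss decoys carry an internal mutation (rejected by
construction).

What the generator does **not** model: ligation and GC bias, RNA
modifications, indel errors, multimapping genomic repeats, adapter dimers,
between-litter random effects, and real database redundancy beyond the
constructed 18S/45S nesting. Passing the end-to-end tests therefore shows
that the pipeline's logic is correct under its own model assumptions — not
that annotation of real libraries is error-free.

## Problem sizes and runtimes

End-to-end runs in the tests and the acceptance script use 25,000 reads per
sample (48 mouse samples ≈ 1.2M reads) — a deliberately scaled-down study
that keeps planted features above 50 RPM mean abundance with wide margin
while a full run stays minutes-cheap on one core; QC memoises identical
(sequence, quality) records, which makes deeply duplicated small-RNA
libraries inexpensive. Statistical calibration checks use 2,000 features ×
8 samples. The oracle-equivalence checks use 5,000 reads (QC), 2,000
sequences (annotation) and 1,000 pairs (homology), all against naive
re-implementations written independently of the production code paths.

## Known limitations

- Common dispersion only; no tagwise shrinkage or GLM framework.
- RPM normalisation only; no TMM/upper-quartile (out of scope), so strongly
  asymmetric global shifts bias fold changes, as discussed above.
- The rescue pass checks genome presence at 0 mismatches; the original
  aligner settings behind such workflows are typically unstated.
- "Other ncRNA" is one terminal biotype; no subdivision into
  snoRNA/snRNA/lncRNA classes.
- Antisense matching, probabilistic multimapper resolution and isomiR-level
  analysis are non-goals.
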