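# Methods

## The contaminant screen

### Statistic

Let `r[o, j]` be OTU `o`'s relative abundance in library `j` (counts divided
by the library total). With blank set `B` and specimen set `S`,

    b(o) = mean_{j in B} r[o, j]
    s(o) = mean_{j in S} r[o, j]
    share(o) = b(o) / (b(o) + s(o)),   share(o) = 0 when b = s = 0.

An OTU is flagged iff `share(o) >= tau` (boundary inclusive; default
`tau = 0.10`). Consequences of the definition, all enforced by tests:

* an OTU absent from every blank has share 0 and is never flagged for any
  `tau > 0`; an OTU absent from every specimen has share 1 and is always
  flagged for any `tau <= 1`;
* flagged sets are nested as `tau` grows (threshold monotonicity);
* the statistic is invariant to permuting samples or OTUs and to library-size
  imbalance between blanks and specimens, because abundances are
  depth-normalized before averaging.

Means of relative abundances were chosen over pooling raw reads precisely for
that last property: a single deep blank cannot swamp the evidence from the
other blanks. Per-blank relative abundances are retained in each `FlagRecord`
so a reviewer can see whether the blanks agree — each blank is an independent
observation of the reagent pool. Alternative aggregations (max over blanks,
prevalence-based) would slot into `blank_shares()` without touching the rest
of the pipeline.

The screen is deliberately not a hypothesis test: no p-values, no
multiple-testing machinery. It is a deterministic triage step whose output a
human reviews. Culling is file-driven (a decisions TSV of `otu_id`,
`remove`/`retain`); flagged OTUs without a decision are retained and recorded
as `pending`, so a partially reviewed run is visible as such. The retention
report states `100 × surviving reads / input reads`, and input reads always
equal surviving plus removed reads exactly (conservation, tested).

### Annotation

Flagged OTUs are annotated with the `top_k = 10` closest matches in a
reference 16S database, carrying percent identity, percent query coverage,
e-value, taxonomy, and the reference record's environmental source — the
evidence a reviewer needs to distinguish "human skin / reagent" hits from
plausible environmental lineages.

## The aligner

Affine-gap Smith–Waterman (Gotoh), a gap of length L costing
`gap_open + L·gap_extend`; defaults `+2 / −3 / −5 / −2` mimic ungapped-BLASTN
conventions. The engine makes no claim of bit-for-bit BLAST equivalence —
what the downstream thresholds need is a well-defined identity and coverage,
so the traceback is canonical:

* among co-optimal alignments the winner has the smallest
  `(query_start, subject_start, query_end, subject_end)`;
* within a traceback, moves tie-break diagonal > gap-in-subject >
  gap-in-query, opening preferred over extending, and a local restart
  (score 0) preferred over any zero-score move.

Identity is matching columns / aligned columns (a local alignment has no end
gaps; internal gap columns count in the denominator). A column matches iff
the two characters' IUPAC sets intersect, and such columns also score as
matches — permissive, deterministic, and documented; ambiguity codes are kept
as read, never collapsed to N. Query coverage is aligned query residues /
query length, i.e. the per-best-HSP reading of a coverage threshold.

The fill runs as a numba-compiled kernel (an alignment-heavy partition run
touches ~10⁸ DP cells); the test suite checks it column-for-column against an
independently written pure-Python oracle implementing the same canonical
rule, on 500 random pairs of 50–400 nt plus property tests.

Seeded search indexes exact k-mers (default `k = 8`, unambiguous words only)
over reference sense strands; queries are looked up as-is and
reverse-complemented, and every subject sharing at least one word is then
fully aligned on both strands (best strand kept, `+` on ties). Ranking is by
score, then e-value, then subject id. E-values follow the Karlin–Altschul
form `E = K·m·n·exp(−λS)` with defaults `K = 0.711`, `λ = 1.374` per score
unit, `m` the query length and `n` the total database length. Word size,
scoring, `K`, `λ` and `top_k` are all configurable; the defaults are declared
conventions, not fitted values. The seeding is the only heuristic: a subject
sharing no exact word with either strand is not scored. The fixture generator
therefore guarantees planted homologs a shared word (below), which is what
makes seeded-equals-exhaustive testable.

## MAG partitioning

### Coverage-uniformity QC

Assembled 16S genes are chimera-prone, and the original practice of eyeballing
per-base coverage does not reproduce, so the screen is quantified: with
`d` the per-base depth over the reconstructed gene (reads mapped to the gene
itself, gene-local coordinates) and `c` the parent contig's per-base depth,

    cv = population stdev(d) / mean(d)
    ratio = mean(d) / mean(c)

and a gene passes iff `cv <= cv_max` and `ratio_lo <= ratio <= ratio_hi`
(defaults 1.0 and [0.25, 4.0], boundaries inclusive). A gene with zero mean
depth fails, with cv recorded as infinite. Both statistics are invariant
under jointly rescaling all depths, so sequencing effort does not move the
decision. Missing positions in a depth track mean depth 0. Genes without an
explicit QC record are treated as passing — QC is an optional screen, and a
user who skips it should not silently exclude every MAG.

### Partition rule

`excluded` = MAGs with no 16S gene or with every gene explicitly failing QC;
`biofilm_linked` = non-excluded MAGs with at least one amplicon match at
`identity >= 99.0` and `amplicon coverage >= 90.0` (inclusive; each
amplicon×gene pair aligned on both strands); `planktonic` = the rest. One
passing match suffices — the classification is binary by design, no vote
counting. The three sets are a disjoint cover of the input MAGs (property
test over random fixtures).

### Read recruitment

Each metagenomic read goes to at most one OTU representative: the
best-scoring alignment passing the same thresholds, ties broken by higher
identity then lexicographic OTU id. Coverage here is measured on the shorter
of read and representative, because fluid metagenome reads may be shorter
than the amplicon; this is a declared choice, isolated in `recruit_reads`.

## Functional comparison

Category abundance for a fraction = annotated genes in the category over the
fraction's MAGs / total predicted ORFs over those MAGs. Differences between
fractions are reported signed, with categories missing from one profile
treated as 0. The per-gene "spider" table rescales each gene's normalized
abundance to [0, 1] by the maximum across the two fractions, so at least one
fraction sits at 1 unless both are 0 — a declared convention for an axis that
admits several readings, isolated in `compare_profiles`. Marker-panel
presence is existential: an entry (a set of alternative gene symbols) is
present in a fraction iff any of the fraction's MAGs carries any of the
symbols (case-insensitive). Presence is monotone in the annotation table, and
excluded MAGs never contribute to either fraction. Annotation itself (KO
assignment, HMM search) is upstream; this module consumes its tabular output.

## Synthetic data

The generator's role is to provide every input with *exact* planted truth.

* **Count tables.** Blank columns give contaminant OTUs `1 − ε` of the mass
  (split log-normally) and background OTUs `ε` (default 0.002), emulating
  cross-contamination of the specimen community into blanks; specimen columns
  are solved from each contaminant's target share via `s = b(1/σ − 1)`, with
  background filling the remainder proportional to a log-normal base
  community (σ = 0.8). Because compositions are constructed, every OTU's
  expected blank share is analytic and recorded: planted contaminants default
  to σ ∈ [0.6, 1.0], and all background OTUs share one value
  `ε / (ε + background specimen mass)` < 0.01 — both sides clear of the 0.10
  threshold by a margin far exceeding multinomial sampling error at the
  default 5×10⁴ reads/library. Library sizes are exact (multinomial with
  fixed total); between-library variation comes from resampling alone.
  Infeasible share sets (requiring > 95% of specimen mass) are rejected.
* **Mutated copies** (contaminant representatives, linked 16S genes,
  metagenomic reads) carry a fixed substitution count, placed at least 2 nt
  from the ends (so the optimal local alignment spans the whole copy and
  identity equals `(L − k)/L` exactly) and outside a protected k-long window
  (guaranteeing a shared seed word). Fixed counts rather than per-site
  Bernoulli mutation make planted truth deterministic: a 250-nt read at the
  default 0.5% rate carries exactly 1 substitution and always passes the 99%
  threshold, so recruitment truth is exact rather than probabilistic.
* **MAG sets** plant the three classes directly; linked genes embed a
  2-substitution amplicon copy (identity 99.2% at 250 nt — just above
  threshold, deliberately), unlinked genes are unrelated random sequence
  (far below any plausible threshold), and excluded MAGs carry no gene.
* **Depth tracks** come in three shapes: `uniform` (cv 0, ratio 1),
  `spiked` (half the gene at 5× contig depth, half at 0: cv exactly 1,
  ratio 2.5 — the canonical chimera signature straddling the default cv
  bound), and `zero`.
* **Annotations** realize a planted presence pattern (default: a
  Wood-Ljungdahl marker in both fractions, RuBisCO plankton-only,
  dsr-operon genes biofilm-only, etc.) plus log-uniform background KO rows
  per category, with ORF totals always at least the annotated count.

What the generator does **not** emulate: sequencing error and chimeras at the
read level, taxon-correlated contamination structure, batch-paired blanks,
compositional correlation between specimens, or realistic 16S sequence
phylogeny (background sequences are i.i.d. random). Passing tests therefore
demonstrate the algorithms' contracts — thresholds, invariants, exact
recovery of planted structure separated from decision boundaries — not
field performance on real communities.

All sampling is routed through `numpy.random.default_rng` seeded from
`(per-operation salt, spec.seed)`, so each generated artifact is
independently reproducible and whole-directory simulation is byte-identical
under a fixed seed.

## Problem sizes and determinism

Headline checks run at the study's stated shapes: 200-OTU tables (4
specimens, 2 blanks, 5×10⁴ reads/library, 20 planted contaminants) and
23-MAG sets (12 linked / 8 unlinked / 3 lacking 16S). Property sweeps (100
random fixtures for flag monotonicity and partition cover) use smaller
randomized shapes — tens of OTUs, 2–8 MAGs, 100–220 nt sequences — chosen so
the full suite runs in about a minute while still exploring the parameter
space. The oracle-equivalence check uses the full 500 pairs at 50–400 nt.

Every CLI output directory contains one `run_manifest.json` (version,
parameters, input SHA-256 digests, seed, timestamp). The manifest timestamp
is the only non-deterministic byte any command writes; all reports and tables
are byte-identical across reruns with the same seed, which the end-to-end
test asserts by hashing everything except the manifest.

## Known limitations

* The blank-share statistic assumes blanks and specimens were processed
  comparably; it has no model of frequency–DNA-concentration relationships
  and cannot detect contaminants absent from every blank.
* The aligner's seeding can miss homologs sharing no exact 8-mer on either
  strand; lower `k` for diverged references.
* QC thresholds (`cv_max`, depth-ratio bounds) quantify a judgment call;
  they are configurable and their defaults are conventions, not estimates.
* MAG identification from GFF3 input assumes contig ids of the form
  `<mag>_<suffix>` in the CLI; library users can build `MagRecord`s with any
  naming.
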