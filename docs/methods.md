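# Methods

## The model

`mirconcord` infers candidate regulatory relationships from expression
concordance, not from sequence. The underlying assumption is the canonical
miRNA mechanism: a mature microRNA loaded into RISC represses its mRNA
targets, so a *functional* interaction between conditions A and B should
show the miRNA and its target moving in opposite directions. The pipeline
therefore intersects three evidence layers:

1. per-study differential expression of microRNAs and protein-coding genes
   (log2 fold-changes with multiplicity-adjusted p-values), consumed as
   tables — DE estimation itself (alignment, dispersion modelling) is out
   of scope;
2. a database of *experimentally validated* miRNA→target edges in a
   mirTarBase-style TSV dialect, treated as a fixed edge set with evidence
   tags passed through as metadata;
3. optionally, metabolite fold-changes plus a gene↔metabolite adjacency
   map (substrate / product / transported).

Expression concordance cannot prove causation; the output is a ranked,
reproducible candidate set, not a validated regulatory network.

### Sign convention

All stored log2 fold-changes are first-condition-over-second (naive over
primed, diapause over reactivated). Sources reporting the opposite ratio
are negated at ingest (`DeTableSchema.sign_convention`). A log2FC recorded
as exactly 0 is a *not-observed* sentinel — public per-study tables pad
absent microRNAs with 0.00 — and never contributes to any consistency
rule. A true effect of exactly zero is indistinguishable from absence at
table level; this loses nothing in practice because a zero effect could
never pass a fold threshold anyway.

### Identifier canonicalization

MicroRNA names are parsed into (species prefix, stem, locus suffix, mature
arm). Joins across studies and species use the **mature key** — stem plus
arm, with the species prefix and duplicate-locus suffix dropped — because
duplicate loci (`let-7f-1`, `let-7f-2`) produce the same mature product.
Gene matching across species uses case-folded symbol equality (human
`ATP13A2` ↔ mouse `Atp13a2`); an explicit ortholog table can replace this
upstream where symbol conventions diverge.

### Consistency rules

**Arm-combining mouse consensus** (`call_mouse_consensus`). Because some
profiling studies did not resolve mature arms, evidence is pooled per
hairpin stem across a study panel. With fold threshold *T* (default 1.5,
compared inclusively: |log2FC| ≥ log2 *T*) and `min_studies` = 2, a stem
is consistent if the -3p arm passes with one sign in ≥ 2 studies (c1), the
-5p arm does (c2), or the two arms pass with the same sign in two
*different* studies (c3). Criteria are evaluated in the order c1, c2, c3
and only label the call; they never change membership. Arm-unspecified
(hairpin-level) records back both arms of a study only when that study has
no arm-resolved record for the stem, and such fills are flagged.

Two degenerate situations are resolved explicitly, as neither follows from
the criteria themselves: (a) a stem whose two arms pass in the *same*
study with opposite signs is excluded and reported as conflicted; (b) when
both directions qualify across studies, the direction with more supporting
studies wins and ties are excluded — agreement is required only among the
supporting studies, so a single strong opposite-direction study does not
veto a two-study consensus. Consequence worth knowing: exclusion (a) is
threshold-sensitive, so the call set is guaranteed monotone in *T* only
for stems whose observed values share one sign.

**Consistent-dataset counting** (`count_consistent_datasets`). The two
human comparisons form one dataset: consistent iff both have padj < α
(default 0.05, strict) and share a sign, which defines the reference
direction. Each mouse study counts iff its value is nonzero, |log2FC| ≥
log2 *T*, and the sign matches the reference. The inclusive bar matters at
the boundary: fold 1.516 (log2FC 0.60) counts, fold 1.4 (0.48) does not.
If the two human comparisons disagree in sign there is no reference
direction; the count is returned flagged ambiguous with only the
per-dataset verdicts that remain computable.

**Cross-species consensus** (`cross_species_consensus`). A mature key is
emitted when it is significant (padj < α) with one sign in *every* human
comparison supplied and clears the fold bar with that sign in at least one
mouse study. Mouse hairpin-level records can support any arm of their stem.

### Networks, triplets, enrichment

`gate_consistent_genes` / `gate_consistent_mirnas` keep features
significant in every supplied study with one shared sign, carrying the
mean log2FC and the worst padj forward. `find_consistent_connections`
keeps each validated edge whose gated endpoints have strictly opposite
signs; features observed with conflicting signs across records are
dropped. Output is sorted (miRNA, gene) and deduplicated on the mature-key
/ symbol pair, so two locus copies of one mature miRNA yield one edge.

Tri-omics triplets require a significant gene, ≥ 1 opposing significant
miRNA (via the connections), and ≥ 1 adjacent significant metabolite. The
metabolite's direction relative to the gene is annotated but *not*
filtered: a transporter's substrate and an enzyme's product can
legitimately move in either direction relative to the gene.

Enrichment is the classic per-term upper-tail hypergeometric test with BH
correction, with one deliberate twist: the background is the DE gene set,
not the genome, so the test asks whether miRNA-targeted DE genes
concentrate in a process beyond what differential expression alone
explains. No ontology graph is shipped or propagated — the term map is a
flat TSV — so graph-aware decorrelation methods are out of scope.

### The 40th-percentile count prefilter

`filter_low_expression` drops genes whose total read count across samples
falls below the q-th quantile (default 0.4) of all per-gene totals. The
quantile uses linear interpolation between order statistics (numpy's
default convention) and the survival comparison is inclusive (total ≥
cutoff).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| α (`alpha`) | 0.05 | significance bar on adjusted p-values, strict `<` |
| fold threshold (`fc_threshold`) | 1.5 | fold bar, applied as \|log2FC\| ≥ log2 1.5 ≈ 0.585, inclusive |
| `min_studies` | 2 | studies required for the single-arm consensus criteria |
| `min_term_size` | 3 | smallest background term tested; tinier terms only inflate multiplicity |
| `quantile_q` | 0.4 | count prefilter quantile |

## The synthetic generator

`generate_bundle` emulates the *statistical* structure of a multi-study
integration: two human miRNA comparisons, three mouse miRNA studies, two
gene studies, a validated-edge table, and a metabolite layer. Defaults
(80 miRNA stems, 300 genes, 30 metabolites, 20% consistent stems, effect
2.0 log2 units over null noise of sd 0.1, target degree ~Poisson(4), 60%
of consistent stems mirrored into the second species) are scaled-down
analogues of real panel sizes, chosen so that every rule has work to do at
run times of well under a second.

Planted stems draw one of four arm patterns (3p-only, 5p-only, both,
cross-arm) with all patterns at nonzero probability, guaranteeing coverage
of criteria c1–c3. Adjusted p-values come from a monotone map of the
standardized effect, padj = 2·Φ̄(|log2FC| / (4·sd_null)) — under this map
planted effects are overwhelmingly significant and null features
essentially never are, which makes exact-recovery statements crisp.
Each planted (human-mirrored) regulator owns a pool of target genes
disjoint from every other regulator's pool and from the DE null genes;
each such gene takes the opposite sign with probability *f* (the
anti-correlation fidelity) and a random sign otherwise. Ground-truth
connections are *all* planted edges, so expected recall is
f + (1−f)/2 ≈ 0.9 at f = 0.8 while precision stays exactly 1.

What the generator deliberately does **not** model: count-level noise and
dispersion (no DESeq-style refitting — the pipeline consumes DE tables),
correlated significance across features, batch effects, shared targets
between planted regulators, and miRNA families with overlapping target
repertoires. Passing recovery tests therefore demonstrates correctness of
the integration logic under clean planted signal, not robustness to the
messier error structure of real studies.

## Numerical and interface conventions

- Floats round-trip bit-for-bit through the TSV writers (`repr`
  serialization); written bundles are byte-identical given (config, seed).
- All randomness flows through one `numpy.random.default_rng(seed)`.
- Deterministic output orders everywhere: connections sort by (miRNA,
  gene), enrichment by (p, term id), consensus by stem.
- Readers skip malformed rows, counting them with line numbers in a load
  report; a missing mapped column is a configuration error, not a skip.
- Duplicate (stem, study, arm) observations with conflicting values raise;
  identical duplicates merge silently.

## Known limitations

- Symbol-equality ortholog matching fails for genes whose human/mouse
  symbols differ beyond case; supply an explicit ortholog map upstream.
- Evidence tiers in the target database are pass-through metadata; no
  weighting by assay strength is attempted.
- Headline network sizes from any particular published integration depend
  on the exact DE lists and target-database version used as inputs;
  identical rule settings on different inputs legitimately produce
  different counts, so the package reports whatever its inputs yield.
- The consensus direction tie-breaks (conflict exclusion, larger-support
  wins) are this package's conventions for cases the written criteria
  leave open; both are surfaced in the outputs (`conflicted_stems`).
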