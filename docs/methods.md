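# Methods

## Data model and normalisation

A dataset is a list of `SampleRun`s — one immunopeptidomics replicate
each — holding unique peptide sequences with their source protein
accessions, optional intensities, the sample's MHC haplotype and a tissue
label (`tumor`, `benign`, `cell_line`). Records are assumed to come from
a search already filtered at the peptide level (e.g. 1 % FDR); `ipqc`
does no spectral work. Normalisation strips parenthesised PTM annotations
(`M(+15.99)` → `M`) and lowercase flanking notation, uppercases, and
rejects any sequence left with residues outside the 20 canonical amino
acids. Duplicate sequences within a run are collapsed to one record with
the maximum intensity and the union of source accessions, so that all
counting is over unique peptides. Allele names are canonicalised across
the common dialects (`HLA-A*02:01`, `HLA-A02:01`, `A*02:01`, `A02:01` →
`A02:01`; `H-2Kd` → `H2-Kd`); normalisation is idempotent.

## Binding model and rank calibration

The built-in predictor is a per-allele, per-length position-specific
scoring matrix. From `N` training binders with per-position residue
counts `c[i,a]`, background frequencies `b[a]` and pseudocount `κ`:

```
M[i,a] = log( (c[i,a] + κ·b[a]) / (N + κ) / b[a] )
```

A peptide's score is the sum of its per-position entries. Supported
lengths are 8–13; the background defaults to uniform 1/20 (a
proteome-derived estimate is available) because no canonical choice is
imposed by the problem. The pseudocount defaults to 1.

Raw PSSM scores are not comparable across alleles, so each (allele,
length) is calibrated against `n_background` random background peptides
(default 100 000; the test and acceptance workloads use 10 000–20 000 to
stay fast). The rank percentile of a query is

```
rank = 100 · #{background scores ≥ score} / n_background
```

which reproduces the "% rank" convention of mainstream MHC predictors and
makes the best (lowest-rank) allele well defined per peptide; ties break
to the alphabetically first allele. Classes are strong binder
(rank < 0.5), weak binder (0.5 ≤ rank ≤ 2) and non-binder (rank > 2). A
peptide whose length no haplotype allele covers is returned unassignable
(allele `none`, class nB). The calibration is reproducible from its
(seed, size) pair, which is what gets serialized; samples are regenerated
on load.

The *binder fraction* of a run counts classes SB + WB, i.e. rank ≤ 2.
The rank of a score is defined on the score scale (not on a derived
affinity), which is documented here because the two conventions differ in
principle though not in ordering.

A surrogate affinity is defined from the score quantile `s` (fraction of
background scores strictly below) as `affinity = 50000^(1−s)` nM — the
classical monotone mapping between a (0, 1] binding signal and the
nanomolar scale. It exists so affinity-threshold criteria ("below
50 nM", i.e. `s ≥ 1 − log 50 / log 50000 ≈ 0.639`) are expressible with
the built-in scorer; an external backend's native nM values take
precedence when one is configured. External predictors implement the
`PredictorBackend` protocol (best-call and per-allele tables); no
external tool is required anywhere in the package or its tests.

## Contaminant filtering

The coverage ratio of protein `P` in a run is `Σ L(p) / L(P)` over the
distinct eluted peptides `p` mapping to `P`; peptides mapping to several
proteins contribute to each, and each peptide counts once regardless of
intensity or charge state. Proteolytic contamination produces nested,
offset-shifted fragment series ("ladders") whose summed length far
exceeds what genuine MHC presentation yields, so contaminated proteins
sit in the extreme upper tail of the ratio distribution.

The flag cutoff is data driven: each known-clean reference run (at least
20 covered proteins, otherwise excluded with a warning) contributes the
95th percentile of its own ratio distribution, computed with
linear-interpolation (type-7) quantiles — the most common default, and
recorded in the calibration output since the choice is conventional — and
the cutoff is the arithmetic mean of those percentiles. Proteins with
ratio strictly above the cutoff are flagged. A peptide is removed only if
*every* source protein is flagged: the conservative rule, chosen because
deleting a shared peptide that a plausible unflagged source could explain
would discard genuine ligands. Accessions absent from the protein
database cannot be flagged and therefore protect their peptides. Cleaning
is idempotent by construction. All runs and references must share one
protein database per calibration.

## Cross-sample comparison

Pairwise overlap between peptide sets defaults to the
Szymkiewicz–Simpson coefficient, `100·|A∩B|/min(|A|,|B|)`: it is
symmetric (required for clustering) and insensitive to the large
run-size differences typical of immunopeptidomics. A per-row
normalisation (`/|A|`) is retained for asymmetric questions but is
rejected by the clustering entry point. The 40 % display cap is applied
only to rendered copies — every computation uses raw percentages.
Clustering is agglomerative (average linkage by default) on distance
`100 − overlap`, via `scipy.cluster.hierarchy`; exactly equal merge
distances are resolved by scipy's deterministic internal order. The
merge tree exports as Newick.

Haplotype encoding builds a sample × allele binary matrix. Four-digit
human alleles reduce to their two-digit group (`A02:01` → `A02`) only
when every aggregated allele carries the same peptide-binding-motif label
in a user-supplied map; with no map the reduction is unconditional and a
warning is emitted, since two-digit groups usually — but not always —
share a motif. Columns present in fewer than two samples are dropped
(singletons carry no clustering information). Haplotype clustering uses
Hamming distance with average linkage: the simplest defensible metric on
one-hot vectors.

Known-ligand annotation is exact sequence matching against plain-text
reference lists, by default restricted to 9mers (the convention for
literature comparisons); no MHC-restriction matching is attempted.

## Proteome scan and abundance statistics

`scan_9mers` enumerates all stride-1 9-residue windows of the chosen
proteins — `max(0, L − 8)` windows per protein, duplicates merged with
unioned sources — and predicts each across the haplotype. The
predicted-vs-observed summary counts predicted strong binders with
rank ≤ 0.5; note the inclusive bound, which differs from the strict SB
class boundary, and both conventions are kept deliberately.

Presentation-vs-abundance association uses a two-sided Mann–Whitney test
comparing the abundance of presented vs non-presented proteins (at least
10 per group), plus Spearman correlations of per-peptide mean intensity,
and of best rank, against the number of replicates in which the peptide
was observed. A distribution-free test is the defensible default for
abundance values of unknown scale. These are single planned comparisons;
no multiplicity correction is applied. Degenerate constant vectors yield
NaN correlations rather than errors.

## Candidate selection

Filters, applied in any order (they commute; the order only affects the
logged survivor counts): source-gene log fold change strictly greater
than 2, predicted affinity strictly below 50 nM, and presence in at
least 3 replicates. Strictness follows the wording of each criterion.
Peptides without a prediction, or without a mapped and measured gene when
upregulation is required, are excluded and counted. Multi-gene peptides
use the maximum log fold change among their genes (sensitivity-favouring
at the shortlist stage). Survivors are ordered by a deterministic total
key — prioritized-tissue evidence, preferred length (9), ascending
affinity, descending replicate count, sequence — replacing any manual
curation step with a reproducible convention, then truncated to `top_k`
(default 15). Poly-K export prepends `k` lysines (default 6); peptides
that already start with K are flagged because stripping the tail would
not recover them unambiguously.

## Synthetic data: what it emulates and what it does not

The generator is the package's test bed and defines its study
conditions. Defaults: a 200-protein random proteome (150–500 residues,
i.i.d. background residues); runs of 1000 unique peptides of which 15 %
are fully random noise and the rest split equally between two synthetic
alleles; motif peptide lengths peaked at nine residues (8: 8 %, 9: 55 %,
10: 12 %, 11: 10 %, 12: 8 %, 13: 7 %) with noise lengths uniform over
8–13; log-normal intensities (log-mean 10, log-sd 1). Each allele has
single-residue anchors at position 2 and the C-terminus — the canonical
MHC-I anchor layout — drawn independently per position with
concentration 0.99, background elsewhere. The near-obligatory anchor
choice is deliberate: these are idealized discriminating alleles, so that
essentially every motif peptide is a predicted binder of its generating
allele and ground-truth recovery rates measure the pipeline rather than
motif strength. The default pair (`A02:01`-like L/V, `B07:02`-like P/L)
has disjoint anchor residues at each position, which is what makes
deconvolution accuracy a meaningful recovery metric.

Ladder injection adds `n_fragments` (default 20) windows of one protein
at consecutive offsets, fragment length 15 by default since proteolytic
contaminants skew long. Expression tables draw an upregulated fraction
from a high log-fold-change range and the rest from a low range, the two
ranges disjoint across the threshold, so the pass set is known exactly.
The planted-candidate cohort builds 15 peptides satisfying every default
selection criterion and distractor classes violating exactly one each.

Every generator is a pure function of (configuration, seed); derived
seeds come from a seed sequence so replicates are independent but
reproducible. What the synthetic data does *not* model: real motif
degeneracy (multiple tolerated anchor residues, auxiliary positions),
peptide processing and transport biases, intensity physics
(retention-time, ionisation), shared peptides between biologically
related samples, and real proteome composition. Passing tests therefore
demonstrate correctness of the statistics and decision rules under known
ground truth — not predictor accuracy on real ligandomes, for which an
external predictor backend should be used.

## Numerical and scale choices

Quantiles use linear interpolation throughout. Rank ties at class
boundaries follow the stated inequalities (SB strictly below 0.5; WB
inclusive at both 0.5 and 2). Empty scopes (no 9mers, empty reference
set, no strong binders) return NaN "missing" values rather than raising.
Test and acceptance workloads use 10 000-peptide rank calibrations,
1000-peptide runs, 100 ladder-injection trials and 1000 null
simulations — sizes chosen so the whole battery runs in seconds while
keeping binomial noise well inside the asserted tolerances. The
acceptance script derives every random stream from its `--seed` argument
and computes all reported quantities at run time.

## Known limitations

- The PSSM treats positions independently; it cannot represent pairwise
  residue couplings, and its surrogate affinity is a calibrated monotone
  transform, not a physical nM measurement.
- The coverage-ratio filter flags whole proteins; a protein that is both
  a genuine presentation source and a contamination source is handled by
  the shared-peptide rule but cannot be split.
- Haplotype encoding trusts the user's motif-group map; unconditional
  two-digit aggregation can merge alleles with different motifs.
- Exact sequence matching for known-ligand annotation ignores I/L
  ambiguity from mass spectrometry.
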