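# Methods

## Model and procedure

`kmertyper` types diploid genotypes of a polymorphic gene family from
paired-end RNA-seq by four k-mer stages; no gapped alignment, phasing or
assembly is involved.

**Taxonomy and classification (k = 31).** The classification tree encodes
the nomenclature itself: a root with two branches, the gene family and a
"distractome" of all other transcripts; the family splits into class I /
class II / other branches (a configured gene→class map, default bucket
*other*), then gene nodes, then one node per precision field actually
present, down to allele leaves. Identical allele sequences are merged
first (representative = lexicographically smallest name; all members
reported in every output that includes the record). The database maps each
31-mer of each leaf sequence — both strands, no canonicalization — to the
LCA of the leaves containing it. A read pair is classified by counting
database hits over the 31-mers of both mates (read 1 reverse complemented,
matching the stranded simulation; an unstranded mode queries both
orientations), scoring every root-to-leaf path by the summed hit counts of
its nodes, and returning the LCA of all leaves attaining the maximal
score. This single rule covers both the generic case (hits on one chain →
deepest hit node, or its unique descendant leaf) and ties across genes
(LCA = class or family branch). Classifications below gene rank are lifted
to the gene; bins above gene rank are kept only as diagnostics and do not
feed profiles. Implementation note: only hit nodes need scoring, because
the path score of any leaf equals the chain score of its deepest hit
ancestor, and maximal hit nodes are never ancestors of one another; the
test suite checks exact agreement with a brute-force all-paths oracle.

**Profiles (k = 50).** Reference profiles are 50-mer counts over simulated
stranded pairs per allele (error-free), restricted to the reads the
classifier bins back to the allele's own gene — exactly the filter sample
reads will pass through. Sample profiles count the gene-binned reads and
drop k-mers with count ≤ 1 (`min_count_threshold`, default 1); a
depth-relative mode (`threshold = max(min, ceil(alpha·mean depth))`,
alpha default 0) exists but is off by default because only the singleton
rule is well determined.

**Candidate selection.** Alleles are ranked by the fraction of their
profile mass observed in the sample; the top n (default 100) are
semifinalists, with boundary ties extending n until the next score is
strictly smaller. All unordered semifinalist pairs — homozygous pairs
included — are scored with
`Error = (1−PropProf) + (1−PropReads) + (1−Cor)`; the pair profile is the
key-wise sum of the two allele profiles. *Cor* is the Pearson correlation
of natural-log counts over the intersection of pair and (filtered) sample
k-mer sets; intersections smaller than two, or zero-variance vectors,
yield the neutral value 0. Ranking ties break lexicographically on the
rendered pair name. The m lowest-Error pairs (default 20) become
finalists.

**Competitive alignment.** For each read pair and ordered finalist pair
(i, j), if each mate is an exact substring of at least one allele of pair
i and the pair-level match fails for j, cell (i, j) gains the quality
weight S of the read's lowest base quality (0 below Q_min = 20, 1 at or
above Q35, linear between). Every off-diagonal cell then gains
`total_matching_reads / 10,000`, where a "matching read" is a read pair
matching at least one finalist; the diagonal is excluded from the
adjustment and from all row/column sums (the only reading consistent with
a total per-row adjustment of 3.75 in a four-pair matrix). Finalists are
ranked by `Score(i) = (row/col)^P · 1/Error(i)` with P = 0.25; a 0/0 ratio
is taken as 1, and Error is floored at 1e−6 so perfect profile matches
rank first instead of dividing by zero.

**Refinement.** Reads are remapped to the called pair allowing one
mismatch per mate (best placement, leftmost on ties); each mate is
assigned to the allele it matches better, ties contributing half weight to
both — support is kept per allele rather than pooled so homozygous and
heterozygous signals stay distinct. A position is substituted iff the top
non-reference base exceeds 75% of coverage *and* beats the reference
support (conjunctive). Substitutions only: the pileup lives in the fixed
reference coordinate system, so indels and splice variants are out of
scope. A corrected sequence containing a same-gene partial reference
allele as an exact substring renames the call to that allele with suffix
`U` (longest match wins; all matches reported); otherwise the base allele
gains suffix `N`. With refinement mode `recalculate`/`all`, a profile is
simulated for the corrected sequence (the binning step is skipped — all
reads come from the one sequence) and the pair Error recomputed; mode
`all` re-ranks all finalists with the corrected sequence substituted.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k_filter` | 31 | classifier k-mer length |
| `k_profile` | 50 | profile k-mer length (≤ read length, else hard error) |
| `n_semifinalists` | 100 | profile-fraction cut, tie-extended |
| `m_finalists` | 20 | Error cut before competitive alignment |
| `q_min` | 20 | quality weight threshold (phred) |
| `power` (P) | 0.25 | exponent on the row/col ratio |
| `min_count_threshold` | 1 | sample k-mers at or below are dropped |
| `min_gene_reads` | 1000 | genes with fewer filtered reads are reported uncallable rather than guessed |
| Pareto `scale/shape/max_insert` | 80 / 0.7 / 1000 | fragment-length model (bp) |
| `num_reads` | 500,000 | simulated pairs per allele for full-scale reference profiles |
| `read_length` | 50 bp | simulated read length |
| `error_rate` | 0 (reference) / 0.001 (evaluation) | per-base substitution probability; qualities constant Q30 |

`threads` is accepted for interface compatibility; execution is serial at
the scales this package targets.

## Synthetic worlds and problem sizes

The fixture generator emulates the structure of the family, not any real
database: a root sequence diverges into gene ancestors (8%/base), allele
groups (2%), proteins (0.8%) and synonymous variants (0.2%, each child at
least one substitution so names stay distinct); partial alleles ship
pseudo-exons 2–3 of six equal slices (the historical peptide-binding-exon
submissions) with the full sequence retained as truth; novel alleles are
held out of the emitted FASTA entirely. Samples draw diploid genotypes
from complete-status alleles (evaluation sets are assembled from fully
known sequences), split reads 50/50 between haplotypes by per-read
Bernoulli draws, and add distractome background to 20% of reads — a
stand-in for the over-representation device that keeps family reads
abundant in a transcriptome mix.

Desk-scale sizes, chosen for per-position 50-mer depth: default world 5
genes × 20 alleles × 1 kb; reference builds simulate 3,000 pairs/allele
(the full-scale default of 500,000 is impractical and unnecessary at 1 kb);
evaluation samples use 6,000 pairs/gene (≈6× per 50-mer position per
haplotype, so the singleton filter removes error k-mers but almost no real
ones; the filtered-read counts are inside the range reported for real
transcriptomes). What the generator does *not* model: expression imbalance
between alleles, tissue-dependent gene expression, coverage non-uniformity
from RNA degradation, quality ramps, indels, and real cross-family
homology structure — so passing tests demonstrate algorithmic correctness
under the stated read model, not robustness to every artifact of
biological data.

## Numerical choices and edge cases

- Truncation of the Pareto at `max_insert` is by rejection; draws below
  the read length are clamped up; sequences shorter than the maximum
  insert simply bound the rejection at their length, and sequences at or
  below the Pareto scale degenerate to a fixed fragment.
- Non-ACGT characters are kept in sequences; any k-mer window spanning one
  is skipped at classification, profiling and refinement.
- Mates shorter than k contribute no k-mers; reads with no ≤1-mismatch
  placement contribute no pileup.
- All ranking ties (semifinalists, finalists, final score) break on
  rendered names, making reports byte-reproducible for a fixed seed; all
  randomness flows through seeded numpy generators (one spawned stream per
  allele during reference builds).

## Known limitations

- Homozygous truth pairs earn no unique competitive-alignment reads (every
  finalist contains the shared allele), so their ranking rests on 1/Error
  alone; at desk-scale depth the log-count correlation is noisy, and a
  handful of error reads that coincidentally convert to a nearby allele
  can promote a heterozygous call. This costs occasional third-field or,
  rarely, second-field precision on homozygotes in scaled-down runs — at
  full reference depth the correlation term is far more discriminating.
- A partial allele whose stored fragment matches the sample region can tie
  the true pair's Error when the rest of its sequence is unknown; such
  confusions are resolved at two-field precision and by refinement, not at
  the exact level.
- The refinement coordinate system cannot express indels; an allele
  differing from its nearest relative by an insertion will be reported as
  novel with an imperfect sequence.
- The distractome here is synthetic and homology-free; real transcriptome
  distractomes shrink the classifier's unique k-mer sets and can only be
  assessed with real references.
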