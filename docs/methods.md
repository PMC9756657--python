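# Methods

This note documents the models and procedures implemented in `intropipe`,
the assumptions behind them, the defaults and why they were chosen, what
the synthetic-data generator does and does not emulate, and the design
choices made where the design was genuinely open.

## Split-read detection of introgressed blocks

A long read sampled across the boundary of an introgressed block aligns
fully to the focal assembly (which contains the boundary) but cannot align
contiguously to either donor: the part left of the boundary matches the
*niloticus*-like donor (donorA) and the part right of it the
*mossambicus*-like donor (donorB). The detector therefore looks for reads
that are (i) fully aligned to the focal assembly, (ii) have at least one
alignment to each donor, and (iii) have donorA and donorB alignments that
are pairwise disjoint in read coordinates.

Parameters and defaults:

- `trim_bp = 10000` — alignments not fully inside
  `[trim_bp, scaffold_len − trim_bp)` are discarded on all three
  references, suppressing false splits where a read merely runs off the
  end of one reference scaffold and onto another. Applying the trim to all
  three references (rather than only the focal one) is a choice; it is
  configurable.
- `min_focal_fraction = 0.95` — "fully aligned" is quantified as focal
  records covering ≥ 95% of the read; the underlying procedure never
  defined the term numerically, so it is exposed as a parameter.
- `min_donor_len = 200` bp — donor fragments shorter than this are noise
  at the divergences involved and are ignored.
- No mapping-quality floor is applied by default; a `mapq` field is carried
  on every record for callers that want one.
- Coverage is counted as **distinct supporting reads per 1 kb bin**, not
  per-base depth, because the procedure downstream intersects read-name
  sets between references. Maximal runs of adjacent bins holding ≥ 1 split
  read are *candidate* intervals; those with ≥ 10 supporting reads outside
  LG0 are *reported* (the candidate/reported split mirrors the two-stage
  funnel of the original procedure, whose merge threshold of 30 reads per
  bin — roughly the mean coverage — is retained as a high-coverage flag,
  `min_count`).
- Partner intervals on each donor are chosen by the largest read-name
  intersection with the focal interval; ties break by coordinate, first
  wins (the tie rule is logged, not silent).

Monotonicity holds by construction: raising `trim_bp`, `min_count` or the
reporting threshold can only shrink the reported set.

## Topology weighting ("complete" enumeration)

For k taxon groups there are (2k−5)!! distinct unrooted bifurcating
topologies on the group names — 15 for the five groups used here.
`enumerate_topologies` builds them by recursive edge insertion and
canonicalizes each as its set of non-trivial splits. For a window tree with
several tips per group, `weight_window` iterates over *every* combination
of one tip per group, restricts the tree's splits to the chosen tips, and
matches the induced unrooted topology; weights are accumulated as exact
rationals (so tests can demand exact agreement with a brute-force oracle).

Combinations whose induced topology is unresolved (a polytomy survives
pruning) split their unit of weight equally among the compatible
topologies; a `discard` policy is available. Window trees are treated as
unrooted throughout; the outgroup is only used to root display newicks.

Window trees come from neighbor joining (scikit-bio) on mean absolute
genotype-code differences in sliding 200 bp windows with 40 bp overlap.
Windows with no variant site are skipped; a sample with no called site in
a window is dropped for that window.

Smoothing is lowess — locally linear regression with the tricube kernel —
with span given as the fraction of each seqid's windows (default 0.05),
evaluated at window midpoints. **Region extraction operates on the raw
weights**: the extraction threshold of 1.0 is attainable only before
smoothing, so the smoothed series exists for reporting and plots only.

Known limitation: 200 bp windows carry few variant sites. With fewer than
about 10 variable sites per window the NJ topology becomes noisy, the
weight-1.0 criterion fragments inside true donor blocks, and isolated
false-positive windows appear outside them. The bundled analyses use ~16
variable sites per window, a density typical of cross-species cichlid
alignments; recovery of planted blocks (Jaccard) degrades below that.

## Admixture statistics

Site filters (defaults, applied jointly): biallelic SNPs only; total depth
in [90, 900]; minor allele count ≥ 3; at most 1 individual missing; more
than 3 bp from any indel's REF span; LG3 (repeat-rich) excluded.
Per-criterion removal counts are logged. LD pruning (drop a site whose
genotype r² with any retained site within 20 kb exceeds 0.6, greedy
left-to-right) is implemented for preparing a species-tree input; the D /
f4 / f-branch statistics themselves run on the filtered, unpruned sites.
Between-species fixed differences are in near-perfect LD, so pruning
removes most sites by design — another reason not to feed the pruned set to
the frequency-based statistics.

Alleles are polarized per site by the outgroup's major allele; sites where
the outgroup ties at 0.5 cannot be polarized and are dropped (counted in
the log). D uses the frequency form of the ABBA/BABA sums; its standard
error comes from a delete-one jackknife over 20 contiguous equal-site
blocks (the block count is a convention, not derived from an LD scale), and
|Z| > 3 is the conventional significance line. The f4-admixture ratio uses
the donor frequency in both denominator slots (the "f_hom" form): with one
to a few samples per population, per-site donor subsampling halves are too
noisy to be useful, and the within-donor form is the standard fallback. The
reported value is clipped to [0, 1]; the raw value is logged.

f-branch: for every branch b of the rooted species tree and every taxon C
neither below b nor below b's parent, f_b(C) is the median over A in the
sister clade of the minimum over B below b of f_G(A, B, C), negatives
clipped to zero, undefined cells left absent. The maximum entry localizes
the dominant gene-flow event.

## The synthetic-data generator

The generator defines the study conditions; its defaults are a 1 Mb,
2-scaffold focal genome, donors each 2% diverged from their common
ancestor, admixture proportion f = 0.1 in exponentially distributed blocks
of mean 50 kb, 30× error-free reads of mean 15 kb (sd 10%), 20 000
genotype sites, two diploids per population, and a 22-LG map fixture with
4 scaffolds per LG, 8 probes per scaffold and 10% injected chimeras.

- **Genomes**: Jukes–Cantor-like independent substitutions, no indels (the
  3 bp indel-proximity filter is exercised with constructed VCFs instead).
  The focal genome is donorA's copy with planted blocks replaced by the
  homologous donorB sequence; block lengths are exponential, placement
  uniform without overlap, and the total is truncated to exactly
  f × genome length. Blocks keep a margin of (read length + 10 kb) from
  scaffold ends so that every planted boundary is detectable in principle
  by the read-based detector — real introgression has no such margin, so
  boundary recall on real data is bounded by scaffold-end losses.
- **Reads and alignments**: reads are error-free (HiFi ≥ Q20 justifies
  this) and forward-strand; names encode the true origin. Alignments are
  emitted exactly from the truth: a full-length focal record plus donor
  records per ancestry segment, so reads spanning a boundary are split and
  disjoint by construction. No mapper runs; mapping ambiguity in repeats —
  a real confounder the original procedure acknowledges — is therefore
  *not* emulated, and passing tests say nothing about repeat-induced false
  splits.
- **Genotypes**: each site gets an independent genealogy from a small
  structured coalescent on the fixed species tree
  ((((focal,niloticus),aureus),mossambicus),urolepis) with speciation
  depths 1, 2, 3, 4 coalescent units; one derived mutation is placed with
  probability proportional to branch length. `ils_rate` maps to the
  coalescence rate in ancestral populations so that the focal/niloticus
  pair resolves discordantly with approximately that probability
  (`rate = −ln(1.5·ils_rate)`, instantaneous coalescence at 0). At sites
  inside planted blocks the focal lineages migrate into the mossambicus
  population at a recent time (0.05 units), which makes the f4-ratio
  recover f and lets f-branch localize the flow — the estimators' own
  consistency conditions. Sites are independent: no recombination, hence
  no realistic LD decay (inter-species LD is still realistic: fixed
  differences repeat patterns). Per-site depths are Poisson; no missing
  calls are generated by default. The engine is numba-compiled (~1 µs per
  site), which is what makes the 100-seed null calibration cheap.
- **Map fixture**: probe cM increases with bp on '+' scaffolds and
  decreases on '−' ones at 1 cM / 20 kb, exactly (no map noise), so clean
  LGs rebuild with Marey monotonicity 1.0; chimeras concatenate two
  scaffolds from different LGs and record the join.

Determinism: all outputs are byte-identical for identical (params, seed);
sub-stages derive independent child seeds from the master seed.

## Anchoring

Chimera candidates are scaffolds whose (best-hit-deduplicated) probes span
two or more LGs. Their per-LG probe bp ranges must be disjoint; the cut is
the **midpoint** between the last probe of one block and the first of the
next. The underlying description ("break at the most distally mapped
probes") does not fix the cut base; midpoint is the symmetric choice and
cut-at-probe variants are a parameter away. Scaffolds with overlapping LG
blocks are left unbroken and reported unresolvable. Ordering uses the
median probe cM (robust to stray hits), ties break by name; orientation is
the sign of the Spearman correlation of bp vs cM, with single-probe
scaffolds set '+' and flagged unknown. Builds concatenate with exactly 100
N between neighbours and emit AGP 2.1 rows that reconstruct the FASTA
exactly. The Marey monotonicity score is the fraction of adjacent probe
pairs (by position on the built LG) whose cM does not decrease.

## Numerical and testing choices

Internal coordinates are 0-based half-open everywhere; GFF3 and VCF are
converted at the I/O boundary. Weight vectors are exact rationals until
exposed as floats; the extraction threshold comparison uses a 1e-9
tolerance. Problem sizes in the test suite (1 Mb genomes at 30×, 20 000 to
50 000 sites, 10–100 seeds per calibration, 50 kb weighting region) were
chosen as the smallest instances at which the statistical claims are
stable, so the full suite runs in about a minute.
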