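# Methods

## Model and procedure

The pipeline infers ceRNA (competing endogenous RNA) pairs from
CLIP-supported miRNA target sites in five stages.

**1. Family collapsing.** Mature miRNAs sharing positions 2–8 (the seed
plus position 8) are collapsed into families; the family is the counting
unit everywhere downstream, so paralogous miRNAs with identical targeting
potential are never counted twice. Catalog entries without a family
assignment become singleton families rather than being dropped.

**2. Target-site discovery.** The built-in scanner reports canonical
seed-match sites on transcript sequences (sense strand, DNA): every
occurrence of the reverse complement of seed positions 2–7 is classified
as 8mer, 7mer-m8, 7mer-A1 or 6mer by the presence of the position-8 match
immediately 5' and an adenosine opposite miRNA position 1 immediately 3'.
Each core occurrence yields exactly one site at its highest attainable
class, so nested matches are not double counted. 6mer sites are disabled
by default, mirroring strict seed-pairing stringency; site coordinates
are transcript-space, 0-based half-open. Hybridisation-energy scoring
(miRanda-style alignment, PITA ΔΔG, mirSVR) is deliberately out of scope:
external program predictions can be ingested from TSV instead, and the
program tag is preserved per site. Sites of one family on one gene whose
intervals overlap by ≥1 bp are merged transitively; the merged site
carries the union of program tags, which is what "predicted by at least
*k* programs" is evaluated against.

**3. CLIP support.** Sites are intersected with binding-site clusters
from a panel of CLIP-seq experiments (BED6, 0-based half-open). Overlap
requires ≥1 bp (configurable) on the same strand ("." is a wildcard;
Argonaute binds the transcribed strand). Support is counted per distinct
experiment, not per cluster. The stringency filter keeps sites with
`supporting_experiments ≥ min_experiments` (default 1 — the definition of
"CLIP-supported") and `program_count ≥ min_programs` (default 1; the
built-in scanner counts as one program).

**4. ceRNA test.** Each gene's profile is the *set* of families with at
least one surviving site (site multiplicity discarded). For a pair with
K and n families, sharing c, in a universe of N families, the p-value is
the hypergeometric upper tail P(X ≥ c). N is the number of families in
the catalog used for prediction — not just families with ≥1 target —
because the test models which families *could* have been drawn. The tail
is computed in log space (log-gamma binomial coefficients + logsumexp);
an exact rational path (`hypergeom_pvalue_exact`) exists for
verification. Exhaustive comparison over every (N ≤ 40, K, n, c) puts the
relative error near 1e-13, far below the 1e-12 contract.

**5. Correction and reporting.** Benjamini–Hochberg step-up q-values are
computed either per query gene (`find_cerna_partners`, mirroring an
interactive single-gene query) or globally over all tested pairs
(`build_cerna_network`, mirroring database construction). Both are
exposed; edges with q below the FDR threshold (default 0.05) are
reported once with `gene_a < gene_b`. Super-sponges are (family,
transcript) pairs ranked by deduplicated site count (ties by
CLIP-supported count, then id); both the total and CLIP-supported counts
are reported since either may be the stringency of interest. Enrichment
uses the same hypergeometric tail per GMT term with Bonferroni (m = terms
in the category) and BH within the category; the background defaults to
the union of the category's term sets but should usually be given
explicitly, since the background choice dominates enrichment p-values.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_experiments` | 1 | CLIP experiments that must overlap a site (≥1 = "CLIP-supported") |
| `min_programs` | 1 | programs that must predict a merged site (3-of-5 is a common stringent choice) |
| `min_common` | 3 | minimum shared families for a pair to be tested |
| `fdr_threshold` | 0.05 | BH q-value cut for reported edges |
| `fdr_scope` | global | BH family: all tested pairs, or one query's candidates |
| `sponge_min_sites` | 5 | minimum same-family site count for a sponge report |
| `min_overlap` | 1 bp | site–cluster intersection threshold |

## The `min_common` caveat

`min_common` pre-selects pairs on the very statistic being tested: every
selected pair already has p ≤ P(X ≥ min_common), so BH applied to the
selected family no longer controls the FDR over it — with `min_common`
well above 1, nearly all selected pairs can pass q < 0.05. It is a
candidate-screening/display convention inherited from interactive use,
not part of the error control. The null-calibration analysis therefore
runs with `min_common = 1` (test every overlapping pair), under which the
realized mean false-discovery proportion over 200 replicate null
simulations is ≈ 0.01 at q < 0.05 — conservative, as expected for
discrete p-values. Treat edge tables produced with larger `min_common` as
"pairs sharing ≥ m families, ranked", not as an FDR-controlled set.

## Synthetic data: what it emulates, what it does not

`simulate_universe` generates the full input bundle: a miRNA catalog
(default 150 families × 2 members), one transcript per gene (default 180
background genes, lengths 500–1500 nt), planted 8mer sites (default 10
families per gene, one site each), per-experiment CLIP BED files whose
clusters cover each planted site independently with probability
`p_support` (default 1.0, 3 experiments, plus 20 decoy clusters per
experiment placed off-site), optional planted ceRNA pairs with an exact
shared-family count, and planted sponge transcripts. Defaults are sized
so a full run takes seconds on one CPU while the planted-pair test
(K = n = 10, c = 8, N = 150, p ≈ 3.8e-10) is unambiguous.

Two constructions make the fixtures exact rather than probabilistic:
family seeds are drawn so that no seed core (positions 2–7) collides with
another family's core or with the unintended 6-nt windows of any planted
8-mer, and background sequence is mutated until no family core occurs
outside planted loci. Consequently the scanner's planted-site recovery
and false-positive checks are exact set comparisons. Each transcript is
emitted as its own single-exon contig, so transcript and genome
coordinates coincide.

What the fixtures do **not** emulate: real seed-site abundance and
sequence composition (background is core-free by construction), UTR
structure and site accessibility, cross-linking biases and
read-depth-dependent cluster boundaries, family co-targeting correlations
in real transcriptomes, and spliced genome-to-transcript projection.
Passing tests therefore demonstrate algorithmic correctness and
statistical calibration under the stated model, not biological
performance on real CLIP corpora.

Determinism: every emitted file has its own RNG stream derived from the
master seed via a stable label (CRC32), so adding outputs never perturbs
existing ones; identical config + seed yields byte-identical bundles, and
the pipeline itself is deterministic end to end (checksummed manifest).

## Numerical and design choices

- Coordinates are 0-based half-open throughout; "overlap" means ≥1 bp,
  so half-open adjacency never counts.
- Chromosome names are compared as exact strings; an optional switch
  strips the `chr` prefix.
- The scanner classifies each core occurrence to its highest class; if
  that class is not enabled the site is dropped, not downgraded.
- Sites spanning exon junctions are not projected to genome space;
  fixtures use single-exon contigs so the question does not arise there.
- BH uses a stable sort, making q-values invariant under input
  permutation; p-values in network construction are computed once per
  unique (K, n, c) triple.
- `hypergeom_pvalue(c = 0)` returns exactly 1.0 rather than a
  log-space round trip.
- Degenerate inputs fail loudly: empty queries/universes, thresholds
  outside their domains, inverted intervals, non-RNA miRNA sequences and
  family seed mismatches all raise with a message naming the violation.
- Validation problem sizes (N ≤ 40 exhaustively for the tail oracle,
  100,000 Monte-Carlo draws, 200 null replicates of 200 genes × 100
  families, 20 planted pairs among 180 null genes, 1,000 × 20 scanner
  comparisons) were chosen so the full validation completes in about a
  minute on one CPU while keeping Monte-Carlo standard errors small
  relative to the tolerances tested.

## Known limitations

- The built-in scanner is seed-match only; no pairing-energy or
  conservation scoring, so its site lists differ from miRanda/TargetScan
  context-aware output.
- Genome-space external predictions are intersected with CLIP clusters
  as given; no liftover between assemblies.
- The ceRNA test ignores expression: it asks whether target repertoires
  overlap, not whether two genes are co-expressed enough to compete.
- Per-query and global BH can disagree near the threshold; the scope is
  a reporting choice and both are exposed deliberately.
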