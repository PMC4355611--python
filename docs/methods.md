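# Methods

## Data model

All computation happens on an integer site × haplotype matrix: bases A, C,
G, T are encoded 1–4 and everything else (uncalled genotypes, 'N', gaps,
IUPAC ambiguity codes) is the missing code 5. Encoding is total over all
byte values, so arbitrary text degrades to missing data rather than
failing mid-run; a `--strict` mode rejects unexpected characters instead.
Genomic coordinates are 1-based and inclusive throughout, and positions
must be strictly increasing. Every diploid (more generally k-ploid) VCF
sample contributes k matrix columns; the written allele order of unphased
('/') genotypes is treated as phase with a prominent warning, because
haplotype-level statistics are otherwise uncomputable — `--strict-phase`
makes unphased calls fatal. Records whose REF or any ALT is not a single
A/C/G/T base (indels, symbolic alleles) are skipped and counted;
multi-allelic SNPs are kept, since every estimator below supports k
alleles per site.

## Statistics

For a window holding matrix rows R over N haplotype columns:

- **Segregating sites** S: rows of R with at least two distinct
  non-missing codes.
- **Haplotype table**: columns grouped by exact code-string equality, with
  the missing code treated as a literal fifth symbol. Treating missing as
  a symbol (rather than wildcard-matching) keeps grouping transitive and
  deterministic; it can split haplotypes that differ only in missingness,
  which is the conservative direction for haplotype counts.
- **Haplotype diversity** Hd = N/(N−1)·(1 − Σⱼ Hf[j]²), the unbiased
  probability that two haplotypes drawn without replacement differ.
- **Per-site diversity** πᵢ = nᵢ/(nᵢ−1)·(1 − Σₗ pₗ²), where nᵢ is the
  site's non-missing count and pₗ the k allele frequencies among those nᵢ.
  This is the unbiased k-allele heterozygosity and equals the mean
  pairwise difference at the site. The biased variant (no nᵢ/(nᵢ−1)
  factor) is a defensible alternative; the unbiased form was chosen for
  consistency with the N/(N−1) correction that Hd carries. Sites with
  nᵢ < 2 have no estimator: they are excluded from both S and Π, and the
  exclusion count is logged.
- **Window diversity** Π = Σᵢ πᵢ, and π = Π/n where n is the window span
  in base pairs — the nominal window size for full bp-mode windows, the
  true truncated span for a partial trailing window, and the genomic span
  (last − first + 1) of the included sites in segregating-sites mode.
- **Watterson's θ** θw = S/a₁(N), per window (not per bp), so that it is
  commensurable with Π in Tajima's D numerator.
- **Tajima's D** = (Π − θw)/√(e₁S + e₂S(S−1)) with the standard chain
  a₁ = Σ1/i, a₂ = Σ1/i², b₁ = (N+1)/(3(N−1)), b₂ = 2(N²+N+3)/(9N(N−1)),
  c₁ = b₁ − 1/a₁, c₂ = b₂ − (N+2)/(a₁N) + a₂/a₁², e₁ = c₁/a₁,
  e₂ = c₂/(a₁²+a₂). A variance at or below 1e-15 is treated as exactly
  zero (a floating-point guard) and D is undefined — rendered as the
  literal `?` in output. Note that at N = 2 the variance is identically
  zero (c₁ = 0), so D is undefined for every window regardless of S.
- **Missing data and N**: πᵢ and segregating status use site-specific
  non-missing counts, while θw and the variance constants use the full
  column count N. These are the standard per-site-exclusion conventions;
  with complete data they coincide exactly.

Haplotype frequencies are computed once over the whole analysed segment
(pooled across populations), independent of window geometry.

## Window schedules

In bp mode, windows are [p + jv, p + jv + n − 1] for j = 0, 1, … while
the right edge stays within the segment; the count therefore equals
⌊(end − start + 1 − n)/v⌋ + 1. A trailing partial window is dropped by
default — the window arithmetic implies full windows — and emitted
truncated by `--emit-partial`. Windows containing no sites are still
emitted (S = 0, Π = 0, D = `?`) so output rows form a regular genomic
grid for plotting. In segregating-sites mode the j-th window holds the
segregating sites with ordinals 1 + jv … n + jv; its bp bounds are the
coordinates of its first and last segregating site, and intervening
monomorphic rows are included. Overlapping ordinal windows (v < n) are
permitted, mirroring bp mode.

In per-population mode each population is analysed entirely on its own
columns: its own N enters every formula, its own segregating sites are
counted, and — in segregating-sites mode — its own segregating sites
define the window schedule. This self-consistency means per-population
windows need not align across populations in that mode; bp-mode windows
always do. Populations with fewer than two haplotypes are skipped with a
warning (no estimator exists). The `--stats` flag selects which output
files are produced; the window table always carries the full column
schema, since all window statistics derive from the same submatrix at
negligible marginal cost.

## Synthetic panels

The generator draws segregating positions uniformly without replacement
along the region and, at each site, a derived-allele count i ∈ {1…N−1}
with probability ∝ 1/i — the site-frequency spectrum expected at
mutation–drift equilibrium in a constant-size neutral population. Under
this spectrum the expected per-site diversity is exactly 1/a₁, so
E[Π] = S/a₁ = θw and Tajima's D is centred on zero by construction: the
generated panels are a genuine neutral null for the whole statistic
chain. Defaults: a 100-kb region; missing-data rate 0; a single
population. The neutral-null checks use N = 40 haplotypes and 1000
segregating sites per panel, sized so that hundreds of replicates run in
seconds while keeping the per-replicate sampling error of D small.

What the generator does **not** model: recombination and linkage (sites
are independent), demography, selection, and sequencing error. The
optional `drift` knob perturbs each population's derived-allele frequency
by a uniform offset — enough to create differentiation for exercising
per-population code paths, but not a demographic model. Passing tests on
these panels therefore validate the estimators and the pipeline, not the
behaviour of the statistics under realistic linkage or demography.

Each panel can be written as a matched phased-VCF / SNP-haplotype-FASTA
pair encoding identical polymorphism data; the test suite requires the
two renditions to produce byte-identical statistic tables.

## Numerical and design choices

- Hd is clipped to [0, 1] to absorb last-bit float jitter; Π uses the
  exact integer identity (n² − Σc²)/(n(n−1)) per site, keeping agreement
  with brute-force pair enumeration at the 1e-12 level.
- Haplotype-frequency output sorts by descending count, ties broken
  lexicographically by decoded sequence — a deterministic, diff-stable
  order.
- Column order follows input sample order (and phase order within a
  sample); per-population results are invariant under column
  permutations.
- Reals are printed to 6 decimal places; undefined D prints `?`.
- Exit codes: 0 success, 2 validation/usage failure, 1 unexpected error.
  Pre-analysis validation reports every failure it finds, naming the
  offending record, field or position.

## Known limitations

- Single-chromosome analysis per run (`--chrom` selects one).
- No Fu & Li or Fay & Wu statistics, no FST, no VCF writing/merging, no
  plotting.
- The FASTA SNP-haplotype dialect carries positions in a sidecar file
  (one 1-based coordinate per line); there is no in-header convention.
- Unphased input analysed with the phase-as-written approximation biases
  haplotype-level statistics (S, π, θw and D are unaffected, as they are
  genotype-symmetric at the site level).
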