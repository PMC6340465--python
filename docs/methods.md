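# Methods

This note documents the models, estimators and numerical choices behind
`yorigin`, and what the synthetic-data generator does and does not
emulate.

## The inference problem

An XY sex-determining region (SDR) suppresses X–Y recombination, so Y
haplotypes form a single genealogical clade wherever the suppression
holds. Three windowed signals localize such a region from
population resequencing data: elevated male–female F_ST (allele-frequency
differentiation driven by Y-linked variants carried only by males),
an excess of sex-limited SNPs (variants at appreciable frequency in one
sex and absent in the other), and male-biased heterozygosity (π_M/π_F).
Once an SDR is localized, gene trees over its windows discriminate the
origin of the Y: a Y clade that is sister to, or nested within, a
*different species'* haplotypes — with divergence *below* the genomic
average — indicates introgression; divergence *above* the genomic
average indicates retained ancestral polymorphism (incomplete lineage
sorting, ILS) or an ancestral sex chromosome.

## Estimators

**F_ST.** Hudson's ratio-of-sums estimator on haplotype frequencies with
the small-sample correction:
per site `num = (p_A−p_B)² − p_A(1−p_A)/(n_A−1) − p_B(1−p_B)/(n_B−1)`,
`den = p_A(1−p_B) + p_B(1−p_A)`; a window's value is Σnum/Σden over
contributing sites (≥ 4 genotyped haplotypes per group). Negative values
are reported as-is, so null distributions stay unbiased. The estimator
is stated in the output headers; no alternative estimator is silently
substituted.

**Sex-limited SNPs.** A site counts when one sex's minor allele (ties at
0.5 allowed) exceeds the MAF threshold (default 0.1) *and* that allele
has frequency exactly zero among the other sex's genotyped haplotypes.
Sites must be genotyped in ≥ 80% of each sex's haplotypes to contribute.

**π and d_xy.** `π = Σ (n/(n−1))·2p(1−p) / L` with L the window length
in bp (`window_bp` mode, default) or the contributing-SNP count
(`snp_only`); `d_xy = Σ [p_A(1−p_B) + p_B(1−p_A)] / L`. Which
denominator a published window-π used is often unstated; both modes are
provided, and all internal comparisons use `window_bp`.

**D and f_d.** Sites are polarized strictly by the outgroup haplotype
(polymorphic or missing outgroup → site skipped; an outgroup that
disagrees with the REF coding re-polarizes the site rather than dropping
it). `D = Σ(ABBA−BABA)/Σ(ABBA+BABA)`;
`f_d = Σ(ABBA−BABA)/Σ(ABBA_d−BABA_d)` with the site-wise dynamic donor
`p_d = max(p₂, p₃)` substituted for both p₂ and p₃ in the denominator.
Handling of degenerate windows: D is undefined (missing) when no
ABBA/BABA-informative sites exist, but f_d's denominator only requires
derived alleles in the donor, so windows with no sharing at all yield
f_d = 0 — the estimator's natural "no admixture" value — rather than a
missing value. f_d is withheld, with a reason code, only when D < 0 (a
demonstrated deficit lies outside the estimator's domain) or when the
denominator itself is zero. Windows need ≥ 20 usable sites by default.

**Gene trees.** Pairwise Jukes–Cantor distances over shared non-missing
sites (`d = −¾ ln(1 − 4p/3)`; p ≥ 0.75 capped at 5.0 and logged), then
neighbor joining (scikit-bio's implementation) with tip ids sorted
canonically first, making the topology independent of caller tip order.
Trees are rooted on the outgroup haplotype when present, else at the
midpoint (logged). XY-consistency searches all clades for an exclusively
focal-male clade with at most one haplotype per male covering at least a
fraction q of the males present (q = 1.0 for the strict scan; q = 0.5
for Y-scoring during phasing, since requiring every male is brittle
under real-data artifacts such as heterozygote dropout). Quartet
topology weights enumerate all one-per-group quartets when the group
product is ≤ 10 000, else Monte-Carlo sample; the realized pairing of a
quartet is the one whose two LCAs are jointly deepest, computed from a
single postorder LCA-depth matrix. The direction classifier tests
nesting by MRCA identity: the donor species is implicated when
MRCA(Y ∪ donor) = MRCA(donor) and contains no focal-X or sister-species
tips; the reverse nesting implicates the focal species as donor.

**Y phasing.** Trees in overlapping windows (default 100 kb, step =
window/5); haplotypes in a qualifying exclusively-male clade are scored
Y-linked (the largest clade wins; two equal disjoint clades skip the
window); each heterozygous site of a scored male receives one unweighted
vote for the allele its scored haplotype carries; the final Y allele is
the simple majority, with ties and uncovered sites left missing.
Rebuilt Y/X haplotypes carry the voted allele and its complement at
decided heterozygous sites, the shared allele at homozygous sites, and
missing elsewhere. **Vote-margin caveat:** around a phase-switch point
the window that straddles the switch is an even toss, so a zone of up to
half a window step on one side of the switch can be decided 3–2 the
wrong way; sites farther than half a window from any switch are
recovered exactly. Recovery is therefore a function of switch spacing
relative to window size: with switches every ~10⁴ sites and 10-kb/2-kb
voting windows, decided-site accuracy is ≥ 99%; when switches are dense
at the scale of any tree-buildable window (e.g. 0.02 per site, one
switch per ~50 SNPs), male haplotype columns are fine X/Y mosaics, no
clean male clade exists, and voting cannot recover phase — no windowed
tree method can. This failure mode is asserted honestly in the test
suite rather than hidden.

**NG86 dN/dS.** Synonymous/nonsynonymous site counts per codon (each
position contributes the fraction of its three possible point mutations
that are synonymous; mutations to stop codons count as nonsynonymous),
averaged over the two sequences; substitution counts for multi-hit
codons average over all minimal mutational pathways with equal weight,
excluding pathways through stop codons (falling back to all pathways if
none avoids a stop); Jukes–Cantor correction applied to p_N and p_S,
with p ≥ 0.75 yielding missing. Codons with gaps or ambiguity are
skipped pairwise; internal stops raise; a shared terminal stop is
ignored. No transition/transversion or codon-frequency parameters — the
method is chosen for exact desk-scale verifiability against pathway
enumeration.

**ILS vs introgression.** One-sided Mann–Whitney U of SDR-window
Y-vs-donor d_xy against autosomal focal-vs-donor d_xy; a significant
excess (α = 0.05) is ILS-consistent, anything else introgression-
consistent. At least 5 windows per class are required.

**SDR inference.** The autosomal windows supply a null F_ST quantile
(default 0.99, ≥ 20 windows required); the SDR call is the longest run
of ≥ 3 consecutive focal-chromosome windows above it.

## Synthetic data

Each window receives one genealogy from a structured coalescent over
((sinensis, tymensis), pungitius) + outgroup; mutations are dropped on
branches as Poisson(μ·L·branch length) under infinite sites with
uniform unique positions. There is no recombination within a window and
free recombination between windows — matching the windowed analyses and
giving closed-form expectations — so single-window statistics are
*tree-limited*: a window's null F_ST or d_xy fluctuates with its one
genealogy rather than averaging over many, making synthetic windows
noisier than equally sized real-data windows. Tests treat per-window
nulls distributionally for this reason.

Defaults (coalescent units; per-pair coalescence rate 20, i.e. small
within-species effective sizes relative to split times, as appropriate
for well-differentiated species): species splits t_st = 0.54 and
t_pun = 0.77, outgroup attachment t_out = 1.3, mutation rate
μ = 0.0152 per site per unit. These were calibrated once so autosomal
divergences match the synonymous-divergence scale of the focal system —
sinensis–tymensis ≈ 0.018 and sinensis–pungitius ≈ 0.025 per site
(measured 0.0176–0.0187 and 0.0249–0.0253 across seeds); within-species
diversity comes out near 0.003, a realistic stickleback value. The
outgroup is kept at t_out = 1.3 deliberately: a deeper outgroup pushes
its per-segregating-site p-distance toward the Jukes–Cantor saturation
point (p = 0.75), where corrected distances become noisy enough to
distort whole NJ topologies. Calibrating the outgroup's true divergence
is not needed by any analysis (it only polarizes and roots).

Scenario construction for SDR windows:

* `introgression` — the per-male Y haplotypes (truth table records which
  of A/B) coalesce to a single lineage by t_intro/2 = 0.05; that lineage
  attaches to a randomly chosen sinensis lineage at t_intro = 0.1, with
  the sinensis population held at ≥ 2 lineages until then so the
  attachment is strictly *inside* the clade, and the final sinensis
  coalescence deferred by a guard interval t_resolve = 0.05 so the
  nesting branch carries enough mutations (~75 at defaults) to be
  resolvable by distance methods. The conditioning and guard make
  nesting a construction guarantee rather than a probabilistic outcome —
  appropriate for a generator whose role is to provide unambiguous
  truth.
* `ils` / `xy_ancestral` — the Y lineage remains distinct until
  t_ydeep = 1.0 > t_pun, producing elevated Y–donor divergence.
* `donor_pungitius` — the reverse transfer: the sinensis lineage nests
  inside the male-limited clade at t_intro, and the combined lineage
  rejoins pungitius at t_xy = 0.35.
* `no_sdr` — every window follows the species tree.

Phase-switch errors are a per-male Markov process along matrix sites:
each site independently toggles a swap state with the given probability,
and the two haplotype columns are exchanged wherever the state is odd;
the truth table continues to refer to the original chromosomes.

What the generator does **not** emulate: within-window recombination
(see tree-limited noise above), gene flow outside the SDR (real systems
with a history of hybridization show genome-wide admixture; here
autosomal f_d is structurally 0, which makes the SDR contrast cleaner
than in real data), heterozygote dropout and genotyping error, selection
and repeat accumulation, and multi-nucleotide or back mutation. Passing
tests therefore demonstrate correctness of the estimators and of
parameter recovery under the stated model, not robustness to every
real-data artifact.

## Problem sizes and determinism

Default study conditions: a 2-Mb sex chromosome (SDR placed by scaling
the 3.5–18.9-Mb inversion interval of a 20.6-Mb chromosome) plus a 2-Mb
autosome, 100-kb windows, 15/15 pungitius males/females, 11/9 sinensis,
13/10 tymensis, one haploid outgroup. Unit and end-to-end tests run
reduced chromosomes (0.2–2 Mb) chosen so each check has ample windows
and sites while the whole suite stays fast. All randomness flows from
explicit seeds through `numpy.random.SeedSequence` spawning (one child
per window), so datasets, stage outputs and reports are byte-identical
across runs; the CLI's `--threads` option never affects results and is
excluded, along with the output directory, from the config hash embedded
in outputs.

## Known limitations

* The SDR boundary is realized at window granularity; sub-window
  breakpoint placement is out of scope.
* The direction classifier requires the outgroup-rooted topology to be
  correct at the nesting branch; very short internal branches return
  `ambiguous` rather than guessing.
* Y-phasing accuracy degrades predictably as phase-switch spacing
  approaches the voting window size (see the vote-margin caveat above).
* PAR windows have no defined X/Y split; topology weighting there labels
  male haplotypes arbitrarily, which leaves T1 (X-with-Y) meaningful but
  makes T2/T3 exchangeable.
* Multi-allelic sites are not supported; they are skipped on input with
  a logged count.
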