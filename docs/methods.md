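# Methods

This note documents the models, estimators and numerical choices behind
`bilqtl`, and what its synthetic populations do and do not establish about
real data.

## Population and genotype model

The package targets backcross inbred lines (BILs): an F₁ between a wild
donor (Ws) and a recurrent cultivar parent (Af) is backcrossed to Af twice
and then selfed by single-seed descent. The simulator executes this
pedigree literally — 80 BC₁ plants of which 65 are retained, 302 BC₂
plants with dams drawn uniformly from the kept BC₁s, six selfing
generations, 110 sampled lines — with Poisson (Haldane, no-interference)
crossovers: counts ~ Poisson(map length in Morgans), positions uniform in
genetic distance. The recombination landscape is uniform by default
(genetic position ∝ physical position), configurable per chromosome.

At a neutral single locus the pedigree gives exactly
P(Ws homozygote) = (1/8)(1 − 2⁻⁶) = 63/512 ≈ 0.1230 and residual
heterozygosity 2⁻⁸ ≈ 0.0039; `expected_genotype_freqs` propagates the
Mendelian transition rules and the test suite checks the simulator against
an independently coded transition-matrix oracle. Because all lines descend
from 65 BC₁ families, realized frequencies at any one locus vary far more
than binomial sampling suggests; tests that check marginal frequencies use
a widened BC₁ base ("neutral sampling") to suppress that family
correlation, which is a property of the check, not of the default
population.

An optional per-locus viability-selection hook (rejection sampling on a
plant-fitness function) can induce segregation distortion; it is off by
default because the selective pressures behind the real population's low
donor fraction (≈ 5.8% observed vs ≈ 12.3% neutral expectation) are
unknown, so the default simulated composition is the *neutral* ≈ 12.3%.

## Observation model

Sequencing is emulated at the genotype-call level: per line and site,
depth ~ Poisson(1.8); each read samples an allele from the true genotype
(fair coin for heterozygotes) and is flipped with probability 0.01; calls
are homozygous when all reads agree, heterozygous when both alleles are
seen, missing at depth 0. Parents are observed identically at 10×. This
reproduces the salient pathologies of ~1.8× data — ~17% missing calls,
true heterozygotes called homozygous with probability 2^(1−d) at depth d —
but not alignment artefacts, depth overdispersion, or allelic-bias errors.

## SNP retention and bin genotyping

Retention requires (1) both parents homozygous for different alleles and
≥ 60 lines (or a configurable fraction) called at the site, and (2) parent
depth strictly greater than fourfold (≥ 5 reads). After filtering, calls
are oriented so code A is the Af allele.

The window caller slides a 50-SNP window in 1-site steps ("50/1" read as
SNP counts, not bp — at bin-map densities a 50 bp window would be empty).
Within a window, heterozygous site calls contribute half a count to each
parent; a window is called homozygous only when a parent's share strictly
exceeds 2/3 (integer half-unit arithmetic makes the boundary exact), and
missing below 10 informative sites. Window calls are smoothed back onto
sites (each site takes its centred window's call) and run-length encoded.

Around every clean crossover the majority rule necessarily produces a
≈ W/3-site heterozygous stripe; stripes shorter than one window between
opposite homozygous runs are therefore collapsed to a single breakpoint at
the stripe's central site pair, which on evenly spaced sites is the exact
midpoint between the two sites flanking the junction (ties to the lower
coordinate). Longer heterozygous runs — genuine residual heterozygosity —
are preserved. Missing runs inherit agreeing flanks.

Bins partition each chromosome into 50 kb grid intervals; per line an
interval takes the genotype covering the majority of its span (an exact
50/50 tie is unresolvable and becomes missing), adjacent intervals with
identical genotype vectors across all lines merge, and SNP-less intervals
are absorbed into a neighbour so every bin carries ≥ 1 SNP. Bins are then
screened by a df-1 chi-square test of homozygote counts against AA:BB =
7:1 (the BC₂ expectation in the complete-inbreeding limit; configurable)
at p < 0.005.

Resolution consequence: a segment shorter than ~2/3 of a window's bp span
is invisible to the caller, and nothing smaller than one grid interval is
representable in the bin matrix. Recovery tests therefore project the true
genotype tracks to grid resolution before matching, and use SNP densities
at which the window's resolution limit sits below one grid interval. At
the package's default desk-scale density (2,000 SNPs over 20 Mb/150 cM per
chromosome) the window spans ≈ 5 cM, which loses ~15–20% of junctions and
shortens the estimated map accordingly; a real ~3 M-SNP panel is
proportionally ~25× finer, so this is a property of the scaled-down genome,
not of the method.

## Linkage map

Between adjacent bins the observed recombinant fraction R counts opposite
homozygotes among lines homozygous at both bins. Because lines accumulate
junctions over repeated meioses, R must be deflated to a single-meiosis r
before applying a map function. The classical selfed-RIL relation
r = R/(2 − 2R) assumes junction density 2 per Morgan (Haldane–Waddington);
propagating the exact two-locus diplotype distribution through *this*
pedigree shows the backcrosses erase most junction accumulation, leaving
R/r → ≈ 1.05 as r → 0 — the RIL-self correction would compress the map
roughly twofold. The default correction (`"bil"`) therefore inverts the
exact pedigree forward map R(r) via a cached monotone interpolation table
(201 nodes on r ∈ [0, 0.4999]); `"ril-self"` and `"none"` remain
switches. R at or beyond the pedigree's two-locus saturation (≈ 0.22)
caps r at 0.4999.

Distances use Kosambi, d = 25·ln((1+2r)/(1−2r)) cM, matching the original
analysis; bins are ordered by physical position (no de novo ordering), and
uninformative adjacent pairs are bridged by splitting the distance between
the nearest informative flanking bins equally. Map summaries divide genetic
length by the number of bins (not bins − 1), the convention that reproduces
the published per-chromosome mean inter-bin distances.

A note on what adjacent gaps can show: after merging, each bin boundary
exists because ~1 line recombines exactly there, so the adjacent-bin
recombinant count is nearly constant and carries no information about the
physical gap size. Recovery of relative genetic distance is instead tested
on separated bin pairs, and absolute recovery on total map length.

## Trait statistics

Nine measured traits (MLL, LW, RL, RSD, RMD, RTD, RW, PW, DMC) are
aggregated to line-year means (median optional) before any statistic; the
seven ratio indexes (iLR = LW/RW, iSM = RSD/RMD, iST = RSD/RTD,
iMT = RMD/RTD, iSL = RSD/RL, iML = RMD/RL, iTL = RTD/RL) are computed from
those aggregates, so iST = iSM·iMT holds identically. Pearson correlations
per year carry two-sided significance tiers (0.05/0.01/0.001); the
between-year comparison is a one-way ANOVA on line means flagged at 0.01.

The phenotype simulator is purely additive — trait = intercept +
Σ a·x (x = +1/0/−1 for Af-homozygote/heterozygote/Ws-homozygote) + year
shift + Gaussian replicate noise. Defaults plant five loci echoing the
magnitudes of the stable chromosome-2 loci (target PVEs 0.16–0.32), with
trait means/SDs chosen at field-realistic values. Effects for a target PVE
are sized by a² = PVE·σ²/((1−PVE)·Var(x)) with Var(x) from the exact
pedigree distribution (≈ 0.434); recovery tests size against the
*realized* genotype variance at the planted locus so the planted PVE holds
exactly in every replicate despite family sampling. No dominance,
epistasis, or genotype-by-environment interaction beyond the additive year
shift is simulated.

## Composite interval mapping

The scan is Haley–Knott regression rather than mixture-model EM: with
nearly fully inbred two-genotype lines the regression form is
near-equivalent and orders of magnitude faster, which matters because
permutation thresholds re-run the entire procedure. At each 1 cM lattice
position the expected score x̂ = E[x | flanking informative bins] is
computed under the two-genotype model with Haldane recombination to the
flanks (exactly ±1 at a line's own homozygous bin; single-flank
conditioning at ends and across missing data; heterozygous bins are
uninformative, x = 0).

Background cofactors are chosen by forward–backward stepwise regression
(partial-F entry/removal at 0.05, at most 5 cofactors, deterministic
tie-breaks toward lower column index, collinear candidates skipped, an
oscillation guard on repeated states) from a candidate set thinned to
≥ 2 cM spacing — background-marker sets in CIM implementations are
similarly limited, and full density is a switch. At each position the
trait is regressed on x̂ plus cofactors outside a 10 cM window centred on
the position; LOD = (n/2)·log₁₀(RSS₀/RSS₁) via partial correlation of
residualized vectors, grouped by active-cofactor set so a whole-genome
scan is a handful of matrix operations.

The genome-wide threshold is the empirical (1 − α) quantile ("higher"
order statistic) of the maximum LOD over trait permutations across lines,
with cofactors re-selected per permutation — the conservative,
self-consistent choice (fixed-cofactor mode available). QTLs are
supra-threshold peaks; peaks within one segment are split only where a
valley drops more than 1.5 LOD below both; the support interval is the
1.5-LOD drop region (the operational "95% confidence interval"); the
additive effect is the x̂ coefficient (positive = Af allele increases the
trait); PVE is reported both as 1 − 10^(−2·LOD/n) and as the partial R²,
which in this regression formulation are algebraically the same number.
Peak PVEs inherit the usual upward biases of CIM (winner's curse at the
maximum, residual variance absorbed by cofactors); calibration tests bound
the bias rather than remove it.

Simulation-based checks: null traits scanned against their own permutation
thresholds show a genome-wide false-positive rate statistically compatible
with α = 0.05, and a planted single QTL with PVE 0.30 at n = 110 on a
9 × 150 cM genome is detected essentially always, with sub-cM median peak
error in physical coordinates.

## Pipeline and reproducibility

`run_pipeline` executes simulate → filter → bin → map → traits → scan with
stage-level logging of record counts, writes every artefact as text (TSV /
CSV / JSON / minimal VCF), and emits a manifest echoing every parameter
(defaults included) plus SHA-256 checksums; equal configs reproduce
bit-identical outputs because every random draw descends from the single
configured seed. The TSV genotype dialect carries no per-call depths, so
the parent-depth criterion is skipped (with a logged warning) on that
input path; the VCF path applies it.

## Problem sizes

Desk-scale defaults are 9 chromosomes × 150 cM × 20 Mb with 2,000 SNP
sites each — a stand-in for the ~3.2 M-SNP real panel chosen so a full
population simulates in ~2 s and a 200-permutation threshold computes in
~2 s on one CPU. Calibration uses 200 null traits × 200 permutations;
recovery uses 100 replicates with 100-permutation thresholds;
resolution-sensitive recovery tests raise the density to 8,000 SNPs per
chromosome as discussed above.

## Known limitations

- No hidden-Markov genotype imputation; the window rule is the method
  under study.
- The exact pedigree rf correction assumes the nominal breeding design;
  deviations (selection, unequal family use) bias the map modestly.
- CIM here is single-QTL-at-a-time with cofactors; no multiple-QTL model,
  epistasis, or cross-year mixed model.
- The simulator omits reference-genome sequence content, structural
  variation, and non-uniform recombination unless configured.
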