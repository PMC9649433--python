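# Methods

## Surface profiling

Per-atom SASA uses the Shrake–Rupley quadrature: each atom is covered with
`n_points` test points (default 960) on a sphere of radius r_vdw + r_probe
(probe 1.4 Å), and the exposed fraction — points outside every neighbouring
atom's inflated sphere — scales the analytic sphere area. The point set is
a golden-spiral lattice, purely arithmetic, so results are bit-identical
across runs; on an isolated atom the quadrature is exact to machine
precision because no point is occluded. Refinement error on the toy helix
fixture is below 2 % between 960 and 3840 points.

Van der Waals radii are a packaged NACCESS-style table (C 1.70, N 1.55,
O 1.52, S 1.80 Å). Hydrogens, HETATM records, waters and ions are ignored;
only the first altloc is kept. Per-residue SASA is the sum over the
residue's atoms; relative solvent accessibility divides by the theoretical
maximum accessible area of the residue type (Tien et al. 2013 theoretical
maxima, packaged as CSV). RSA was chosen as the accessibility measure
because the default surface threshold 0.3717 — the published
reference-panel median accessibility score — is dimensionally consistent
with a fraction; the threshold is configuration, not a constant.

When profiling a structure, all chains (bound peptide, light chain) occlude
solvent but only the heavy chain contributes profile positions. Author
numbering is mapped to 1-based mature-protein positions through a global
alignment against the reference sequence (≥ 95 % identity required over
aligned columns); unresolved positions are *absent*, never zero, since zero
means genuinely buried. Automatic heavy-chain selection takes the longest
chain and refuses chains under 80 residues — toy fixtures pass the chain id
explicitly.

## Allele database and the accessibility predictor

All alleles of the Class I group live on one alignment grid (a consensus
string; insertions relative to it are dropped, deletions become the gap
symbol `-`). Sequences rejected below 70 % identity to the consensus are
assumed to belong to a different locus group. RSA values are clipped to
[0, 1.5] and stored as missing at gaps.

Alleles without structures get predicted profiles. The production concept —
a learned sequence→surface model — is reduced here to a deliberately simple
reference implementation behind the same fit/predict contract: the k
nearest training alleles by global sequence identity (k = 3, ties broken by
allele name for determinism) contribute a position-wise mean RSA. With
k = 1 a training sequence is recalled verbatim, which the contract
guarantees and the tests pin. Any stronger model can be dropped in without
touching the scoring code.

## Scoring

The Snowflake score treats the donor allele's *own* surface as the
immunogen: accessible positions come from the donor profile at the
configured threshold, and a (position, residue) pair is mismatched when no
allele in the recipient's comparison repertoire carries that residue at
that position (self-repertoire model, not pairwise comparison). The locus
score is the size of the union of mismatched pairs over the locus's donor
alleles — union, not sum, so a mismatch shared by both donor alleles counts
once (locus-specific rather than mismatch-specific semantics). Interlocus
scoring compares against all six recipient Class I alleles, intralocus
against the same-locus pair only; since the comparison set only grows, the
interlocus score never exceeds the intralocus score. A donor allele present
in the recipient repertoire contributes nothing at any threshold.

Eplet counts require every (position, residue) of a registry pattern to
match an allele's aligned sequence (no partial credit); an eplet counts
when present on at least one donor allele of the locus and on none of the
recipient's Class I alleles, each distinct name once. AbvEPS restricts to
antibody-verified entries and is therefore bounded by AllEPS.

The presentation surrogate enumerates core-length windows (default 9) of
the donor's ungapped sequence containing at least one mismatched residue
and filters them through a pluggable presentation predicate per presenter
locus. The default predicate accepts everything; it is a stand-in interface
for peptide–MHC binding prediction, and counts under the default should be
read as mismatched-peptide loads, not presented-peptide predictions.

## Typing imputation

Candidate haplotype pairs are enumerated from the frequency table, matched
against the typing tokens (explicit alleles pass through, multi-allele
codes expand via the code table, serologic antigens expand via the
allele→antigen map), and weighted f(h1)·f(h2), doubled for heterozygous
pairs (Hardy–Weinberg). Weights are normalized over matching pairs, pairs
at or below the 1 % floor are dropped (the floor is strict: "exceeds"),
and the retained weights are renormalized to one so the weighted score is
a proper expectation — renormalization after the cut is this package's
documented choice. Donor and recipient imputations are independent;
combination weights are products. Imputed scores are therefore convex
combinations of candidate scores and collapse to direct scoring when the
typing is unambiguous.

## Cohort statistics

Pooling turns each pregnancy or transplant into up to three per-locus
records. Pregnancy records exist only for informative loci — mismatched,
and not child-homozygous for an allele shared with the mother. Transplant
records are dropped when all four score families are zero (with ambiguous
typing, a zero-mismatch call is unreliable, so fully-zero loci are treated
as matched); the antibody flag is positive if a DSA was observed against
either donor allele of the locus.

Score families are standardized within locus on the post-exclusion
analysis set before pooling, using the sample (n−1) standard deviation;
presentation counts are transformed log(1+x). Effects are reported per
1 SD. The two-group comparison uses the independent-samples rank-sum
(Mann–Whitney) test — exact enumeration for tie-free combined samples of
at most 20, tie-corrected normal approximation otherwise. Logistic models
are maximum-likelihood binomial fits with Wald 95 % CIs on the log-odds
scale; complete separation is flagged as non-converged rather than
reported silently. Stepwise selection is bidirectional from the full
model, taking the single add/drop with the lowest AIC per step, stopping
when no move improves — the selected AIC never exceeds the full model's.
Cox models use the partial likelihood (via lifelines); a standalone score
test at β = 0 with Breslow tie handling is provided, which on two-group
data without tied event times is exactly the log-rank test — the tests
exploit that identity as an oracle. No multiple-testing correction is
applied; p < 0.05 is the configured significance threshold.

The cross-locus analysis restricts to cases mismatched at all three loci
and regresses each target locus's antibody flag on source-locus predictors.
Because haplotype structure links mismatch loads across loci, *marginal*
off-locus associations are expected even without any causal cross-locus
effect; the meaningful null is conditional on the own-locus score, and the
null-simulation tests assert exactly that.

## Synthetic data generator

The generator emulates the *designs* of the two validation cohorts, not
their content. Defaults: 6 alleles per locus in 3 serologic groups on a
50-position grid, 60 % polymorphic columns with two shared alternative
residues each, 12 haplotypes with Dirichlet frequencies, 300 cases per
cohort. Each allele has exactly round(0.4 × 50) = 20 true-surface
positions: RSA is drawn uniform on (0.45, 1.0) there and (0, 0.30)
elsewhere, so the 0.3717 threshold separates surface from buried without
boundary effects. Surface sets are allele-specific: a shared position
ranking perturbed per allele, mimicking protein-specific accessibility.

The eplet registry enumerates the panel's surface polymorphisms — one
single-residue eplet per (position, residue) configuration observed at a
polymorphic position on an allele whose own surface exposes it. A
configuration exposed on *every* carrier allele is marked
antibody-verified; one exposed only on some carriers is not. This
deterministic rule encodes the view that verified epitopes are the robustly
accessible ones, and it is what makes the verified subset track the
allele-specific surface mismatch count most tightly — the generator's
constructed analogue of B-cell-epitope scores agreeing with each other more
than with a T-cell-epitope count.

Pregnancy cases draw two maternal haplotypes and transmit one to the child
alongside an independent paternal haplotype; child-specific antibodies are
Bernoulli with logit p = β₀ + β·z(true Snowflake) per informative locus
(defaults β₀ = −1.3, β = ln 1.63 — the published pregnancy-cohort effect
size used as a generator input, not as a reproduction claim). An optional
cross-locus coupling adds the mean z of the other loci to the logit.
Transplant cases draw donor and recipient genotypes independently; per
informative locus the time to DSA is exponential with hazard
λ₀·exp(β_h·z) (λ₀ = 0.016/yr, β_h = ln 1.32), censored by an independent
exponential calibrated to the configured censoring fraction (0.3) and
capped at 15 years. Degraded typings replace alleles by serologic antigens
(p = 0.4), multi-allele codes (p = 0.4) or leave them explicit, exercising
imputation against known truth.

Single-antigen-bead panels draw log-normal MFI (baseline 30, σ = 0.4 on the
log scale, true targets elevated ×100); antibodies are called when MFI
exceeds both the absolute floor of 100 and mean + 3 SD of the self beads.

Toy structures are idealized α-helices (2.3 Å radius, 100°/1.5 Å per
residue) with backbone atoms near the axis and side-chain dummy spheres
pointing outward (one extra sphere for bulky residues), written and parsed
as standard PDB. They exercise the SASA geometry, chain-occlusion and
alignment logic, not real HLA folds: β-sheet topology, the peptide groove,
and realistic burial patterns are absent, so passing structure tests shows
the machinery is correct, not that predicted surfaces of real alleles would
be.

All randomness flows from `numpy.random.default_rng` seeded per call;
identical configuration and seed give bit-identical output.

## Problem sizes and verification scale

The parameter-recovery experiment uses 50 replicate pregnancy cohorts of
400 cases each, truncated to the first 600 pooled mismatch records, at a
true odds ratio of 1.6 per SD; coverage of the Wald 95 % CI and stepwise
retention of the true predictor are the reported operating characteristics.
The correlation-ordering check runs 20 independent seeds. These sizes make
the full suite run in a few minutes on one CPU while keeping the binomial
noise on coverage proportions small.

## Known limitations

- The accessibility predictor is a nearest-neighbour average; it cannot
  extrapolate surface changes caused by substitutions absent from the
  training panel.
- The presentation surrogate with the accept-all predicate measures
  mismatched-peptide load only; conclusions about presented peptides
  require plugging in a binding model.
- Imputation assumes a single population haplotype table and independence
  of donor and recipient; linkage between donor and recipient typings
  (e.g. related donors) is not modelled.
- Class II scoring is out of scope; presenter genotypes enter only through
  the presentation predicate interface.
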