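# snowmatch

HLA epitope matching from allele-specific protein surfaces.

Antibodies against mismatched donor HLA (donor-specific antibodies, DSA)
are a major cause of graft loss after organ transplantation, and the same
alloimmune mechanism produces child-specific antibodies (CSA) in mothers
after pregnancy. Because antibodies bind patches on the *surface* of the
donor's HLA proteins, a mismatch should only matter immunologically if the
mismatched amino acid is solvent-accessible — and solvent accessibility
differs between HLA proteins, so it must be evaluated per allele rather
than per locus.

`snowmatch` implements this idea end to end for HLA Class I:

1. **Surface profiling** — per-residue solvent-accessible surface area
   (SASA) of a structure by the Shrake–Rupley rolling-probe method,
   normalised to relative solvent accessibility
   RSA(i) = SASA(i) / maxASA(aa_i).
2. **Allele database** — profiles for alleles without structures are
   extrapolated by a pluggable sequence→surface predictor (reference
   implementation: position-wise mean over the k most similar alleles).
3. **Snowflake score** — for a donor allele d with surface set
   S(d) = { p : RSA_d(p) ≥ t } (default threshold t = 0.3717, the
   reference-panel median RSA), the locus score is

       Snowflake = | ⋃_d { (p, aa_d(p)) : p ∈ S(d),
                           aa_d(p) ∉ { aa_r(p) : r ∈ recipient Class I } } |

   i.e. the number of distinct solvent-accessible (position, residue)
   mismatches against the recipient's complete HLA-A/B/C repertoire
   (interlocus; an intralocus variant restricts the comparison set).
   Allele-matched pairs score zero by construction.
4. **Reference scores** — mismatched eplet counts from a registry table
   (AllEPS, and the antibody-verified subset AbvEPS) and a surrogate
   donor-peptide presentation count (PIRCHE-like, pluggable presentation
   predicate) for comparison.
5. **Typing imputation** — ambiguous typings (serologic antigens,
   multi-allele codes) are resolved via a haplotype-frequency table:
   Hardy–Weinberg pair weights, a strict 1 % normalized-frequency floor,
   renormalisation, and frequency-weighted expected scores.
6. **Cohort statistics** — per-locus pooling of mismatch records
   (mother/child and donor/recipient designs), within-locus z-scoring and
   log(1+x) transforms, rank tests, Spearman correlation, univariable and
   stepwise-AIC logistic regression, and Cox proportional-hazards
   regression for time-to-antibody data.
7. **Synthetic cohorts** — a seeded generator producing toy structures,
   allele panels with known accessibility, surface-derived eplet
   registries, haplotype/MAC/serology tables and both cohort designs, so
   the whole pipeline is testable without any external data.

## Worked example

```python
from snowmatch import SimulationConfig, make_allele_pool, simulate_pregnancy
from snowmatch.cohort_stats import logistic_univariable, normalize, pool_pregnancy
from snowmatch.epitope_matching import locus_scores

pool = make_allele_pool(SimulationConfig(seed=7))
donor = {L: (h.alleles[i], h.alleles[i]) for i, L in enumerate(pool.loci)
         for h in [pool.haplotypes[0]]}
recipient = {L: (pool.haplotypes[1].alleles[i], pool.haplotypes[2].alleles[i])
             for i, L in enumerate(pool.loci)}
for s in locus_scores("pair1", donor, recipient, pool.db, pool.registry):
    print(f"{s.locus}: snowflake={s.snowflake} all_eps={s.all_eps} "
          f"abv_eps={s.abv_eps} pirche_DRB1={s.pirche['DRB1']}")

cases = simulate_pregnancy(pool)
records = normalize(pool_pregnancy(cases))
result = logistic_univariable(records, "z_snowflake")
```

Output:

```
A: snowflake=0 all_eps=0 abv_eps=0 pirche_DRB1=0
B: snowflake=0 all_eps=0 abv_eps=0 pirche_DRB1=28
C: snowflake=2 all_eps=2 abv_eps=2 pirche_DRB1=24
pooled mismatches: 513, antibody events: 105
odds ratio per SD: 1.73 (95% CI 1.40-2.12, p=2.91e-07)
```

The donor is allele-matched at HLA-A (everything zero). At HLA-B the donor
allele differs, but every solvent-accessible mismatch is covered elsewhere
in the recipient's repertoire — the presentation surrogate still counts
buried-position peptides, the surface scores do not. At HLA-C two
accessible (position, residue) mismatches remain. On a simulated pregnancy
cohort whose antibody risk rises with the true Snowflake score (odds ratio
1.63 per SD by design), pooling the informative locus mismatches and
fitting a logistic model recovers an odds ratio of 1.73 (CI 1.40–2.12).

A `snowmatch` command-line interface mirrors the library
(`simulate`, `surface`, `build-db`, `score`, `impute`, `analyze`); run
`snowmatch --help`.

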