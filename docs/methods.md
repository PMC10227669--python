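# Methods

## The coverage problem

A donor bank is a subset of donor genotypes; a patient is *covered* when at
least one selected donor can treat them under the active clinical rule.
Patients with the same 5-locus genotype are merged, so the patient pool is a
set of distinct genotypes *g<sub>i</sub>* with positive integer weights
*p<sub>i</sub>* (occurrence counts).  For a coverage target *t* we set
*P* = ⌈*t* · Σ*p<sub>i</sub>*⌉, which makes "cover 50%" well defined on
integer weights.  Selection minimizes Σ *c<sub>j</sub>x<sub>j</sub>* over
*x<sub>j</sub>* ∈ {0,1} subject to

* Σ *p<sub>i</sub>y<sub>i</sub>* ≥ *P*, and
* *y<sub>i</sub>* ≤ Σ<sub>j : i∈S<sub>j</sub></sub> *x<sub>j</sub>*, with
  0 ≤ *y<sub>i</sub>* ≤ 1.

The coverage constraint is an inequality rather than an equality: with
integer weights an exact-equality target is generically infeasible, and
under minimization the inequality form cannot undercut the equality form's
optimum.  Costs are 1 per donor except in scenario 3, where a knockout
product costs `cost_ko + 1` (one donor plus `cost_ko` donors' worth of gene
editing; default `cost_ko = 10`).

## Stage 1: matching by reduced keys

Mismatches are counted per locus as 2 minus the multiset intersection of
the two unordered allele pairs, summed within a class (class 1 = A, B, C,
six slots; class 2 = DRB1, DQB1, four slots).  This resolves the homozygous
edge case explicitly: the intersection of {x,x} and {x,y} is one x, i.e.
one match.  The condition "at most *a* class-1 and *b* class-2 mismatches"
is evaluated by expanding each genotype's class projection into *reduced
keys* — all canonical projections with 0..*a* (resp. 0..*b*) slots replaced
by a wildcard.  Dropping either copy of a homozygous allele yields the same
canonical key, so keys deduplicate.  Two genotypes share a key at *k* drops
iff their class mismatch count is ≤ *k* (each side drops its unmatched
slots), so donor-patient compatibility reduces to a nonempty key
intersection per class, implemented as inverted indexes (key → genotype
ids).  Donor and patient drop budgets are shared; directionally asymmetric
budgets (GvH vs HvG) are not modeled.  A brute-force pairwise predicate
(`oracle_match`) implements the same semantics with no key construction and
the test suite checks exact agreement on hundreds of random pools.

Scenario specializations:

* **Scenario 1** skips class-1 keys entirely (class 1 unconstrained) and
  joins on the exact class-2 projection; within each class-2 bucket, donors
  cover the patients of opposite Bw4 presence status.  Bw4 status is binary
  presence (≥1 flagged allele among the four A/B slots); copy number is
  ignored.  The default treats a status difference in either direction as a
  KIR-ligand mismatch; the one-sided missing-ligand rule (donor Bw4+,
  patient Bw4−) is available as `mismatch_direction =
  donor_positive_patient_negative`.  The clinical literature motivates the
  one-sided rule, but the binary-status-differs reading is the more
  conservative default given that a "same epitopes ⇒ KIR matched"
  definition is symmetric; both are implemented and tested.
* **Scenario 2** builds keys over the four HLA-A/-B slots only (drop budget
  4 − `min_matches`), then filters join candidates with the full predicate:
  both genotypes carry the restricting allele (default A\*02:01), and for
  every locus at which the donor is homozygous for some allele x the
  patient must not carry x (applied at all five loci — "any HLA allele").
  The A/B match count is kept as per-pair metadata for priority weighting.
  Coverage percentages are always reported against the *total* population
  weight, not the eligible (A\*02:01⁺) subset.
* **Scenario 3** expands each donor into its full product plus one variant
  per distinct allele slot with that allele removed (≤10 knockouts; fewer
  with homozygosity).  A variant covers a patient iff, per locus, its
  remaining allele *set* is a subset of the patient's (so a donor
  homozygous at a locus matches a heterozygous patient carrying that
  allele).  Variants join patients directly through an index of all
  per-locus non-empty allele subsets of each patient genotype (≤3⁵ keys per
  genotype).

## Stage 2: solvers

* **Greedy** — lazy (heap-accelerated) weighted greedy; valid because a
  donor's uncovered gain only shrinks as coverage grows.  Ties break toward
  the lowest donor index for reproducibility.  With a scenario-2 priority,
  the gain is Σ *p<sub>i</sub>* · Prior(*i*) with Prior = `prior4` for 4/4
  A/B matches and 1 otherwise; the stopping rule still uses plain covered
  weight.
* **Cost-aware greedy (scenario 3)** — per iteration, the best knockout
  covers uncovered weight S<sub>K</sub>; a mini-greedy over full products
  finds the fewest N<sub>G</sub> whose union covers ≥ S<sub>K</sub>
  (reaching S<sub>F</sub>).  The knockout is taken iff its cost per covered
  patient, (`cost_ko`+1)/S<sub>K</sub>, is strictly below
  N<sub>G</sub>/S<sub>F</sub>; both ratios are logged per iteration for
  audit.
* **LP relaxation** — `scipy.optimize.linprog` (HiGHS) on the same sparse
  constraints with x, y ∈ [0,1].  The fractional objective is reported as a
  lower bound on any integer selection's cost and never rounded into a
  selection (one cannot take half a donor).
* **ILP** — `scipy.optimize.milp` (HiGHS branch-and-bound) with binary
  x and *continuous* y ∈ [0,1]: with integer x the coverage indicators are
  free to reach their bounds, so the optimum is unchanged while the search
  tree stays smaller.  Default time limit 300 s; on expiry the incumbent is
  returned flagged non-optimal.
* **Random baseline** — donors drawn uniformly without replacement until
  the target is met; 5 trials by default, reported as per-trial counts and
  costs with mean and sample standard deviation.  For scenario 3 the draw
  can include knockout variants or be restricted to full products.

Selections are re-scored from scratch (`evaluate_coverage`, union
semantics: overlapping S<sub>j</sub> count each patient once), so reported
objectives never rely on solver-internal bookkeeping.

## The synthetic registry

The generator emulates the registry features the optimization is sensitive
to, at desk scale:

* **Haplotype-level simulation.**  Individuals are unions of two i.i.d.
  haplotype draws (random mating), so genotype (h<sub>i</sub>,h<sub>j</sub>)
  arises at 2f<sub>i</sub>f<sub>j</sub> (i≠j) and linkage disequilibrium
  exists by construction — per-locus independent allele draws would make
  "rare donors that cover many patients" impossible.
* **Heavy-tailed frequencies.**  Haplotype rank k gets weight
  (k + offset)<sup>−shape</sup> (Zipf–Mandelbrot), default shape 1.5 and
  offset 10, putting ~5% of mass on the top haplotype and making duplicate
  genotypes (p<sub>i</sub> > 1) common at n = 10⁴.  A pure Zipf law
  (offset 0, also available) concentrates ~38% of mass on one haplotype —
  far beyond any published registry spectrum — and degenerates the
  experiments.  A symmetric Dirichlet law is available as an alternative.
* **Allele panels.**  Default panel sizes A 15 / B 25 / C 12 / DQB1 4 /
  DRB1 7 at two-field resolution, drawn within haplotypes with 1/rank
  weights so common alleles recur across haplotypes.  The small class-2
  panels stand in for the near-absolute DRB1~DQB1 linkage of real
  populations, where a few dozen class-2 blocks carry most of the mass;
  with large independent class-2 panels, exact class-2 matching (scenario
  1) becomes unrealistically rare.
* **Bw4 annotation.**  Each distinct A/B allele is flagged independently
  with probability 0.3 (roughly the fraction of common B alleles carrying
  Bw4), giving mixed Bw4⁺/Bw4⁻ populations; for real data a curated allele
  list is supplied by file.
* **Cross-population pairs.**  `derive_overlapping_table` keeps the top
  ⌈s·H⌉ source haplotypes (populations share their *common* haplotypes) and
  replaces the rest with novel ones scattered across the whole re-drawn
  rank spectrum, the kept ranks jittered so shared frequencies are
  correlated but not equal.  With s = 0.5 about half the derived
  population's mass sits on haplotypes the source lacks.

What the generator does **not** emulate: typing ambiguity and imputation
error, multi-race mixture structure, empirical allele/haplotype identities,
realistic Bw4 allele lists, and the fine-grained class-2 diversity of real
registries.  Passing tests therefore show that the algorithms behave
correctly and that the qualitative contrasts (optimal ≪ random;
cross-population robustness of optimal selection; the knockout regime)
reproduce under registry-*like* statistics — not that specific published
counts would be reproduced on real data.

## Experiment designs used by the tests and the acceptance script

* **Algorithm comparison (scenario 1).**  n = 10,000 individuals, donor
  pool = patient pool, 50% coverage target: greedy vs 5-trial random mean
  vs LP/ILP.  Across probed seeds greedy equals the ILP count and is
  several-fold below the random mean.
* **Cross-population contrast (scenario 3).**  Same 10,000-donor pool;
  patients either the same pool or 10,000 individuals from a 50%-overlap
  table.  At 25% coverage the full-only random baseline inflates several-
  fold cross-population while the greedy cost barely moves.  Knockout
  products are examined at a coverage demand halfway between the
  cross-population *full-match frontier* (the fraction reachable by full
  products alone) and the knockout-extended frontier: by construction of
  the cost model this is the regime where gene editing becomes necessary,
  and the exact solver selects knockouts cross-population while the
  same-population run at the identical demand needs none.  A fixed demand
  below the frontier would be served entirely by full products in either
  population and show nothing.
* **Solver exactness.**  ILP solutions equal subset-enumeration minima on
  random instances with ≤12 donors; LP ≤ ILP ≤ greedy throughout; truncated
  greedy attains ≥ (1 − 1/e) of the enumerated optimum at fixed budgets;
  the three-set instance {1,2},{2,3},{1,3} exhibits the classic 1.5 vs 2
  integrality gap.

Problem sizes in the default test run (10⁴ individuals, ≤12-donor
enumeration instances) keep the whole suite under a minute while leaving
every qualitative contrast with a wide margin.

## Numerical and degenerate-input choices

* Allele fields beyond two are truncated with a warning; within-locus
  allele order is canonicalized (sorted) so equality and hashing are
  phase-free; files use the fixed locus order A, B, C, DQB1, DRB1.
* Haplotype frequencies must be positive and sum to 1 within 1e-9.
* Greedy uses a 1e-12 slack when comparing stale heap gains; LP/ILP
  comparisons in reports use the recomputed integer-weight coverage, not
  solver floats.
* Infeasible targets raise a structured error carrying the maximum
  achievable coverage; the CLI maps it to exit code 2 (3 for an ILP
  time-limit incumbent).
* All randomness flows from named integer seeds (population, sampling,
  baseline, overlap derivation); identical configuration and seeds
  reproduce byte-identical files and reports.

## Known limitations

Single-allele knockouts only (no multi-edit products); no ambiguity-aware
(posterior-weighted) matching; no antigen-level vs allele-level
distinction; no per-subpopulation coverage constraints; the LP bound is
reported but not used to certify greedy gaps; scenario-1 Bw4 semantics
depend entirely on the supplied allele list.
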