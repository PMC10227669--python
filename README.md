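# hlacover

**Sizing allogeneic cell-therapy donor banks by HLA genotype coverage
optimization.**

Off-the-shelf cellular therapies (NK cells, TCR-transduced T cells,
polyclonal T-cell products) are manufactured from healthy donors and given
to HLA-mismatched patients under treatment-specific compatibility rules.  A
central design question for anyone building such a bank is: *how many
donors — and which ones — are needed so that a target fraction of the
patient population has at least one compatible product?*

`hlacover` answers this in two stages:

1. **Matching (stage 1).** For every donor genotype *d<sub>j</sub>* compute
   the set *S<sub>j</sub>* of patient genotypes it can treat.  Genotypes are
   5-locus UMUGs (one unordered pair of two-field alleles at HLA-A, -B, -C,
   -DQB1, -DRB1).  Instead of an all-pairs scan, both pools are expanded
   into *reduced keys* — class-restricted genotype projections with up to
   *a* (class 1) / *b* (class 2) allele slots dropped.  Two genotypes share
   a key with *k* dropped slots iff their mismatch count in that class is
   ≤ *k*, so coverage is a hash-join on keys.
2. **Selection (stage 2).** With patient weights *p<sub>i</sub>*
   (occurrence counts), choose donors *x<sub>j</sub>* ∈ {0,1} minimizing
   Σ *c<sub>j</sub>x<sub>j</sub>* subject to Σ *p<sub>i</sub>y<sub>i</sub>*
   ≥ *P* and *y<sub>i</sub>* ≤ Σ<sub>j: i∈S<sub>j</sub></sub>
   *x<sub>j</sub>* — weighted partial set cover.  Four solution routes:
   lazy **greedy**, the **LP relaxation** (a cost lower bound, never rounded
   into a selection), the exact **ILP** (HiGHS branch-and-bound), and a
   5-trial uniform **random baseline**.

Three clinical matching scenarios are built in:

| Scenario | Rule | Objective |
|---|---|---|
| 1 — NK cells | donor KIR-Bw4-ligand mismatched to patient, full class-2 match, class 1 free | min donors |
| 2 — TCR T cells | both carry A\*02:01; donor not homozygous at any locus for an allele the patient carries; ≥3/4 HLA-A/-B matches (optional priority for 4/4) | min donors |
| 3 — polyclonal T cells | every donor allele present in the patient (subset match); a single allele may be knocked out by gene editing at cost `cost_ko` extra donors | min total cost |

Registry-scale genotype data is rarely shareable, so the package includes a
synthetic-population generator with the statistical structure that matters:
heavy-tailed haplotype frequencies (Zipf–Mandelbrot), linkage via
haplotype-level simulation, random-mating genotypes, duplicate merging with
occurrence weights, Bw4 annotation, and pairs of populations with a
controllable shared-haplotype fraction for cross-population experiments.

## Worked example

Generate a synthetic registry of 2,000 individuals (donor pool == patient
pool), then size an NK-cell (scenario 1) bank for 50% population coverage:

```sh
hlacover synth -O out_dir=data -O seed=42 -O n_donors=2000 -O n_patients=2000
# wrote data/donors.tsv (1481 distinct), data/patients.tsv (1481 distinct)

hlacover optimize -O donors=data/donors.tsv -O patients=data/patients.tsv \
    -O scenario=scenario1 -O bw4_file=data/bw4.txt \
    -O algorithm=greedy -O target_fraction=0.5 -O report=greedy.json
```

The report (`greedy.json`) shows greedy needs **37 donors** for **50.6%**
coverage; the exact ILP also needs 37, and the 5-trial random baseline needs
151–183 (mean **172.6 ± 13.4**) — optimal selection is ~4.7× more efficient
here.  The per-iteration log doubles as a coverage curve
(`greedy.curve.tsv`):

```
n_selected  cumulative_fraction
1           0.031500
2           0.062500
3           0.087000
...
```

The same pipeline is available as a library:

```python
import hlacover as hc

table = hc.generate_haplotype_table(hc.PopulationConfig(seed=42))
donors = hc.sample_population(table, 2000, seed=43, role=hc.PoolRole.DONOR)
patients = hc.GenotypePool(donors.entries, hc.PoolRole.PATIENT)
bw4 = hc.generate_bw4_table(table, 0.3, seed=44)

criteria = hc.MatchCriteria(scenario="scenario1",
                            scenario1=hc.Scenario1Config(bw4))
cov = hc.build_coverage(donors, patients, criteria)      # stage 1
result = hc.greedy_select(cov, patients, target_fraction=0.5)  # stage 2
print(len(result.selected), result.coverage_fraction)
```

`hlacover sweep` repeats a configuration across population sizes (with
`cross_population: true` the donor pool stays fixed while patient pools are
drawn from an overlapping-but-different haplotype table) and writes a
donors-needed-versus-size table.

## File formats

* **Genotype tables** — tab/comma-separated, header `id  genotype  weight`;
  genotypes as `A*01:01+A*02:01^B*07:02+B*08:01^...` (locus blocks joined by
  `^`, alleles by `+`, fixed order A, B, C, DQB1, DRB1).
* **Haplotype frequencies** — CSV `haplotype,frequency`, alleles joined by
  `~`.
* **Bw4 lists** — one A/B allele per line.

## Limitations

Matching operates on fully-typed, unambiguous two-field genotypes; typing
ambiguity, imputation posteriors and loci beyond the five used here are out
of scope, as are directionally asymmetric mismatch counting and
antibody-mediated rejection.  See `docs/methods.md` for the model details,
generator assumptions and numerical choices.
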