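# condld

Estimation of the two-locus linkage-disequilibrium coefficient **D** from 3×3
genotype count tables, built for samples that were **not** collected at random
— genotype-class exclusions and case–control ascertainment in particular.

Two estimators are provided:

* **Method L (conditional)** — maximises the conditional likelihood of the
  disease genotype given the marker genotype, with the allele frequencies
  `(p, q)` supplied externally (population survey, controls, …). Because the
  likelihood conditions on the classes actually sampled, the estimate always
  lies inside the theoretical bounds
  `[max(−pq, −(1−p)(1−q)), min(p(1−q), (1−p)q)]` and is robust to how many
  individuals of each class entered the sample.
* **Method H (joint)** — the classical joint-likelihood estimator
  (chromosome-counting EM / cubic stationarity equation, `D̂ = ĝ₁₁ − p̂q̂`).
  It assumes random sampling; a `replication` mode runs the literal counting
  iteration with externally supplied frequencies and flags estimates of
  `g₁₁` that leave their theoretical interval — reproducing the failure mode
  of this estimator on ascertained samples.

Both come with a 1-df likelihood-ratio test (`lambda = 2(ℓ(D̂) − ℓ(0))`,
`lod = lambda / (2 ln 10)`, chi-square p-value). A useful identity to know:
with **both** `p` and `q` plugged in from the *same* sample, the conditional
and joint log-likelihoods differ only by terms free of `D`, so the two
estimators coincide; they separate exactly when frequencies come from
different sources (controls, surveys), which is the ascertained-data setting
the conditional method is for.

The package also contains a Monte-Carlo simulator of three sampling schemes
(random; genotype-class-excluded; case–control), auxiliary statistics
(r², Hardy–Weinberg chi-square, case–control allelic chi-square), TSV
readers/writers, a pairwise LD-scan driver and a CLI.

## Layout

```
src/condld/core.py          parameter types, count tables, bounds, r², HWE/allelic tests
src/condld/conditional.py   Method L: conditional probabilities, likelihood, MLE, LRT, q-profile
src/condld/joint.py         Method H: joint distribution, EM, cubic, MLE, LRT
src/condld/sampler.py       sampling schemes I/II/III and the replicated-study driver
src/condld/io.py            count-table / genotype-matrix / config file formats
src/condld/scan.py          pairwise LD scan against a focal locus
src/condld/cli.py           `condld` command-line interface
```

## CLI

```sh
# estimate D from a count table (TSV, rows MM/Mm/mm, columns AA/Aa/aa)
condld estimate --counts counts.tsv --method L --q 0.03
condld estimate --counts counts.tsv --method H --h-mode strict --json

# replicated simulation study from a key = value config file
condld simulate --config sim.cfg --out summary.tsv

# scan every locus of a genotype matrix against a focal (disease) locus
condld scan --matrix panel.tsv --focal focal --method L --p-from controls --q 0.03

# LOD profile of the estimate over a grid of disease allele frequencies
condld profile --counts counts.tsv --q-grid 0.01:0.10:0.01
```

Genotype matrices are TSV with an `id` column, one column per locus holding
0/1/2 (copies of the designated allele) or `.` for missing, and an optional
trailing `status` column (`case`/`control`). A simulation config looks like:

```
scheme = III
p = 0.5
q = 0.01
D = 0.004
n = 200
n_case = 100
n_control = 100
q_mode = survey
reps = 1000
seed = 1
```

Validation errors exit with status 2.

## Notes

* `GenotypeCountTable` accepts fractional cells so that noise-free
  expectation tables (`n ×` joint probabilities) can be analysed directly.
* `replicate_study` gives Method L the generating population frequencies in
  Schemes I/II by default (`l_freq_source="population"`); pass `"sample"` to
  feed both methods the same per-sample allele counts, in which case their
  estimates coincide by the identity above.
* Degenerate (monomorphic) inputs return `D̂ = 0` with a `degenerate` flag
  rather than raising, since monomorphic loci occur in scans.
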