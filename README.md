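# xlinkrates

Maximum-likelihood estimation of recombination rates between adjacent
X-chromosomal markers (and per-marker mutation rates) from pedigree genotype
data, with a pedigree simulator for validation.

Recombination on the X chromosome is observed only through female meioses.
The package extracts two kinds of informative families from an arbitrary
pedigree:

* **type I** — a mother phased via her own genotyped father (the children's
  maternal grandfather) plus one or more children whose maternal haplotype is
  observable (sons directly; daughters by subtracting the father's haplotype);
* **type II** — a mother of unknown phase with two or more such children,
  whose likelihood sums over all compatible maternal phasings.

The exact family likelihood sums over every inheritance vector with a
single-step STR mutation kernel (a mutation changes the repeat count by
exactly one unit) or, for non-STR markers such as SNPs and INDELs, a 9:1
transition/transversion kernel.  Two engines compute the same value: a
literal exponential enumeration (reference, refused beyond 20 markers) and a
linear-time forward recurrence with rescaling that handles chromosomes with
tens of thousands of markers.  Type II families branch depth-first through
the maternal phasings, sharing partial forward states and pruning
zero-likelihood branches early.  Rates are estimated by minimizing the
dataset negative log-likelihood with L-BFGS-B under box constraints
(rates in (0, 0.5]).

## Command line

Estimate rates from a PLINK PED file in one command:

```sh
xlinkrates estimate --ped data.ped --out-prefix run1
# writes run1.rates.tsv (theta per marker interval, mu per marker)
# and run1.report.txt (family counts, warnings, convergence diagnostics)
```

Useful flags: `--marker-info markers.tsv` (tab-separated `name`/`type`
columns, type in `STR`/`POLY`, overriding the inferred marker names/types),
`--mu-mode {per-marker,shared,fixed}`, `--fix-mu 0.001`,
`--engine {dynamic,direct}`, `--max-markers-typeii N` (guard against the
exponential type II phasing sum).  Exit codes: 0 success, 3 parse error,
4 no informative families, 5 non-convergence, 6 refused by the marker guard.

Simulate pedigrees with known rates:

```sh
xlinkrates simulate --out-prefix sim --n-markers 12 \
    --n-typei 100 --n-typeii 100 --theta 0.05 --mu 0.001 --seed 1
# writes sim.ped and sim.truth.tsv (true phases, inheritance vectors,
# mutation events)
```

Evaluate the dataset negative log-likelihood at fixed rates:

```sh
xlinkrates loglik --ped sim.ped --theta 0.05 --mu 0.001
```

## Library

```python
from xlinkrates import (
    parse_ped, build_family_graphs, extract_families,
    estimate_rates, EstimationConfig,
)

panel, individuals = parse_ped("data.ped")
families = extract_families(build_family_graphs(individuals))
result = estimate_rates(families, panel, EstimationConfig(mu_mode="per-marker"))
print(result.theta_hat, result.mu_hat, result.converged)
```

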