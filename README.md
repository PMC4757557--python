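# aplnet

Mutation-prioritization analysis for small leukemia cohorts: somatic
variant filtering with an auditable cascade, gene recurrence enrichment
against a reference population, functional-category burden and co-mutation
analysis, pairwise co-occurrence networks, and interactome-based
candidate-gene prioritization with a resampling null — plus synthetic-data
generators so every stage can be exercised and validated without any
external download.

## The scientific problem

Acute promyelocytic leukemia (APL) is defined by the *PML/RARA* fusion, but
the fusion alone does not produce the full leukemic phenotype, and the
cooperating mutations are scattered: cohort sequencing finds many mutated
genes, few of them recurrent. With cohorts of 25–30 patients, single-gene
recurrence statistics are underpowered, so the analysis leans on three
complementary signals:

1. **Recurrence enrichment.** A gene mutated in $k$ of $n$ patients is
   compared against its carrier frequency $f_0$ in a healthy reference
   population with the one-sided exact binomial tail
   $P(X \ge k),\; X \sim \mathrm{Bin}(n, f_0)$. Genes absent from the
   reference are floored at $f_0 = 1/(N_{\mathrm{ref}}+1)$.
2. **Co-occurrence.** For every gene pair, the $2{\times}2$ carrier table
   is tested with the uncorrected chi-square statistic
   $\chi^2 = n\varphi^2$ (1 df); significant pairs form a network whose
   edges carry the co-mutated sample count and whether it sits above or
   below the independence expectation $n p_1 p_2$.
3. **Interactome connectivity.** The recurrently mutated genes are mapped
   onto a protein–protein interaction graph and their *minimal connected
   network* (MCN) is built: all direct seed–seed edges plus any non-seed
   intermediate adjacent to two or more seeds whose pair lacks a direct
   edge (one intermediate allowed per length-2 path), pruned to a
   minimum-cardinality intermediate set. Connectivity (connected seed
   count, component count, mean seed degree) is scored against $M$ random
   seed sets with the add-one empirical p-value
   $p = (1 + \#\{T_{\mathrm{null}} \ge T_{\mathrm{obs}}\})/(M+1)$.

Candidate drivers are the genes that are **both** recurrence-enriched and
members of a significantly connected network module.

Upstream of all three sits a seven-stage somatic filter cascade (detected →
somatic → absent in complete remission → high quality → coding →
deleterious → unknown in dbSNP) with a per-patient, per-stage audit table,
matched-remission subtraction or a germinality heuristic for unmatched
samples, and Ti/Tv spectrum summaries.

## Worked example

Simulate a 25-patient cohort (50 genes, background carrier rate 0.08) with
five genes planted at 4× the background rate and as a dense interactome
module, then run the full prioritization:

```sh
aplnet simulate --out-dir sim --seed 7
aplnet prioritize --matrix sim/matrix.tsv --reference sim/reference.tsv \
    --interactome sim/interactome.sif --seed 7 -M 999 --out-dir run1
aplnet report --run-dir run1
```

prints (abridged):

```text
MCN connected_seed_count: observed 5, p=0.01 (999 null draws, seed 7)

Prioritized candidates (5):
gene  k  n  enrichment_p  cooccurrence_degree
G003  9 25      0.000084                    4
G002  8 25      0.000523                    4
G004  8 25      0.000523                    0
G001  6 25      0.012293                    3
G000  5 25      0.045144                    3
```

The five planted genes (G000–G004) are recovered exactly: each is mutated
in 5–9 of 25 patients (columns `k`/`n`), far above the reference rate
(binomial `enrichment_p`), and the five together form a module whose
connectivity exceeds all but 1% of random seed sets of the same size
(`p=0.01`). Re-running with the same seed reproduces every output file
byte for byte.

The same machinery runs on the bundled published-style screen table
(15 recurrently mutated APL genes vs the 1000-genomes reference, 25
patients):

```python
from aplnet import screen_cohort
from aplnet.datasets import load_screen_cohort_matrix, load_screen_reference

for r in screen_cohort(load_screen_cohort_matrix(), load_screen_reference())[:4]:
    print(f"{r.gene:10s} k={r.k:2d}/25  f0={r.f0:.4f}  p={r.p_value:.3g}  q={r.q_value:.3g}")
```

```text
HERC1      k=11/25  f0=0.0300  p=5.35e-11  q=8.02e-10
SMC1A      k= 3/25  f0=0.0000  p=1.45e-07  q=1.09e-06
USP9X      k= 3/25  f0=0.0009  p=1.65e-06  q=8.26e-06
CACNA1E    k= 4/25  f0=0.0060  p=1.48e-05  q=5.56e-05
```

All 15 genes clear the 0.05 screen threshold (`q` is the
Benjamini–Hochberg value reported alongside).

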