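# ervphylo

Phylogenetic analysis of endogenous retrovirus (ERV) insertion and
solo-LTR formation across six primate genomes.

## The problem

ERVs integrate as full-length proviruses — internal retroviral genes
flanked by a pair of initially identical long terminal repeats (LTRs) —
and are later reduced to *solo-LTRs* when the paired LTRs recombine and
delete the internal region. Most ERV loci in primate genomes are solo-LTRs,
so any account of retroviral activity based only on full-length elements
depends critically on how fast, and how age-dependently, this deletion
process runs. `ervphylo` is for researchers in molecular evolution who want
to estimate branch-specific insertion rates and deletion dynamics jointly
from presence/absence/solo-LTR calls at orthologous loci, rather than from
LTR–LTR divergence dating.

## The model

Observations are **site patterns**: per-locus vectors
`U = (u_1, …, u_6)ᵀ` over `{0, 1, x}` (absent, full-length/partial
provirus, solo-LTR) in the fixed order human, chimp, gorilla, orangutan,
macaque, marmoset, on a chronogram with branches
`h, c, g, o, m, hc, hcg, hcgo, hcgom` (marmoset is the outgroup; `u_6 = 0`
always). The only permitted history is `0 → 1 → x`, so the non-0 positions
of a coherent pattern determine the insertion branch uniquely.

* **Insertion** on branch *i* is Poisson with rate `Φ_i` per Myr; with
  `φ_i = Φ_i T_i` the insertion likelihood is `∏_i e^{−φ_i} φ_i^{N_i} / N_i!`
  and the MLE is the closed form `Φ̂_i = N_i / T_i`.
* **Deletion** is a renewal of age since insertion: exponential
  (`S(a) = e^{−ψa}`, constant hazard) or Weibull
  (`S(a) = exp[−(a/ψ_w)^ω]`, hazard `∝ a^{ω−1}`, so `ω < 1` means young
  proviruses are deleted fastest). The exponential model is the `ω = 1`
  submodel. On the insertion branch the insertion time is uniform, giving
  the closed form `Pr(0→x) = 1 + (e^{−ψt} − 1)/(ψt)` (exponential) and an
  incomplete-gamma expression (Weibull); on post-insertion branches the
  retention probability is the uniform average of the survival ratio
  `S(t_2 − t_i)/S(t_1 − t_i)`, which collapses to `e^{−ψ(t_2−t_1)}` for the
  exponential model by memorylessness.
* **Pattern likelihoods** sum over all internal-node states consistent with
  `0 → 1 → x` using a pruning-style dynamic program that tracks cumulative
  time from the insertion-branch origin (needed because the Weibull process
  is age dependent).
* Models are compared with a likelihood-ratio test
  (`2Δℓ = 2(ℓ_w − ℓ_e)` vs the χ²₁ cutoff 10.83), uncertainty comes from a
  case-resampling bootstrap, and adequacy from forward simulation plus a
  Monte-Carlo exact test on observed-vs-simulated pattern frequencies.
* A **Wright–Fisher** module simulates a new insertion segregating in a
  diploid population while mutations accumulate across its paired LTRs,
  quantifying how quickly LTR–LTR differences (which suppress the
  recombinational deletion pathway) arise relative to fixation.

The package also implements the upstream **pattern extraction** pipeline:
a 6×m classification matrix over `{d, g, s-id, c-id}` built from per-species
repeat annotations on a six-way alignment, collapse of identical-column
runs (≥ 50 bp) into pre-patterns, scanning for anchored candidate windows,
the four-rule coding heuristic, and the flank/backing/85%-relabel filters —
plus a fixture generator with known ground truth.

## Worked example

Fit both deletion models to a synthetic HERV-H-like family generated at
the reference study conditions:

```python
import ervphylo as e
from ervphylo.simulate import generate_synthetic_study
from ervphylo.patterns import count_insertions

tree = e.default_tree()
pats = generate_synthetic_study(seed=7)["HERV-H"]       # 122 patterns
counts = count_insertions(pats, tree)
rates = e.fit_insertion_rates(counts, tree)

fe = e.fit_deletion(pats, tree, model="exponential", seed=0)
fw = e.fit_deletion(pats, tree, model="weibull", seed=0)
cmp_ = e.likelihood_ratio_test(fe, fw)

print(fe.params.psi, fe.log_likelihood)      # 0.066  -119.17
print(fw.params.inv_scale, fw.params.omega,  # 0.128  0.255
      fw.log_likelihood)                     # -108.25
print(cmp_.statistic, cmp_.favors_weibull)   # 21.83  True
print(100 * e.survival(fw.params, 0.4))      # 62.6 (% full-length at 0.4 Myr)
print(100 * e.survival(fw.params, 25.0))     # 26.1 (% full-length at 25 Myr)
```

Reading the output: the exponential fit says HERV-H-like loci are deleted
at a constant 0.066/Myr, but the Weibull fit (shape 0.255 « 1) is better by
2Δℓ = 21.83 — far beyond the 10.83 cutoff — meaning the deletion hazard
drops steeply with age: most survivors of the first ~0.5 Myr remain
full-length for tens of Myr. The survival percentages are the fitted
model's predictions at the neutral-fixation timescale (0.4 Myr) and at the
depth of the phylogeny (25 Myr).

The same analyses are available from the shell:

```bash
ervphylo synth --seed 7 --out-dir study/
ervphylo lrt study/HERV-H.tsv
ervphylo gof study/HERV-H.tsv --branch hcgom --params '{"model":"weibull","psi":7.8,"omega":0.18}'
ervphylo wf --pop-size 1000 --mutation-rate 1e-7 --n-fixations 2000
```

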