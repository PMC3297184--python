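# flaxnet

Haplotype-network analysis of a candidate crop-domestication locus.

Crop domestication leaves a locus-specific signature: cultivated
lineages carry a subset of the wild diversity at genes that were under
selection, ancestral haplotypes often remain extant, and recombination
among lineages shows up as character conflict.  `flaxnet` takes an
aligned gene region (e.g. the *sad2* stearoyl-ACP desaturase locus of
wild and cultivated flax) together with sample group labels and
produces, end to end:

* **Diversity statistics** per group and region: segregating sites S,
  haplotype number H, nucleotide diversity π, Watterson's θ, Tajima's
  D, Fu & Li's D*/F*, and the Hudson–Kaplan four-gamete lower bound
  R_m on recombination events;
* **A reticulate parsimony network** (median-joining, ε = 0) over the
  substitution characters plus any multi-base indel coded as a single
  character, with mutation-labelled edges, median nodes, reticulation
  cycles, and the domestication common ancestor (DCA) — the node with
  the shortest total parsimony path to all cultivated haplotypes;
* **Recombination significance tests**: under uniform mutation the
  probability that a mutation is homoplasious (same site, same derived
  base) is p = (1/3)(1/L)·m for a network of m substitutions over L
  sites, so E = m²/(3L) homoplasies are expected; each reticulation
  branch with N substitutions and H homoplasies is scored with the
  upper-tail binomial P(X ≥ H | N, p), and the network-wide count with
  Binomial(m, p);
* **Calibrated node dating**: one node of known age T fixes the clock
  r = k/(L·T) (substitutions/site/year) from its substitution depth k,
  and every node is dated as age = d/(r·L);
* **A synthetic-data generator** producing alignments with known
  genealogy, planted homoplasies, recombinant mosaics, an indel, and
  group-structured sampling, plus a truth record that replays to a
  byte-identical alignment.

## Worked example

Simulate a survey-scale dataset (113 samples, 2560 bp, 11 haplotypes,
one recombinant, one 46-bp indel) and run the full pipeline, dating the
network with the main cultivated node IX calibrated to 10,000 years:

```sh
flaxnet simulate --preset --out demo/sim
flaxnet run \
  --alignment demo/sim/alignment.fasta --groups demo/sim/groups.tsv \
  --cultivated Lu-o --cultivated Lu-f --cultivated Lu-w \
  --cultivated Lu-n --cultivated Lu-d \
  --calibration node=IX,age=10000 --out demo/run
```

`demo/run/summary.json` then contains (abridged):

```json
{
 "n": 113, "L": 2560, "S": 36, "n_haplotypes": 11,
 "pi_per_bp": 0.00368, "tajima_D": 1.12, "Rm": 5,
 "network": {"m": 43, "H_net": 7, "dca_node": "H09",
             "P_net_point": 4.54e-09},
 "events": [{"event": "R1", "N": 2, "H": 2,
             "P_binom": 3.13e-05, "significant_01": true}]
}
```

Read: the 113 sequences collapse to 11 haplotypes with 36 segregating
sites; overall diversity π = 0.00368/bp with a positive Tajima's D
(wild groups hold intermediate-frequency variation that the
bottlenecked cultivated groups lack).  The network carries m = 43
substitution occurrences of which H_net = 7 are homoplasies — far more
than the E = m²/(3L) ≈ 0.24 expected from repeat mutation
(point probability 4.5 × 10⁻⁹) — and its one reticulation tests at
P = 3.1 × 10⁻⁵, so recombination, not repeat mutation, explains the
conflict.  `chronology.tsv` dates every node; with node IX (depth 11.7
substitutions) pinned at 10,000 years the rate is 4.6 × 10⁻⁷
subs/site/year and, e.g., haplotype I dates to ≈ 5100 years.  The
deepest reported statistics match the planted truth record written by
the simulator.

Each stage is also available separately (`flaxnet stats`, `network`,
`events`, `date`, `validate`), and the library functions
(`flaxnet.segregating_sites`, `build_network`, `homoplasy_model`,
`branch_test`, `calibrate_and_date`, …) expose the same computations to
Python.

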