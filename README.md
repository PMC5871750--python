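# dhrcall

Windowed ChIP-seq analysis of **sperm histone retention**: calling
differential histone retention regions (DHRs) between control and exposure
lineages, conserved and universal-core retention sites from read-depth
thresholds, individual-level reproducibility, and gene association — with a
seeded synthetic-data generator so the whole pipeline can be validated
against planted truth without any sequencing data.

## Background

During spermatogenesis most histones are replaced by protamines; only a
small fraction of the genome retains nucleosomes in mature sperm. Histone
ChIP-seq read depth therefore marks *retention sites*, and differences in
per-window coverage between an exposure lineage and its control mark
*differential* retention regions. The analysis operates entirely on fixed
100 bp genome windows:

1. **Count.** The genome is tiled into 100 bp windows; each mapped chromatin
   fragment increments every window it overlaps. This yields a
   window × sample count matrix `Y` with group labels.
2. **Test.** For each window, a two-sided conditional negative-binomial
   exact test compares the groups. Samples are scaled to a common effective
   library size; scaled counts are summed within groups; conditional on the
   grand total `n = y_A + y_B`, the group-A total follows

   `P(Y_A = k | n) ∝ C(k + r_A − 1, k) · C(n − k + r_B − 1, n − k)`,
   `r_g = w_g / φ`,

   where `w_g` is the group's summed effective size and `φ` the common NB
   dispersion (`Var = μ + φμ²`), estimated by maximizing the summed
   conditional log-likelihood over windows. For `φ = 0` the law is
   `Binomial(n, w_A/(w_A + w_B))`. The p-value is the total probability of
   all outcomes no more likely than the observed one.
3. **Call DHRs.** Windows with `p` below a stringent cutoff (10⁻⁷ or 10⁻⁶
   depending on the comparison) seed regions; edges are extended to absorb
   any window with `p < 0.1` within 1000 bp of an edge, iterated to a
   fixpoint, and touching regions merge.
4. **Call retention sites.** A window qualifies as *retained* when its raw
   count reaches 150 reads (alternate 25) in every sample of a group
   (conserved sites) or in a single sample (individual sites); qualifying
   windows merge and extend with the same 1000 bp rule. The *universal core*
   is the subset of a representative group's conserved sites overlapping a
   site in every other group.
5. **Summarize.** Threshold sweeps (all DHRs vs DHRs with ≥ 2 significant
   windows), window-level Venn partitions across individuals, site-set
   overlaps, length histograms, and genes overlapping or within 10 kb of a
   site edge.

## Worked example

Simulate a small dataset with planted truth (one 1 Mb chromosome, 8 core
sites, 5 exposure-gained differential sites, 3 pools per group) and run the
full analysis:

```python
from dhrcall import SimulationSpec, AnalysisParams, cmd_simulate, cmd_run

spec = SimulationSpec(chrom_lengths={"chr1": 1_000_000}, n_core_sites=8,
                      n_differential_sites=5, seed=4)
cmd_simulate("demo/sim", spec)
res = cmd_run("demo/sim/chrom.sizes", "demo/sim/manifest.tsv", "demo/out",
              params=AnalysisParams(dhr_p_threshold=1e-6))
print(res["dhrs"].sites)
```

which prints

```
  chrom   start     end  n_sig_windows      score  length_kb
0  chr1  201200  203800             15  19.509571        2.6
1  chr1  225000  226300             11  22.150444        1.3
2  chr1  499400  500700              9  19.024716        1.3
3  chr1  851300  856600              9  15.666426        5.3
4  chr1  933400  937300             28  23.369547        3.9
```

— the five called DHRs, one per planted differential site: `n_sig_windows`
counts seed windows below the 10⁻⁶ cutoff inside each region, `score` is
−log₁₀ of the smallest window p-value, and the coordinates are window-aligned
half-open intervals after edge extension. The estimated common dispersion
was `φ̂ = 0.0173`, the conserved-site caller found all 8 planted core sites
in both groups (and their intersection), and the threshold sweep
(10⁻⁴ … 10⁻⁸) gave monotone counts 6, 5, 5, 5, 5.

The same stages are available from the shell:

```bash
dhrcall simulate --seed 4 --out demo/sim
dhrcall run --chrom-sizes demo/sim/chrom.sizes --manifest demo/sim/manifest.tsv \
            --dhr-p 1e-6 --out demo/out
```

Outputs are plain TSV/BED files (count matrix, per-window p-values, DHR and
conserved/core BEDs, sweep table, Venn partition, gene annotations), each
with a header line echoing the parameters.

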