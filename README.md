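# splicedisp

Sequence-composition analysis of human acceptor splice sites through the
**dispersion of hexamer subsets**.

Canonical introns end in AG at the acceptor (3′) splice site. Around that
junction the DNA is far from random: a pyrimidine-rich tract runs in from
upstream, the core carries the splicing signal, and the downstream exon has
its own composition. `splicedisp` quantifies this structure — and the
differences between splicing modes — with a subset-dispersion statistic
over hexamers, for anyone studying splice-site sequence composition or
building features for splice-site prediction.

## The statistic

All 4⁶ = 4096 hexamers are partitioned, for each dinucleotide XY, into the
**XY1** subset (hexamers containing XY as a contiguous substring) and the
complementary **XY0** subset — 1185/2911 when X ≠ Y and 991/3105 when
X = Y. Windows of 100 bp are aligned on the splice junction with
zero-skipping site labels −50..−1, +1..+50 (A and G sit at −2/−1). A
6-bp sliding window with 1-bp step gives 95 hexamer start sites,
−50..+45. At each site, with σ_XY the population standard deviation of the
member frequencies and σ that of all 4096 frequencies, the dispersion is

    ρ_XY = σ_XY / σ

ρ_XY < 1 flags conservative (narrow, correlated) usage of the XY-containing
hexamers at that site; ρ_XY > 1 flags random usage.

Acceptors are classified from the donor↔acceptor pairing graph of a
transcript annotation: **common** (one-to-one), **constitutive** (one
acceptor, several donors), **alternative** (several acceptors, one donor;
sub-classified as **normal**, **exonic** or **intronic** by position
relative to the reference junction), or ambiguous (excluded). Events are
filtered out when the intron spans fewer than 100 bp or when alternative
acceptors sharing a donor lie closer than 100 bp. Mode differences are
tested region-by-region (upstream −50..−7, core −6..+1, downstream
+2..+45 sites) with paired t-tests (df = sites − 1) under
Benjamini–Hochberg FDR, and each pattern is grouped A/B/C by how many of
its pairwise mode comparisons are significant.

## Worked example

A synthetic three-mode run in which the alternative mode carries a 3×
AG-dinucleotide enrichment over downstream sites +5..+30:

```python
from splicedisp import simulate as sim
from splicedisp.dispersion import count_kmers_by_site, profile
from splicedisp.region_stats import compare_modes
from splicedisp.kmers import SubsetPartition

part = SubsetPartition.build(6)
cfg = sim.GeneratorConfig(
    n_per_mode=2000, seed=1,
    injections=(sim.Injection("AG", 5, 30, 3.0, "alternative"),),
)
profiles = {
    m: profile(count_kmers_by_site(sim.generate_windows(cfg, m)), part)
    for m in ("common", "constitutive", "alternative")
}
res = compare_modes(profiles)
ag = res[(res.region == "downstream") & (res.pattern == "AG")]
print(ag[["mode_a", "mode_b", "t", "df", "p_adj", "stars", "group"]].to_string(index=False))
```

```
      mode_a       mode_b         t  df        p_adj stars group
      common constitutive -2.190285  43 6.523043e-02    ns     B
      common  alternative -8.936968  43 1.102875e-09  ****     B
constitutive  alternative -8.347940  43 1.102875e-09  ****     B
```

The two comparisons involving the enriched mode reject decisively (the
planted AG enrichment flattens the AG1 frequency distribution downstream,
shifting ρ_AG1), while the two null modes do not differ — the AG pattern
lands in group B, "one mode distinguished from the other two".

The same analysis runs from a genome FASTA + GTF via the CLI:

```sh
splicedisp run genome.fa annotation.gtf --out-dir results/
splicedisp simulate --seed 1 --inject AG:5:30:3:alternative --out-dir sim/
```

`run` writes the acceptor catalog (`acceptors.tsv`/`.bed`), retained
windows (FASTA/TSV), rejection log, per-mode and per-submode dispersion
profiles, region test tables and a JSON manifest. `catalog`, `extract`,
`profile` and `test` expose the individual stages.

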