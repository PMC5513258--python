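# radpara

Paralogy-aware SNP discovery and diversity estimation for RADseq read-count
piles.

RADseq panels for non-model species are usually mapped onto a de-novo
pseudo-reference. When a genome is rich in repeats, reads from diverged
paralogous copies collapse onto a single reference locus and masquerade as
polymorphism: every individual looks heterozygous at the diverged sites, the
minor-allele-frequency (MAF) spectrum piles up near 0.5, the inbreeding
coefficient F<sub>IS</sub> = 1 − H<sub>O</sub>/H<sub>S</sub> goes strongly
negative, and sequence diversity (θ) and error-rate estimates are inflated.
`radpara` implements the in-silico defence: genotype-likelihood SNP calling
from per-site base counts, a one-locus vs two-locus likelihood-ratio test that
flags putatively paralogous positions, Nei-style diversity statistics with and
without the flagged loci, and a minimum-depth sweep that quantifies how the
depth-of-coverage threshold interacts with paralogy. A synthetic
collapsed-paralog generator with known truth makes every step testable at desk
scale.

## The model

**Genotype calling.** Reads at a site are multinomial draws over A, C, G, T.
A copy carrying base *a* is read as *a* with probability 1 − ε and as each
other base with probability ε/3, so an unordered diploid genotype {a,b} emits
*a* and *b* with probability (1 − ε)/2 + ε/6 each. With a flat prior over the
10 unordered genotypes, a genotype is called when its posterior reaches `th1`
(default 0.95) and the pile depth reaches `min_depth`; otherwise the call is
missing.

**Error and heterozygosity by ML.** Per individual, the mixture
Σ<sub>sites</sub> log[(1 − H)·P<sub>hom</sub>(counts | ε) + H·P<sub>het</sub>(counts | ε)]
is maximised jointly over (H, ε) by alternating golden-section sweeps; H is
the per-site heterozygosity, reported as the individual's θ.

**Paralogy filter.** For each SNP with major/minor alleles (a, b), the
one-locus model marginalises each individual's genotype over Hardy–Weinberg
weights at a free allele frequency p; the two-locus model instead assumes a
fixed collapsed duplication in which every read comes from the a-carrying
copy with one shared ratio r. The statistic Λ = max(0, 2(lnL₂ − lnL₁)) is
referred to a χ²(1) upper tail; a site is `PARA` when p < `th2` (default
0.01) and the two-locus model fits better, and a locus is paralogous as soon
as one of its sites is `PARA`.

**Diversity.** Per site over the n called individuals:
H<sub>O</sub> = fraction heterozygous,
H<sub>S</sub> = (2n/(2n−1))(1 − Σ p̂²) (Nei's unbiased gene diversity),
F<sub>IS</sub> = 1 − H<sub>O</sub>/H<sub>S</sub>, MAF = frequency of the
second-most-frequent allele. Sequence-level θ is the length-weighted mean of
per-site H<sub>S</sub> with monomorphic sites included.

## Worked example

```python
import radpara as rp

# 500 RAD loci x 9 diploids; 20% of loci hide two extra diverged copies
piles, truth = rp.simulate_dataset(rp.SimConfig(n_loci=500, seed=1))
result = rp.run_depth_sweep(piles, rp.SweepConfig(depths=(4, 18)))
t = result.table.set_index("min_depth")
for d in (4, 18):
    print(f"depth {d:>2}: {t.loc[d, 'n_loci']:4d} loci analysed, "
          f"{t.loc[d, 'pct_para']:.1f}% flagged paralogous, "
          f"theta {t.loc[d, 'theta_all']:.4f} -> {t.loc[d, 'theta_nonpara']:.4f} filtered")
snp4 = result.snp_tables[4]
print(f"median FIS of PARA SNPs: {snp4[snp4.flag == 'PARA'].fis.median():.2f}")
```

prints

```
depth  4:  500 loci analysed, 36.0% flagged paralogous, theta 0.0088 -> 0.0070 filtered
depth 18:  109 loci analysed, 91.7% flagged paralogous, theta 0.0139 -> 0.0015 filtered
median FIS of PARA SNPs: -0.89
```

Reading this: at a permissive 4× calling depth all 500 loci are analysable and
the filter flags 36% of them (the 20% true collapsed loci plus error-artifact
sites); at 18× only high-coverage loci survive, and because collapsed loci
carry ~3× coverage the analysed set is dominated by them — the same
composition effect that makes detected paralogy rise steeply with the depth
threshold on real data. Removing flagged loci pulls θ back down, and the
strongly negative F<sub>IS</sub> of flagged SNPs is the heterozygote-excess
signature of collapse.

The same pipeline is scriptable from the shell:

```bash
radpara simulate --n-loci 500 --seed 1 --out sim/
radpara sweep    --piles sim/piles.tsv --out sweep/
radpara filter   --piles sim/piles.tsv --min-depth 4 --out filt/   # VCF + site table
radpara call     --piles sim/piles.tsv --out call/
radpara validate --genotypes call/genotypes.tsv --assay sim/assay.tsv --out val/
```

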