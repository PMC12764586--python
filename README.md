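# graphtad

TAD calling from Hi-C contact matrices via closed-form graph embedding
and density clustering.

Topologically Associating Domains (TADs) are contiguous genomic
intervals with elevated internal contact frequency in Hi-C maps,
bounded by sharp interaction drop-offs. `graphtad` identifies them by
treating each fixed-width genomic bin as a node of a weighted graph
(edge weights = interaction frequencies), embedding that graph with
NetMF — the closed-form factorization of the matrix that random-walk
skip-gram (DeepWalk) implicitly factorizes,

    χ = vol(G)/(b·T) · (Σ_{r=1..T} (D⁻¹A)^r) · D⁻¹,

followed by the shifted-PPMI floor `χ' = max(χ, 1)`, the elementwise
log, and a rank-*a* factorization whose node vectors are
`U_a √Σ_a` — and clustering the embedded bins with HDBSCAN
(mutual-reachability density clustering). Maximal runs of consecutive
same-cluster bins become candidate domains; candidates outside the
100 Kb – 5 Mb mammalian TAD size range are discarded.

Chromosome-scale matrices are processed in windows of at most 5000
bins; each window after the first is extended left/top by a 3 Mb
overlap region, and duplicated calls inside an overlap are adjudicated
by the TAD Quality score (mean intra-domain contact minus mean
inter-domain contact), higher score winning.

The package also ships the evaluation statistics used for domain
callers — Measure of Concordance (MoC), a TAD-adjusted R² profile of
contact variance over genomic distance, boundary signal profiles
(e.g. CTCF ChIP-seq ± 250 Kb), reference recovery rate, and
split/merge rearrangement events — plus a synthetic Hi-C generator
with known ground-truth partitions so the whole pipeline is testable
offline.

## Worked example

```python
from graphtad import simulate_hic, TadCaller, moc

sim = simulate_hic(n_bins=600, resolution=10_000, seed=1)
print("true domains :", len(sim.truth))
caller = TadCaller(resolution=10_000).fit(sim.matrix)
print("called domains:", len(caller.tads_))
for t in caller.tads_:
    print(f"  {t.chrom}\t{t.start_bp}\t{t.end_bp}")
print(f"MoC vs truth  : {moc(caller.tads_, sim.truth):.3f}")
```

prints

```
true domains : 5
called domains: 5
  chrS	0	970000
  chrS	970000	1980000
  chrS	2060000	3760000
  chrS	3770000	5320000
  chrS	5320000	6000000
MoC vs truth  : 0.990
```

The simulated 6 Mb chromosome contains five ground-truth domains on an
exponential distance-decay background (4× intra-domain contact boost,
Poisson counting noise plus additive noise). The caller recovers all
five, with boundaries within a bin or two of the truth, giving a
Measure of Concordance of 0.99 (1.0 would be an identical partition).

`TadCaller` is a scikit-learn-style estimator: `get_params`/
`set_params`/`clone` work, `fit_predict` returns per-bin domain labels
(−1 outside every domain), and the embedding stage alone is available
as the `NetMFEmbedding` transformer.

The same pipeline is exposed on the command line:

```sh
graphtad simulate --n-bins 600 --seed 1 --out-matrix m.tsv --out-truth truth.bed
graphtad call m.tsv --resolution 10000 --out tads.bed
graphtad eval moc tads.bed truth.bed --resolution 10000
```

with further subcommands `eval adjr2 | profile | recovery | events`.

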