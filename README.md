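# cbcnv

Cluster-based copy-number-variation (CNV) calling from tumor–normal matched
whole-genome sequencing read depth.

Somatic and germline CNVs leave a depth-of-coverage footprint: the number of
reads mapped to a genomic window is roughly proportional to its copy number.
`cbcnv` detects that footprint without fitting a parametric depth
distribution. Instead it treats CNV detection as local outlier discovery on
a segmented read-depth profile:

1. **Binning & masking** — the chromosome is divided into fixed,
   non-overlapping bins (default 2,000 bp); bins containing any `N`
   reference base are removed; per-bin mean read depth `RD_i` is computed.
2. **GC correction** — `RD'_i = RD_i · RD_m / RD_gc`, where `RD_m` is the
   profile mean and `RD_gc` the mean over bins sharing bin *i*'s GC stratum
   (1% strata).
3. **Fused-lasso segmentation** — the exact minimizer of
   `½Σ(y_i−β_i)² + λΣ|β_{i+1}−β_i|` is computed in one linear sweep; maximal
   constant runs become read-depth segments `RDS`.
4. **2-D features** — each segment becomes a point
   `(CN_i, RDSD_i)`: a copy-number estimate `CN_i = 2·RDS_i/RDS_m` and the
   mean absolute difference between the segment's depth ratio and its `L`
   left/right neighbours (default `L = 10`).
5. **Cluster-based abnormal score (CBAS)** — k-means (default `k = 5`)
   partitions the points; clusters are split into large/small by a mass
   ratio `x = 0.9` and a size-gap multiple `y = 5`. Small-cluster members
   score their distance to the nearest large-cluster centre; large-cluster
   members their distance to their own centre.
6. **Tukey's fences** — segments with `CBAS > T = Q3 + w·(Q3−Q1)`
   (default `w = 1.5`) are called, merged, typed gain/loss against the mean
   depth of the uncalled segments, and classified somatic/germline by
   ≥50% reciprocal overlap against the matched normal's calls.

The package also ships a matched tumor/normal simulator (purity-mixture
depth model, negative-binomial counts, smooth GC bias) and an evaluation
harness (>50%-overlap matching, sensitivity/FDR, precision/recall/F1, and
the overlapping density score `ODS = O_m · O_r` for truth-free comparisons),
so the whole method is testable end to end with no external data.

## Worked example

```sh
cbcnv simulate --purity 0.3 --coverage 10 --bin-size 2000 --seed 7 \
    --fasta --out-dir sim/
# simulated 22 CNV regions over 20000 bins -> sim/

cbcnv call --tumor sim/tumor.tsv --normal sim/normal.tsv \
    --fasta sim/reference.fa -o calls/
# tumor: 14 calls (14 somatic, 0 germline); normal: 7 calls -> calls/

cbcnv evaluate --calls calls/tumor_calls.bed --truth sim/truth.bed \
    --report report.json
# sensitivity=0.636 fdr=0.000 f1=0.778 (14/22 truths, 14 calls)
```

The simulated tumor carries 22 CNVs (12 gains of copy number 3–6, 4
heterozygous and 6 homozygous losses, 2–100 kb) at tumor purity 0.3 and 10×
coverage. The caller recovers 14 of the 22 events — long events are found
reliably, single-bin 2 kb events are usually below the segmentation's
resolution at this noise level — with no false calls on this sample; every
called event is absent from the matched normal, hence somatic.

The same steps are available as library calls:

```python
from cbcnv import SimConfig, simulate_pair, CallerParams, call_pair, evaluate_calls
from cbcnv.simulate import profile_from_table

cfg = SimConfig(purity=0.3, seed=7)
sim = simulate_pair(cfg)
pair = call_pair(profile_from_table(sim.tumor, sim.gc, cfg.bin_size),
                 profile_from_table(sim.normal, sim.gc, cfg.bin_size),
                 CallerParams())
print(evaluate_calls(pair.tumor_calls, sim.truth).to_dict())
```

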