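# kronstat

Estimation and inference for **high-dimensional transposable data**:
studies in which every subject contributes a whole matrix — typically
genes × tissues — so that rows *and* columns are both correlated.

With N subjects each measured as an r × c matrix X_i (r genes, c tissues,
r ≫ N), kronstat works under the matrix-variate model

    X_1, …, X_N  i.i.d.,   E[X_i] = M,
    Cov(X_ij, X_lm) = (Σ_R)_il (Σ_C)_jm        (Kronecker-product covariance)

where M is the mean expression matrix, Σ_R the gene–gene covariance and
Σ_C the tissue–tissue covariance (identified by the convention
tr(Σ_C) = c).  Ignoring the tissue-wise dependence — as per-gene ANOVA-style
analyses do — distorts both gene-level inference and apparent gene–gene
correlation; kronstat estimates and accounts for both sides.

It provides:

* **Data handling** — a labelled N × r × c cube with long/wide delimited
  I/O, label-driven subsetting, and the standard low-expression filter
  (drop genes whose tissue-sum falls below a threshold, default 0.1).
* **Trace functionals** — unbiased pair-difference U-statistics of
  tr(Σ), tr(Σ²), tr²(Σ), Σ_j Σ_jj² for either side, each verified against
  a literal O(N⁴) enumeration oracle.
* **Stein-type shrinkage** — covariance estimates
  (1−λ)·S + λ·T toward spherical, identity, or diagonal targets with a
  data-driven λ ∈ [0,1]; invertible for any r, with Monte-Carlo-verified
  Frobenius risk improvement over the sample covariance when r ≫ N.
* **Mean-conservation tests** — is the mean expression profile of a gene
  set constant across all tissues, or within chosen tissue groups?  A
  projection U-statistic with exact null mean zero, valid for r ≫ N,
  including pairwise reference-vs-other screens with BH/FDR adjustment.
* **Covariance-structure tests** — sphericity ("proportional to
  identity") and identity tests for either side, applied e.g. to every
  tissue pair to map which tissues are dependent, with FDR control.
* **Simulator** — matrix-variate Gaussian or heavy-tailed (scaled Gamma)
  generator with exact Kronecker covariance, structured covariance
  factories, and a calibration harness for size/power studies.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

A simulated multi-tissue study shaped like the motivating application
(2000 genes × 9 tissues × 11 subjects; a third of the genes silent):

```python
from kronstat import (
    gtex_like_config, sample_dataset, filter_rows_by_total,
    all_pairs_sphericity, pairwise_conservation_tests,
    shrink_covariance, correlation_from_covariance,
)

ds = sample_dataset(gtex_like_config(r=2000, c=9, n_subjects=11, seed=7))
kept, dropped = filter_rows_by_total(ds, threshold=0.1)
print(f"kept {kept.n_rows} of {ds.n_rows} genes after the 0.1 expression filter")

est = shrink_covariance(kept, "columns", target="spherical")
sd, corr = correlation_from_covariance(est)
print(f"tissue covariance: shrinkage intensity lambda = {est.intensity:.3f}")

results, p_adj = all_pairs_sphericity(kept, fdr=0.05)
n_cor = sum(t.details["reject_fdr"] for t in results)
print(f"sphericity rejected (FDR 0.05) for {n_cor} of {len(results)} tissue pairs")

genes = kept.row_ids[:40]
tests, adj = pairwise_conservation_tests(kept, genes, reference_col="t1")
worst = min(tests, key=lambda t: t.details["p_adj"])
print(f"gene-list conservation vs t1: smallest adjusted p = "
      f"{worst.details['p_adj']:.3f} (tissue {worst.details['other']})")
```

Output:

```
kept 1400 of 2000 genes after the 0.1 expression filter
tissue covariance: shrinkage intensity lambda = 0.768
sphericity rejected (FDR 0.05) for 36 of 36 tissue pairs
gene-list conservation vs t1: smallest adjusted p = 0.788 (tissue t2)
```

Reading the numbers: the filter removes exactly the 600 silent genes; the
tissue covariance is strongly shrunk (λ ≈ 0.77, as expected with 11
subjects); every tissue pair rejects sphericity because the generator put
compound-symmetric correlation 0.2 between all tissues; and the randomly
chosen "gene list" shows no tissue-specific mean signal (all adjusted
p ≥ 0.79), matching how it was simulated.

The same pipeline is available from the shell:

```sh
kronstat simulate --r 2000 --c 9 --n 11 --sigma-r ar1:0.5 --sigma-c cs:0.2 \
    --seed 7 --out study.tsv
kronstat filter -i study.tsv --threshold 0.1 --out filtered.tsv
kronstat test-cov -i filtered.tsv --side columns --null sphericity --pairs --fdr 0.05
kronstat test-mean -i filtered.tsv --groups "t1,t2,t3,t4" --rows genelist.txt
kronstat shrink -i filtered.tsv --side columns --target spherical --out cov.tsv
```

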