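# ibexniche

Spatial immune-niche analysis of multiplex immunofluorescence (IBEX-style)
images of metastatic mouse lungs.

Disseminated tumor cells in the lung form lesions ranging from single
dormant cells to proliferating colonies, and whether a lesion stays dormant
depends on the immune cells around it. `ibexniche` turns multichannel
tissue images (or per-cell intensity tables) into a quantitative answer to
three questions:

1. **What is each cell?** Per-cell mean fluorescence intensities (MFIs) are
   gated by an automatic "elbow" threshold per marker, matched against
   expected +/− profiles for known cell types, and ambiguous cells are
   rescued by modeling their MFI vector as a linear mixture of the learned
   representative profiles (largest significant positive coefficient wins).
2. **Where are the lesions, and are they dormant?** Tumor cells ≤ 200 μm
   apart are linked; connected components are lesions. Non-tumor cells
   within 200 μm of any member tumor cell join that lesion (possibly
   several). Lesions of 1–8 tumor cells are *dormant*, larger ones
   *proliferative*.
3. **Which immune niches do lesions live in, and do genotypes differ?**
   Per-lesion immune counts are centered-log-ratio (CLR) transformed,
   standardized per cell type, and analyzed by correlation modules and PCA.
   Three regression models compare genotypes: a logistic model of each
   cell's tumor status (`tumor ~ genotype`, sample grouping), a
   zero-truncated negative binomial (ZTNB) model of lesion size
   (`size ~ genotype`, log link, NB2 with variance μ + μ²/θ conditioned on
   Y ≥ 1, likelihood implemented directly), and a Gaussian model of each
   lesion's niche PC1 score (`PC1 ~ log size × genotype`).

Because matched raw image data are not publicly available, the package
ships a first-class synthetic-data generator (`ibexniche.synthdata`) that
emulates the study design — two genotypes × 3 mice, ZTNB lesion sizes with
observed means 16.8 (control) vs 3.8 (myeloid-TGFβR2-knockout), ring-placed
immune cells drawn from two niche profiles tied to lesion size and
genotype, and log-normal marker intensities — with full ground truth, so
every stage is testable offline.

## Worked example

```python
import ibexniche as ix

# simulate the default two-genotype study
cfg = ix.SimConfig(seed=1)
cells, truth = ix.simulate_cells(cfg)          # 28,004 cells, 180 lesions

# phenotype, lesions, niches, models
calls, report = ix.classify_cells(cells, seed=0)
les = ix.assign_immune(cells, calls, ix.build_lesions(cells, calls))
panel = ix.default_panel()
immune = [t for t in panel.immune_types() if t not in panel.exclusion_list]
lesion_df = ix.lesion_table(les, immune)
print(ix.classify_and_summarize(les)["per_genotype"]
      [["genotype", "n_lesions", "mean_size", "pct_dormant"]])

mods = ix.analyze_niches(ix.build_niche_table(lesion_df))
fit = ix.fit_lesion_size(lesion_df)
print("genotype effect on lesion size:",
      round(fit.coef("genotype_ko"), 2), "p =", fit.pvalue("genotype_ko"))
```

prints

```
  genotype  n_lesions  mean_size  pct_dormant
0  control         90  15.222222    34.444444
1       ko         90   3.688889    93.333333
```

and a strongly negative genotype coefficient
(`genotype effect on lesion size: -1.94 p = 2.42e-19`): knockout lesions
are a few cells while control lesions average ~17 cells, with dormant
(1–8 cell) lesions dominating the knockout arm — the expected consequence
of disabling myeloid TGF-β signaling in this model. The niche analysis
splits the immune types into a T-cell/macrophage/cDC2 module and a
CD103⁺ cDC/NK/NKT/monocyte module, with small and knockout lesions scoring
toward the latter on PC1.

The same stages are available from the shell:

```bash
ibexniche simulate --seed 1 --out synthetic/
ibexniche phenotype synthetic/cells.csv --out calls.csv
ibexniche lesions synthetic/cells.csv calls.csv --radius 200
ibexniche niches lesions.csv --modules 2
ibexniche fit lesions.csv --model size --grouping fixed
ibexniche run --seed 1 --out runs/      # everything, with a manifest
```

Imaging-mode inputs (OME-TIFF stacks) go through
`ibexniche measure`, which saturates the brightest 0.01% of pixels per
channel, converts to 8-bit, applies configured pairwise channel
subtraction, segments nuclei (Otsu + distance-transform watershed), and
measures per-cell MFIs with membrane markers Gaussian-smoothed (σ = 4 px).

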