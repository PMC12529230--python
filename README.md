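# napchip

Characterization of genome-wide binding by non-sequence-specific
nucleoid-associated proteins (NAPs), built around the ChIP-seq occupancy
analysis of the Lrs14-family protein AbfR1 in the thermoacidophilic archaeon
*Metallosphaera sedula*, together with quantification of the matching in
vitro readouts (EMSA saturation binding, AFM topographs).

NAPs bind DNA with little or no sequence specificity, so their ChIP
enrichment profiles are not motif-centred peaks but broad, kilobase-scale
zones whose placement tracks bulk DNA properties — here, local AT content.
`napchip` provides the analysis steps such a study needs, each exercisable
on seeded synthetic data:

- **Genic-context classification** of each enrichment peak: the summit
  window spans 30 bp upstream through 30 bp downstream of the peak summit
  (60 bp); a peak is called *intergenic* iff strictly more than 30 bp of
  that window overlap the intergenic complement of the merged gene set,
  otherwise *coding*.
- **Category statistics** over the standard peak classes — all peaks,
  fold enrichment (FE) ≥ 2, top-20 and bottom-20 by FE — including percent
  intergenic and mean width.
- **AT-enrichment testing**: summit-window AT fractions versus the genomic
  intergenic/coding backgrounds with an unpaired *t* test (Welch by
  default, Student's pooled variant selectable) and a seeded permutation
  companion; significance flagged at *p* < 0.001.
- **Subpeak merging** into lettered parent regions (472a, 472b, …),
  **gene annotation** of peak spans, and the **width–enrichment Pearson
  correlation**.
- **EMSA quantification**: fraction bound per lane and apparent-K_D fits of
  the single-site isotherm θ = [P]/(K_D + [P]) (Hill variant optional) with
  a multistart least-squares search.
- **AFM quantification**: plane leveling, 8-connected complex segmentation,
  per-complex maximum height binned as [0,2), [2,4), [4,6), > 6 nm, percent
  of tall (> 12 nm) complexes, and foci counting by prominence-filtered
  regional maxima.
- **Synthetic data** for everything above: genomes with contrasting
  coding/intergenic AT composition (53% vs 62%), AT-biased occupancy
  tracks, Poisson triplicate coverage, a toy peak segmenter, EMSA
  titrations and AFM topographs with ground truth.

Fit/transform-shaped steps are scikit-learn-style estimators
(`SummitContextClassifier`, `BindingIsothermRegressor`,
`AfmComplexSegmenter`) with plain-function wrappers; I/O follows the
field's formats (FASTA, GFF3, MACS-style narrowPeak, BED, bedGraph, TSV).

## Worked example

```python
import napchip as nc

# a seeded synthetic ChIP experiment at the package's study conditions
genome, genes = nc.simulate_genome(nc.GenomeSpec(), seed=11)
part = nc.genic_partition(genes, genome)
track = nc.occupancy_track(genome, nc.OccupancySpec())["sim_1"]
coverage = nc.sample_coverage(track, depth=50, n_replicates=3, seed=12)
peaks = nc.call_toy_peaks(coverage)

clf = nc.SummitContextClassifier().fit(part.intergenic, genome)
contexts = clf.transform(peaks)
fe2 = nc.filter_fe(peaks, 2.0)
frac = (contexts.set_index("peak_id").loc[fe2.df.peak_id].context
        == "intergenic").mean()
rep = nc.at_report(peaks, contexts, genome, part.intergenic, part.coding)
row = rep[(rep.category == "FE>=2") & (rep.context == "intergenic")].iloc[0]
corr = nc.width_fe_correlation(peaks)

print(f"{len(peaks)} peaks, {len(fe2)} with FE >= 2, "
      f"{100 * frac:.0f}% intergenic")
print(f"AT {100 * row.mean_at_peaks:.1f}% vs background "
      f"{100 * row.mean_at_background:.1f}%  (Welch p = {row.p:.1e})")
print(f"width-FE Pearson r = {corr.pearson_r:.2f} (n = {corr.n})")
```

prints

```
81 peaks, 47 with FE >= 2, 98% intergenic
AT 67.9% vs background 61.6%  (Welch p = 7.3e-10)
width-FE Pearson r = 0.66 (n = 81)
```

i.e. with an AT-biased occupancy model the pipeline recovers the expected
signature of a nonspecific NAP: FE ≥ 2 peaks centred on intergenic
sequence, summit windows significantly AT-richer than the intergenic
background, and wider zones showing higher enrichment. Setting
`OccupancySpec(bias_alpha=0)` removes all three signals.

A command-line interface mirrors the library
(`napchip simulate|classify|atstats|correlate|merge|emsa-fit|afm-quant|report`).

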