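# musavar

Ploidy, SNP and bunch-phenotype concordance analysis for
inflorescence-dichotomous plantain (*Musa* spp., AAB genome) cultivars.

Plantain normally flowers once and bears a single fruit bunch per
pseudostem. In some False Horn cultivars the inflorescence dichotomizes,
producing two or three bunches — a phenotype that recurs unreliably across
the plant crop and the ratoon crops regrown from the same stool. `musavar`
implements the quantitative side of characterizing this system for plant
geneticists and breeders working with such panels:

* **Concordance** — how persistent is a bunch phenotype across crop cycles?
  For each cultivar the concordance coefficient pools both ratoon cycles:

  CC = Σᵢ Nᵢᵢ / (Σᵢ Nᵢᵢ + Σᵢⱼ Nᵢⱼ),  i ≠ j

  where Nᵢᵢ counts ratoon observations matching the same plant's plant-crop
  bunch count and Nᵢⱼ those that differ (dead plants excluded). CC = 1 ⇒
  Normal/Persistent; anything less ⇒ Random/Non-persistent.

* **Variants** — SNPs and deletions called from a gapped multiple sequence
  alignment of a gene region (here a GTPase-protein-binding gene of the
  leaf-tissue gene complex) against a designated reference row. Every call
  is classified chemically (purine Pu = {A,G}, pyrimidine Py = {C,T};
  transition when the class is conserved, transversion otherwise) and by
  codon effect under the standard genetic code (synonymous vs
  non-synonymous), then condensed into per-cultivar spectrum tables and
  minimal VCFs.

* **Ploidy** — cytotype calls by two routes: the modal metaphase chromosome
  count divided by the *Musa* basic number (x = 11, so 2n = 2x = 22,
  2n = 3x = 33), and flow-cytometry DNA-content histograms read against a
  triploid internal standard, where ploidy = round(control_ploidy × p / p₀)
  for a dominant sample peak at channel p and control peak at p₀. Ambiguous
  inputs are refused, not rounded, and refusals are reported.

* **Synthetic data** — seeded generators for all four input kinds
  (phenology tables, variant-implanted alignments, chromosome-count tables,
  flow histograms) with explicit truth sets, so the whole pipeline is
  testable without deposited data.

## Worked example

Run the bundled six-cultivar panel end to end (simulate → concordance →
snp-call → ploidy-call → report):

```sh
musavar report --seed 1
```

`musavar_run/concordance.tsv` — one simulated field season; the
single-bunching control is fully persistent while the dichotomous cultivars
revert at cultivar-specific rates (CC here is a stochastic realization of
each cultivar's concordance probability):

```
cultivar  plant_crop_n  ratoon_n  concordant_n  cc    occurrence  persistence
Agbagba   10            20        20            1.00  Normal      Persistent
DB1P      10            20        17            0.85  Random      Non-persistent
DB2P      10            20        9             0.45  Random      Non-persistent
TB1P      10            20        2             0.10  Random      Non-persistent
TB2P      10            20        2             0.10  Random      Non-persistent
TB3P      10            20        0             0.00  Random      Non-persistent
```

`musavar_run/substitution_spectra.tsv` — the SNP caller recovers each
cultivar's implanted spectrum exactly: 55 purely transitional, synonymous
sites for the control and 77–86 predominantly transversional,
non-synonymous sites for the dichotomous cultivars, with the two most
frequent substitution types listed per row:

```
cultivar  n_snp_sites  top_substitutions  substitution_class  mutation_type
Agbagba   55           26G>A / 12A>G      Pu-Pu               synonymous
DB1P      82           46T>G / 23C>A      Py-Pu               non-synonymous
DB2P      77           33A>C / 12G>T      Pu-Py               non-synonymous
TB1P      81           40T>A / 18C>G      Py-Pu               non-synonymous
TB2P      79           33A>T / 19C>A      Py-Pu               non-synonymous
TB3P      86           28G>C / 21T>G      Pu-Py               non-synonymous
```

The flow-cytometry tally over the 100-plant ratoon cohort reads
`{'2x': 95, '4x': 5}`: 95 diploids and 5 tetraploids against the triploid
internal control. `deletions.tsv` reports the shared 12-base deletion
(start 91) carried by every dichotomous cultivar's sequence.

Single stages run standalone, e.g.:

```sh
snp-call --alignment musavar_run/alignment.fasta --reference Ancestral \
         --frame 1 --out-prefix run1
ploidy-call --cytology musavar_run/cytology.csv \
            --flow-manifest musavar_run/flow_manifest.csv --control-channel 75
```

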