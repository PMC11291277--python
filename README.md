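# paleozooms

A desk-scale pipeline for collagen-based taxonomic identification of bone
(ZooMS), ancient-protein degradation screening, consensus proteome
reconstruction, protein phylogenetics and faunal-assemblage statistics.
Every stage runs on synthetic, ground-truthed data generated by the package
itself, so the whole analysis chain is testable without any external
download.

## What it does

- **markerdb** — in-silico tryptic digestion of COL1 sequences,
  monoisotopic marker m/z prediction (hydroxylation/deamidation aware), and
  a taxonomy-aware peptide-marker database with TSV serialization.
- **spectra** — MALDI-TOF peak-list I/O (TSV, read-only mzML), profile-mode
  peak picking, and merging of triplicate spectra into a consensus peak
  list by single-linkage clustering.
- **zooms_id** — marker matching at a configurable mass tolerance and
  taxonomic assignment via best-supported root-path scoring with
  lowest-consistent-taxon resolution and secure/tentative quality calls.
- **deamidation** — glutamine deamidation on the 0–1 scale (1 = none,
  0 = complete) for the collagen peptides COL1α1 508–519 (GVQGPPGPAGPR,
  "P1105") and COL1α1 435–453 (DGEAGAQGPPGPAGPAGER, "P1706"), by
  non-negative least-squares decomposition of the overlapping Q/deamidated
  isotope envelopes; per-layer summaries with 68.2% bootstrap intervals.
- **proteome_consensus** — target–decoy FDR filtering of PSM tables,
  majority-consensus protein reconstruction weighted by peptide counts
  (proteins with fewer than five peptides are rejected), isoform-edit-aware
  concatenated alignments, and coverage statistics.
- **phylo** — maximum-likelihood placement under the Dayhoff substitution
  model: Felsenstein pruning with site-pattern compression and scaling,
  per-branch length optimization, exhaustive topology enumeration (≤ 8
  taxa) or NNI hill-climbing, and nonparametric bootstrap support.
- **fauna_stats** — combination of morphological and ZooMS identifications
  at ZooMS group levels, NISP tables, bone-surface-modification
  percentages, and Shannon/Simpson diversity with bootstrap CIs.
- **synthetic_data** — seeded generators for all of the above: COL1-like
  sequences over a known taxonomy with guaranteed diagnostic markers,
  triplicate spectra with controllable noise/dropout/deamidation,
  PSM tables with decoys, and alignments evolved under the Dayhoff model.

## Command line

```bash
paleozooms simulate taxa --seed 42 --out sim/          # COL1 FASTA + taxonomy
paleozooms markers predict --fasta sim/col1.fasta \
    --taxonomy sim/taxonomy.tsv --hyd 0:1 --out markers.tsv
paleozooms simulate spectra --seed 42 --out sim/       # triplicate peak lists
paleozooms merge sim/BSY-0001_acid_rep*.tsv --tol 0.2 --min-support 2 --out merged.tsv
paleozooms identify sim/BSY-0001_acid_rep*.tsv --db markers.tsv \
    --taxonomy sim/taxonomy.tsv --out assignments.csv --evidence evidence.csv
paleozooms deamidate sim/BSY-0001_acid_rep*.tsv --peptide P1105 --out deam.csv
paleozooms summarize-deamidation --estimates deam.csv --layers sim/truth.csv \
    --boot 1000 --seed 42 --out layers.csv
paleozooms consensus --psms psms.csv --reference-length 1464 \
    --fdr 0.005 --min-peptides 5 --out consensus.fasta
paleozooms concat --proteomes proteomes.json --edits edits.json \
    --out-fasta aln.fasta --out-partitions parts.txt
paleozooms phylo --alignment aln.fasta --model dayhoff --boot 100 --seed 42 --out tree.nwk
paleozooms fauna --nisp nisp.csv --boot 1000 --seed 42 --out diversity.csv
```

An example isoform-edit configuration ships at
`src/paleozooms/data/isoform_edits_example.json`.

## File formats

- Marker DB: TSV (`label sequence n_hyd n_deam mz_MH taxon rank source`);
  taxonomy: TSV (`child parent rank`).
- Peak lists: two/three-column TSV (`mz intensity [snr]`), file names
  `<specimen>_<protocol>_rep<k>.tsv`; mzML accepted read-only.
- PSM tables: CSV mirroring a search-engine "protein-peptides" export.
- Alignments: FASTA plus a `protein = start-end` partitions file; trees:
  Newick with bootstrap support as internal node labels.
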