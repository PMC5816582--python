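# hetarray

Analysis toolkit for cross-species (heterologous) two-color cDNA microarray
experiments: spot-level quality control, model-based dye/array normalization,
per-gene differential-expression testing with family-wise error control,
length-bias-aware category enrichment, and coexpression module detection —
plus a synthetic-data generator with exact ground truth so every stage is
testable at desk scale.

## Pipeline

1. **QC** (`hetarray.probe_qc`) — two probe filters: a per-channel
   signal-to-noise window (default `3 <= fg/bg <= 10` in both channels,
   flagged spots always removed) and a cross-species alignment filter on
   BLAST tabular hits (`evalue <= 1e-10` and alignment length `> 150` bp).
   A probe enters a species' analysis set only if it passes both; the
   common set is the intersection across species.
2. **Normalization** (`hetarray.normalization`) — background subtraction
   (`fg - bg`, non-positive values become missing), a saturated
   array + dye + array:dye ANOVA on log2 signal (residuals are exactly
   within-cell-centered values), a global positivity shift of the residuals,
   factor-wise log2 expression ratios (species, water, temperature, date),
   and a robust loess correction of each ratio set against log10 intensity.
3. **Differential expression** (`hetarray.diffexpr`) — a pooled Type-II
   ANOVA over all genes plus per-gene linear models (main effects and the
   species:water, species:temperature, water:temperature interactions),
   fitted only where estimable from each gene's missingness pattern.
   Per-term Bonferroni adjustment (BH available); DE calls require
   `|log2 FC| > 1` and adjusted `p < 0.05`.
4. **Enrichment** (`hetarray.enrichment`) — a monotone probability
   weighting function (P(DE | probe length), binned isotonic regression)
   feeding Wallenius noncentral hypergeometric category tests, computed with
   an exact sequential-draw recurrence; BH adjustment across categories.
5. **Coexpression** (`hetarray.coexpression`) — unsigned adjacency
   `|cor|^6`, topological overlap similarity, average-linkage clustering
   with a static cut (minimum module size 5), module eigengenes and
   eigengene–trait correlation tests. The pipeline default mirrors the
   published framing: day-18 samples, per water treatment, trait = species.
6. **Simulation** (`hetarray.synthetic_data`) — the full
   2 species x 2 water x 2 temperature x 2 dates x 2 replicates design
   (32 samples, dye-swapped array pairs, 8 arrays per species per date),
   with planted per-term effects, exact-count inclusion sets, length-biased
   DE probabilities, and planted correlated modules.

## Command line

```bash
hetarray simulate --out-dir sim --seed 1 --n-genes 2000
hetarray qc --spots sim/spots.tsv --design sim/design.tsv \
    --aln-ag sim/aln_ag.tsv --aln-sn sim/aln_sn.tsv --out-dir qc_out
hetarray normalize --spots sim/spots.tsv --design sim/design.tsv --out normed.tsv
hetarray de --normed normed.tsv --design sim/design.tsv --out de.tsv
hetarray enrich --de de.tsv --go sim/go.tsv --fasta sim/probes.fa --term water
hetarray modules --normed normed.tsv --design sim/design.tsv
```

Or run everything from a YAML config (all keys optional; defaults are the
published thresholds):

```yaml
# config.yaml
out_dir: run1
seed: 1
simulate: {n_genes: 2000, effects: {water: [0.05, 2.0]}}
```

```bash
hetarray all --config config.yaml
```

Outputs land under `out_dir`: included-probe sets, the adjusted-residual
matrix, per-factor ratio tables, `de.tsv`, per-species water-response
tables, `enrichment.tsv`, module assignments, and a `summary.json` report
(stage counts, DE tallies per term/direction, module–trait statistics,
full config and seed). Identical config + seed gives byte-identical
outputs.

## File formats

- **Spot table** (TSV): `array_id  probe_id  fg_ch1  bg_ch1  fg_ch2  bg_ch2
  flagged`; a minimal GenePix `.gpr` (ATF) reader is also provided
  (532 nm block -> ch1, 635 nm -> ch2, negative Flags -> flagged).
- **Design table** (TSV): `array_id  dye  sample_id  species  water
  temperature  date  replicate` with two rows per array (`ch1`/`ch2`).
- **Alignments**: BLAST tabular `-outfmt 6` (NCBI default 12 columns).
- **Annotations**: two-column TSV (probe, category) plus a FASTA of probe
  sequences (lengths feed the enrichment weighting).

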