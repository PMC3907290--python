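# splicebind

Predicting RNA-binding-protein target sites and the cassette exons they
regulate, from sequence alone. `splicebind` implements two coupled models:

1. **A two-state triplet-emission hidden Markov model** trained with
   Baum–Welch on protein-bound cluster sequences (e.g. CLIP clusters). The
   trained model scores any RNA sequence as a log-odds ratio against a
   background model, decodes per-base binding-state paths with Viterbi, and
   normalises scores into z-scores using either random-sequence nulls
   (100,000 sequences of matched length by default) or genome-scale length
   bins (1,000 sequences per bin).
2. **A three-class multinomial logistic regression** that converts four exon
   features — 3′ splice-site strength (x1) and the binding z-scores of the
   upstream 250 nt, the exon, and the downstream 100 nt (x2–x4) — into the
   probability that an exon is repressed (or enhanced) by the protein, with
   t-test feature screening, outlier removal, backward-AIC stepwise
   selection, leave-one-out cross-validation with ROC/AUC, and decision
   thresholds (call repressed above 0.65; call unregulated at or below 0.20).

Everything is testable offline: the `synthetic_data` module generates every
input with recorded ground truth (planted-HMM clusters in token and
nucleotide space, planted-logit exon tables, PSI tables).

## Running the tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle equivalence
against brute-force path enumeration, EM monotonicity, planted-parameter
recovery, normalisation self-consistency, anchor profiles, end-to-end
synthetic pipeline, and more).

## Command-line usage

All functionality is wired into one CLI; every run writes a
`provenance.json` with version, configuration, seeds and input checksums.

```bash
# synthetic training data with ground truth
splicebind simulate clusters --n 2000 --length 30 --seed 1 --out-prefix work/cl

# train the binding HMM (FASTA, or BED + genome FASTA)
splicebind train-hmm --clusters work/cl.fasta --restarts 10 --seed 0 --out work/model.json

# score sequences, decode binding sites, build a null and normalise
splicebind score --model work/model.json --fasta probes.fa --out work/scores.tsv
splicebind viterbi --model work/model.json --fasta probes.fa --out work/sites.bed
splicebind null --model work/model.json --length 69 --n 100000 --seed 0 --out-prefix work/null
splicebind normalize --mode probe --scores work/scores.tsv \
    --null-summary work/null.json --null-scores work/null.scores.tsv --out work/z.tsv

# binding maps
splicebind map --model work/model.json --upstream up.fa --exon ex.fa --downstream down.fa --out work/map.tsv
splicebind heatmap --features region_z.tsv --out work/heatmap_order.tsv
splicebind anchors --model work/model.json --fasta tags.fa --anchor-table anchors.tsv --out work/profile.tsv

# exon features and the regulation model
splicebind features --genome genome.fa --exons exons.bed --model work/model.json \
    --ss-matrix ss3.tsv --out work/features.tsv
splicebind train-regulation --features work/features.tsv --labels labels.tsv --out work/reg.json
splicebind cv --features work/features.tsv --labels labels.tsv --out-prefix work/cv
splicebind predict --model work/reg.json --features work/features.tsv --out work/ranked.tsv
```

## Package layout

| module | contents |
| --- | --- |
| `splicebind.seq_io` | FASTA/BED/bedGraph I/O, strand-aware region extraction (RNA alphabet, 0-based half-open coordinates) |
| `splicebind.triplet_hmm` | overlapping-triplet encoding, forward/Viterbi in log space, Baum–Welch with restarts, binding-state labelling, log-odds scoring |
| `splicebind.score_norm` | random-sequence nulls, z-scores, empirical p-values, length-bin normalisation, mono/di shuffles (Altschul–Erickson), score–affinity correlation |
| `splicebind.binding_map` | per-base state tracks, 24-nt/8-nt-overlap window densities, splice-site-anchored group maps, heatmap clustering, anchored state-frequency profiles |
| `splicebind.splice_features` | splice-site PWM scoring (min–max scaled to 0–100), regulatory region definitions, the x1..x4 feature vector |
| `splicebind.regulation_model` | PSI-based exon labelling, multinomial logit (baseline = non-regulated), screening/outliers/stepwise, LOOCV + ROC, thresholds, binned-response analysis |
| `splicebind.synthetic_data` | seeded generators with truth sidecars for all of the above |
| `splicebind.cli` | the `splicebind` entry point |

### Notes on conventions

- Sequences are tokenised as **overlapping** triplets (L−2 tokens), giving
  per-nucleotide state paths.
- Raw log-odds scores are base-2 by default; z-scores are base-invariant.
- Empirical p-values use the "greater or equal" count with no pseudocount
  (500 of 100,000 at-or-above gives exactly 0.005); a `(k+1)/(n+1)` mode is
  available.
- A final partial length bin of fewer than 500 sequences is merged into its
  predecessor.
- Enhanced-class predictions are reported but are markedly less reliable
  than repression calls.
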