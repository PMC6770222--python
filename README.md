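# vaemda

Unsupervised miRNA–disease association prediction with variational
autoencoders. The pipeline:

1. **Similarity construction** — two DAG-based disease semantic similarity
   models (decay and term-frequency), Gaussian interaction-profile kernels
   for both diseases and miRNAs, and integrated similarity matrices (SD/SM)
   that use semantic/functional similarity where available and the kernel
   otherwise.
2. **Feature splicing** — the association matrix `A` (nm × nd) is
   concatenated with the integrated miRNA similarity into `SSM`
   (nm × (nd+nm)), and `Aᵀ` with the integrated disease similarity into
   `SSD` (nd × (nm+nd)).
3. **Two VAEs** — one trained per spliced matrix (300–100–300 bottleneck,
   batch normalization + ReLU encoder, sigmoid decoder, summed binary
   cross-entropy + Gaussian KL loss, Adam). Implemented directly in NumPy
   with hand-derived gradients; training is bit-reproducible from one seed.
4. **Scoring** — each side's association block is reconstructed through the
   latent mean (no sampling) and the two blocks are averaged into the final
   nm × nd score matrix.
5. **Evaluation** — global/local LOOCV, repeated k-fold, and global/local
   leave-one-disease-out CV, with in-fold recomputation of the profile
   kernels, re-integration of SD/SM and full retraining, plus
   Mann–Whitney/ROC AUC with midrank tie handling.

A synthetic-data module generates complete input datasets (associations,
functional similarity, disease DAGs) with planted low-rank structure, so
every stage is testable offline.

## CLI

```bash
# generate a synthetic dataset
vaemda simulate --nm 100 --nd 60 --density 0.1 --seed 0 --out-dir data/

# dump all similarity matrices (SS1/SS2/KD/KM/SD/SM)
vaemda similarity --associations data/associations.tsv --fs data/fs.csv \
    --dags data/dags.tsv --out-dir sims/

# train the two VAEs and write JSON checkpoints + loss histories
vaemda train --associations data/associations.tsv --fs data/fs.csv \
    --dags data/dags.tsv --seed 0 --out-dir models/

# score all pairs and list top candidates for one disease
vaemda predict --associations data/associations.tsv --fs data/fs.csv \
    --dags data/dags.tsv --vae1 models/vae1.json --vae2 models/vae2.json \
    --disease d0000 --top 50 --out-dir predictions/

# cross-validate (schemes: gloocv, lloocv, kfold, glodocv, llodocv)
vaemda eval --associations data/associations.tsv --fs data/fs.csv \
    --dags data/dags.tsv --scheme kfold --k 5 --reps 10 --seed 0 \
    --out-dir eval/
```

Leave-one-out schemes retrain both VAEs once per known pair; use
`--subsample N` to evaluate a seeded random subset of folds. Every command
writes a `manifest.json` with input paths, seeds and output hashes;
rerunning with the same seeds reproduces identical hashes.

## File formats

- associations: two-column TSV `(mirna_id, disease_id)`; the matrix uses
  first-appearance id order.
- functional similarity: square CSV with id header row and column; values
  in [0, 1]; miRNAs absent from the file fall back to the profile kernel.
- disease DAGs: TSV `(disease_id, child_term, parent_term)` edges; diseases
  absent from the file fall back to the profile kernel.
- scores: long-format TSV `(mirna, disease, score, is_known)`, disease-major,
  descending score.

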