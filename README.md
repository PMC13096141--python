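# perturbrank

Network-aware drug repurposing from perturbation transcriptomics.

Given a directed molecular interaction graph and a pair of transcriptomic
states — an initial cell state and a desired target state — `perturbrank`
asks: *which drugs, acting through their known direct protein targets, would
push the cell from the first state toward the second?* It is built for
settings where the training signal comes from perturbation-response
compendia of non-cancer cells and the goal is early prioritization of a
small number of candidates for experimental validation (cell conversion,
differentiation, rare-disease phenotype rescue).

## The method

The pipeline decouples *protein-level* perturbation prediction from the
drugs themselves, so it can rank drugs that never appear in training data.

1. **Graph feature embeddings.** From the two states, differentially
   expressed transcription factors (DETFs) are labeled +1 (up) or −1
   (down), capped at 100 random sources to avoid saturating the graph.
   Each protein carries a base feature vector `X = [baseline expression,
   DETF status]`, which is propagated over the row-normalized adjacency in
   both directions (SIGN-style precomputed message passing):

   `Z = Concat(X, {A_fwd^k X}_{k=1..K}, {A_rev^k X}_{k=1..K})`, `K = 5`.

   Eight row-wise summary statistics (sum, mean, max, min, median,
   population SD, 25th/75th percentiles), three DETF-relative topological
   features (shared pathway counts, minimum directed path length to a DETF,
   percent of DETFs reachable), a full degree-2 polynomial expansion,
   constant-column pruning, and column-wise min–max scaling
   `z_j = (x_j − min x)/(max x − min x)` complete the per-protein features.

2. **VAE denoising.** A variational autoencoder (encoder with batch norm +
   ReLU, widths halving from 1500 down to a 100-d latent space; mirrored
   decoder without batch norm; log-variance clamped to [−5, 5]; loss =
   MSE + β·KL with β = 0.001) regularizes the features. The *decoded*
   matrix, same width as the input, feeds the classifier.

3. **Ensemble target prediction.** Three independently seeded feedforward
   networks (decaying widths, batch norm, LeakyReLU, dropout 0.0,
   lr 0.005) classify every protein as activated (1), inhibited (−1) or
   unaffected (0), after balancing classes to the mean class size by
   downsampling and VAE-decoded augmentation. Ambiguous annotations
   (class 2) never enter training. Majority voting gives the consensus;
   three-way splits conservatively resolve to 0.

4. **Bayesian enrichment score (BES).** For each drug with `n` known
   targets, `k` of which fall in the `N` predicted targets of an
   `M`-protein network:

   - hypergeometric enrichment `p_hyp = Σ_{i=k}^{min(n,N)} C(n,i)·C(M−n,N−i)/C(M,N)`;
   - a permutation null `p_emp`: the fraction of 100 row-shuffled feature
     matrices under which ≥ 1 known target is still predicted;
   - `posterior = 1 − π₀·p_emp` (π₀ = 0.99), modulated by
     `CWF = exp(−λ(1 − p_emp))` (λ = 1) into `s_posterior = posterior·CWF`;
   - `BES = 20·s_posterior + 1·(1 − p_hyp) + 1·r_hyp`, where `r_hyp` is the
     normalized rank of `p_hyp` (1 = best). Drugs with `p_hyp = 1` score 0.

   Drugs are ranked by descending BES (min-method ties); candidates are the
   top 2.5th percentile. Evaluation uses early recall (recall@q%) against
   an over-representation (GSEA-style) baseline and random ranking.

A synthetic-data module generates signed signaling graphs, pathway
collections, drugs with planted targets, and perturbation datasets whose
DETFs arise causally from those targets, so the entire pipeline trains,
scores and benchmarks itself with no download.

## Worked example

Train and benchmark on the desk-scale synthetic world (300 proteins, 30
TFs, 60 drugs, 40 training / 8 held-out test datasets, zero noise; about
nine minutes on one CPU):

```python
from perturbrank import synth, pipeline

bench = synth.make_benchmark(synth.GeneratorParams(noise_rate=0.0, seed=1))
outcome = pipeline.run_benchmark(bench, pipeline.desk_config(seed=1))

print(outcome["ensemble_metrics"]["macro_f1"])
for res in outcome["results"]:
    print(res.method, dict(zip(res.curve.percentiles, res.curve.mean_recall)))
```

prints (exactly reproducible with these seeds):

```
0.993
dl_framework {0.5: 0.375, 1.0: 0.375, 2.0: 0.75, 2.5: 0.75, 5.0: 0.875, 10.0: 0.875}
gsea_baseline {0.5: 0.875, 1.0: 0.875, 2.0: 0.875, 2.5: 0.875, 5.0: 1.0, 10.0: 1.0}
random {0.5: 0.0, 1.0: 0.0, 2.0: 0.0, 2.5: 0.0, 5.0: 0.0, 10.0: 0.125}
```

The ensemble fits the balanced training pool at macro-F1 0.993, and the
trained framework places the drug that actually generated each held-out
dataset within the top 1% of the 60-drug pool in 3 of 8 datasets (random:
0 of 8). Inspecting one held-out ranking shows the recovery is mechanistic,
not a tie artifact — the true drug's known targets really are in the
predicted set:

```
test_002  true drug D026: rank 1, k=5 of n=5 known targets among N=8
          predicted, p_emp=0.11, BES=9.32
```

The same pipeline is available from the shell:

```bash
perturbrank simulate --seed 1 --outdir world --noise-rate 0
perturbrank benchmark --seed 1 --outdir results --world world
```

which writes per-method ranked tables, a JSON summary and a recall-curve
plot under `results/`.

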