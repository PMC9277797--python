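# longbin

Reference-free binning of error-prone long metagenomic reads.

Third-generation sequencing (PacBio, Oxford Nanopore) produces reads long
enough to carry a useful compositional signal, but metagenomic datasets of
raw long reads cannot be binned with contig-binning tools: there is no
per-read coverage track, error rates are high, and species clusters range
from hundreds to millions of reads. `longbin` bins such reads without any
reference database by fusing two alignment-free signals per read and
clustering them in a learned latent space. It is aimed at microbiome
researchers who want species-level read bins before (or instead of)
metagenome assembly.

## Method

For every read the pipeline computes a 64-dimensional feature vector
`V = [V^C, V^T]`:

- **Composition `V^T`** — frequencies of the 32 canonical trimers (a 3-mer
  and its reverse complement merged), normalised by the number of trimers
  in the read.
- **Coverage `V^C`** — a 32-bin histogram of dataset-wide 15-mer counts.
  All 15-mers of all reads are counted once (canonical, 2-bit encoded);
  each of the read's 15-mers contributes its dataset count `c` to bin
  `min(floor(c / 10), 31)`, and the histogram is normalised. Reads from
  abundant species carry high-count 15-mers, so the histogram is an
  abundance proxy that needs no alignment.

A variational auto-encoder (encoder 64 → 128 → 128 → 8, mirrored decoder,
batch normalisation and dropout p = 0.1) embeds `V` into an 8-dimensional
latent mean μ, trained with

    total loss = w_cov · E_cov + w_com · E_com + w_kld · D_KL,
    E = Σ (V_in − V_out)²,   w_cov = 0.1, w_com = 1, w_kld = 1/500.

Clusters are then extracted iteratively from the latent means using cosine
distance `d(a,b) = 1 − a·b/(‖a‖‖b‖)`. A random point whose distance
histogram (bin width Δ = 0.005) has a valley-to-peak ratio `H[valley]/H[peak]
< 0.5` seeds a *candidate cluster* (all points within Δ × valley); 10 % of
the candidate (up to 1000 points) is sampled, the sampled point with the
lowest ratio becomes the anchor, and the points within its own valley radius
form the *confident cluster*, which is removed from play. Extraction stops
when fewer than `min_cluster_size` points remain (default 5000), after
`max_iterations` clusters (default 1000), or when no seed can be found.
Remaining reads are assigned to bins by maximum likelihood over per-bin
diagonal Gaussian profiles fitted to the raw coverage and composition
vectors:

    bin(l) = argmax_i PDF(V^C_l; μ^C_i, σ^C_i) · PDF(V^T_l; μ^T_i, σ^T_i).

Against a ground-truth table the package reports precision, recall and F1
(`Σ_k max_s a_ks / Σ a`, `Σ_s max_k a_ks / Σ a`, their harmonic mean) plus
per-bin completeness and contamination.

A bundled generator (`longbin simulate`) creates synthetic communities —
per-species 3rd-order Markov mock genomes, abundance-weighted read sampling
from both strands, configurable substitution/insertion/deletion noise
(defaults 0.01/0.11/0.04) — so the whole pipeline is testable offline.

## Worked example

```
longbin simulate --out-dir sim --n-species 4 --n-reads 6000 \
    --abundances 1,3,10,30 --seed 0
longbin run --reads sim/reads.fastq --out-dir run \
    --epochs 100 --min-cluster-size 200 --seed 0 \
    --evaluate sim/truth.tsv
cat run/metrics.json
```

produces (from the run recorded in `run/metrics.json`):

```
{
  "precision": 1.0,
  "recall": 1.0,
  "f1": 1.0,
  "bins_detected": 4,
  "reads_evaluated": 6000,
  "reads_excluded": 0
}
```

All four planted species are recovered as bins — including the rarest one at
2 % of the reads (roughly 3× sequencing coverage) — and every read lands in
the bin of its source species. `run/` also holds the per-stage checkpoints
(`features.npz`, `latent.npy`, `clusters.json`), the per-epoch loss trace
(`loss.csv`), per-bin FASTA files, a `bins_detailed.tsv` distinguishing
directly clustered reads from likelihood-assigned ones, and a `manifest.json`
recording every parameter and seed; rerunning with the same manifest
reproduces `bins.tsv` byte for byte.

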