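# decograd

Segmentation and meta-analytic functional decoding of cortical
connectivity gradients.

## The problem

Diffusion-map embedding of a dense functional connectome yields
*gradients*: continuous axes of connectivity similarity across the
cortical surface, with the principal gradient running from unimodal
sensorimotor to transmodal association cortex. Interpreting what a
gradient *means* functionally requires decoding it against the
neuroimaging literature — but a gradient is a dense map, and
meta-analytic decoders are built for sparse activation-like maps.
`decograd` implements the full decoding framework for researchers who
work with connectivity gradients:

1. **Gradients** — inverse Fisher transform, top-10%-per-row
   sparsification, cosine affinity, diffusion-map embedding with
   explained-variance ratios.
2. **Segmentation** — percentile (PCT), 1-D k-means (KMeans), and
   KDE-minima (KDE) splits of the gradient axis for k = 2..32, scored by
   silhouette, variance-ratio (Calinski–Harabasz) and cluster-separation
   (Davies–Bouldin) metrics; k-means clustering of the joint n-D gradient
   space, compared by NMI.
3. **Pseudo-activation maps** — each segment becomes a continuous target
   via a Gaussian kernel of gradient-space distance to a segment peak,
   `A(v, p) = exp(-D²(v, p) / 2σ²)`, with σ the average within-segment
   distance.
4. **Meta-analytic maps** — term-based (TFIDF feature threshold 0.001)
   and topic-based (LDA, `p(topic|article)` threshold 0.05) chi-square
   meta-analyses of a coordinate database, with 10-mm binary
   modeled-activation kernels.
5. **Decoding** — Pearson correlation of every target against every
   labelled map, spin-permutation spatial nulls (Váša-style bijective
   rotation, medial wall fixed), fraction p-values and Benjamini–Hochberg
   FDR.
6. **Evaluation** — correlation profiles, information content, TFIDF,
   expert-category classification and decoding SNR across the full
   strategy grid (segmentation × map source × database).

Everything runs on synthetic data with planted ground truth (module
`decograd.synthetic`), so the whole pipeline is testable without any
external downloads. See `docs/methods.md` for models, conventions and
limitations.

## Worked example

Decode the two ends of a planted principal gradient (k = 2, topic maps):

```python
import numpy as np
import decograd as dg

world = dg.synth_world(n_vertices=500, n_studies=300, n_topics=10,
                       vocab_size=200, seed=7)
grads = dg.gradients_from_connectome(world.connectome, seed=7)
print("explained variance (first 3):", np.round(grads.explained_variance[:3], 3))

seg = dg.segment_kmeans(grads.components[:, 0], k=2, seed=7)
quality = dg.cluster_quality(grads.components[:, 0], seg.labels)
print(f"k=2 mean silhouette: {quality.mean_silhouette:.3f}")

pseudo = dg.build_map_set(seg)
for pm in pseudo:                       # lift cortex maps onto the full mesh
    full = np.zeros(world.mesh.n_vertices)
    full[world.mesh.cortex_mask] = pm.values
    pm.values = full

model = dg.fit_topics(world.corpus, n_topics=12, seed=7)
maps, _ = dg.build_topic_maps(model, world.study_maps)
maps = [m for m in maps if np.std(m.values[world.mesh.cortex_mask]) > 0]

table = dg.decode(pseudo, maps, world.mesh, n_perm=1000, seed=7)
for sid, group in table.groupby("segment_id"):
    top = group.loc[group["r"].idxmax()]
    print(f"segment {sid}: top label {top['label']}  r={top['r']:.2f}  "
          f"q={top['q']:.3f}  significant={top['significant']}")
```

Output:

```
explained variance (first 3): [0.15  0.145 0.138]
k=2 mean silhouette: 0.689
segment 0: top label w0003__w0011__w0010  r=0.67  q=0.000  significant=True
segment 1: top label w0025__w0035__w0034  r=0.61  q=0.012  significant=True
```

The generator plants topic 0 (signature words `w0000..w0019`) at one end
of the latent axis and topic 1 (`w0020..w0039`) at the other. Both
terminal segments decode — significantly under the spin null after FDR —
to the topic that generated their end of the gradient: the labels are
drawn from the correct signature blocks, and the correlations (0.6–0.7)
sit in the range typical for well-aligned continuous decoders.

## Command line

```bash
decograd simulate --out ws --seed 0            # synthetic inputs + truth.json
decograd gradient --connectome ws/connectome.npy --value-kind r --out grads
decograd segment  --gradients grads --method KMeans --k 2 --out segs
decograd decode   --out run --method KMeans --source topic --k-min 2 --k-max 5
decograd evaluate --out eval                   # strategy-grid benchmark
```

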