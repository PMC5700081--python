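# dreammachine

Tools for building and analysing *simulated visual hallucinations*. The
package has two halves that mirror how such experiments are run:

1. **A Deep-Dream video engine.** Given a convolutional network, the engine
   clamps a chosen layer and iteratively rewrites each video frame by
   gradient ascent so the frame amplifies whatever that layer already
   detects — shallow layers yield geometric textures (simple
   hallucinations), deep layers yield object-like imagery (complex
   hallucinations). Frames inherit hallucinatory content from their
   predecessors along estimated dense optical flow, with per-pixel blending
   (0.9 in moving foreground, 0.1 in static background), so the imagery
   stays stable as the scene moves. Equirectangular panoramic frames get
   their seam wrap-padded so the dreamed content is continuous across the
   360° join.
2. **The statistics used to evaluate the experience.** JZS Bayes-factor
   t-tests (Cauchy(0, 0.707) prior on the standardized effect), Cohen's *d*
   from summary statistics, Bonferroni correction, a two-way
   repeated-measures ANOVA for tone-cued temporal-production data, and the
   screening rules used with that task. Because the Bayes factor and *d*
   depend on the data only through (t, n), the whole questionnaire analysis
   can be reproduced from published summary tables.

A small deterministic toy conv net (`default_toy_net`) ships with the
package so everything is testable without downloads; any object exposing
`activations(image, layer_id)` and `input_gradient(image, layer_id)` — e.g.
a wrapper around a pretrained classification network — can be dropped in
its place.

## The core computations

**Dream ascent.** With layer activations $a(x)$ of image $x$, the objective
is $L(x) = \tfrac12 \lVert a(x)\rVert^2$ and each step is

$$x \leftarrow \mathrm{clip}\Big(x + \eta\, \frac{\nabla_x L}{\langle |\nabla_x L| \rangle}\Big),$$

applied under a random cyclic jitter shift, over an octave pyramid
(defaults: 3 octaves, scale 1.8, 32 iterations per octave, jitter 32,
step 1.5, zoom 1).

**Temporal coherence.** For frame $t$, dense flow $f$ is estimated from raw
frame $t{-}1$ to raw frame $t$ (iterative Lucas–Kanade); the previous
dreamed frame is backward-warped along $f$ and blended per pixel:

$$\text{input}_t(p) = \rho(p)\,\widetilde{D}_{t-1}(p) + (1-\rho(p))\,\text{raw}_t(p),
\qquad \rho(p) = \begin{cases}0.9 & \lVert f(p)\rVert > 1\text{ px}\\ 0.1 & \text{otherwise},\end{cases}$$

and the blend is dreamed.

**JZS Bayes factor.** For an observed $t$ with $\nu$ degrees of freedom and
effective sample size $N$,

$$\mathrm{BF}_{10} = \frac{\int T_\nu\!\big(t;\ \delta\sqrt{N}\big)\,
\mathrm{Cauchy}(\delta; 0, r)\, d\delta}{T_\nu(t;\,0)}, \qquad r = 0.707,$$

evaluated as a scale-mixture-of-normals integral by adaptive quadrature in
log space ($N = n$ paired; $N = n_1 n_2/(n_1+n_2)$, pooled df, independent).

## Worked example

```python
>>> import numpy as np, dreammachine as dm
>>> net = dm.default_toy_net(seed=0)
>>> frames, truth_flow = dm.generate_synthetic_video(dm.SyntheticVideoSpec())
>>> sink = dm.ListFrameSink()
>>> manifest = dm.process_video(dm.ListFrameSource(frames), net,
...                             dm.PipelineConfig(), sink)
>>> len(sink.frames), round(min(manifest["objectives"]))
(8, 92299)
>>> res = dm.summary_ttest(t=3.705, n=21, design="paired")
>>> print(f"BF10 = {res.bf10:.3f}, d = {res.cohens_d:.3f}, p = {res.p_two_tailed:.4f}")
BF10 = 26.986, d = 0.808, p = 0.0014
>>> dm.interpret_bf(res.bf10)
'supports_H1'
```

The 8-frame manifest records per-frame dream objectives (all positive — the
clamped layer's activation energy after dreaming) and the seeds needed to
re-run bit-identically. The `summary_ttest` line re-analyses a published
summary (t(20) = 3.705, n = 21): a Bayes factor near 27 is strong evidence
for a difference, with a large paired effect of d ≈ 0.81.

Command-line wrappers `dream-image`, `dream-video` and `ascq-stats` expose
the same operations with the defaults above; see `--help` on each.

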