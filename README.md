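# motifpoim

Reconstruct the DNA sequence motifs that drive a trained string-kernel SVM.

Support vector machines with the weighted-degree (WD) kernel are among the
most accurate classifiers for genomic discrimination tasks such as splice-site
detection, but the decision function is a black box: the biological motifs it
relies on are hidden in a weight vector over billions of positional oligomer
features. *Positional oligomer importance matrices* (POIMs) expose that
information — each entry scores a (k-mer, position) pair by how much the
decision value is expected to move when that k-mer is present — yet a POIM of
order k has 4^k rows, so direct inspection stops being feasible around k ≈ 5.

`motifpoim` goes the other way: it treats the motif as the free parameter of a
probabilistic model, computes the POIM that a candidate motif *would* generate,
and optimizes the motif until its induced POIM matches the one actually
observed. The recovered motifs are ordinary position weight matrices (PWMs)
and may be overlapping or hundreds of nucleotides long.

## The model

For sequences x ∈ {A,C,G,T}^L the WD kernel counts matching positional
substrings up to degree d,

    κ(x, x') = Σ_{l=1}^{d} Σ_{j=1}^{L−l+1} 1{x[j]^l = x'[j]^l},

and the SVM score is linear in a sparse embedding, s(x) = Σ_{l,i} w_{(x[i]^l, i)}.
The order-k POIM is the centered conditional expectation under uniform X,

    Q_{k,y,j} = E[s(X) | X[j]^k = y] − E[s(X)],

computed here in closed form from the nonzero weights (no sampling).

A candidate motif is a *probabilistic positional motif* (PPM) m = (r, μ, σ):
a 4×k column-stochastic PWM r with a Gaussian start-position belief N(μ, σ²).
It induces weights v_{(z,i)} = N(i; μ, σ²) · Π_l r[z_l, l] over positional
k-mers and hence its own POIM R(m). Long motifs are decomposed into
D = k − k̃ + 1 overlapping SubPPMs of small order k̃ ∈ {2, 3}, so the
reconstruction always lives at order k̃. Motif recovery minimizes

    f = ½ Σ_{y,j} ( Σ_t λ_t R_{y,j}(m_t) − Q_{k̃,y,j} )²

over (r, μ, σ, λ) of all candidate motifs jointly with bound-constrained
L-BFGS-B and analytic gradients. Initialization is greedy: the differential
POIM localizes each motif's extent, and the order-1 POIM seeds each PWM column
with 0.7 on the leading nucleotide. Overlapping motifs are fitted sequentially
with POIM deflation before a final joint polish, and very long motifs are
fitted in windows whose PWMs are stitched in genomic order.

Everything is validated against literal brute-force oracles (4^L enumeration
of the POIM definition, the reduced two-set summation, finite-difference
gradients) in the test suite.

## Worked example

```python
import tempfile
from motifpoim.pipeline import RunConfig, run

report = run(
    RunConfig(dataset="s1", n=2500, K=(6,), truth_motif="CCTATA", seed=1),
    tempfile.mkdtemp(),
)
m = report["motifs"][0]
print(m["consensus"], round(m["mrq"], 3), round(report["heldout_accuracy"], 4))
```

This simulates 2,500 length-30 sequences with CCTATA planted at positions
11–16 in 25% of them, trains the WD-kernel SVM (C = 1, d = 20), locates the
motif from the differential POIM, and fits one length-6 PPM. It prints

```
CCTATA 0.956 0.9992
```

— the recovered consensus equals the planted motif, the motif reconstruction
quality (MRQ; 1 = identical PWMs) against the one-hot truth is 0.956, and the
SVM's held-out balanced accuracy is 0.9992. The fitted PWM itself, the POIM
tables and the model are written to the run directory (see
`examples/03_recover_single_motif.py` for the full script; the other examples
cover POIM inspection, overlapping motifs and the 200-nt repeat motif).

The same pipeline is available from the shell:

```sh
motifpoim simulate --dataset s1 --n 2500 --seed 1 --out s1
motifpoim train --fasta s1.fasta --labels s1.labels.tsv --out model.tsv
motifpoim poim --model model.tsv --kmax 7 --out poims/
motifpoim fit --poims poims/ --lengths 6 --out motifs/
motifpoim eval --truth truth.pfm --found motifs/motif0.pfm
```

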