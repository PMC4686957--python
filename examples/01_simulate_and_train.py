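"""Simulate a planted-motif benchmark and train the WD-kernel SVM.

Builds 2,500 uniform random DNA sequences of length 30 in which a quarter
carry the motif CCTATA at positions 11-16, trains an SVM on the explicit
weighted-degree embedding (all positional substrings up to length 20), and
reports training and held-out accuracy.
"""

from motifpoim import datasets, wdsvm
from motifpoim.pipeline import RunConfig, heldout_accuracy

data = datasets.make_s1(2500, seed=1)
print(f"{len(data)} sequences of length {data.length}, "
      f"{int((data.labels == 1).sum())} positives")

model = wdsvm.train(data, C=1.0, d=20, seed=1)
print(f"model keeps {model.nnz()} nonzero oligomer weights")

train_acc = wdsvm.accuracy(model, data)
test_acc = heldout_accuracy(model, RunConfig(dataset="s1", n=2500, seed=1), seed=99)
print(f"training accuracy {train_acc:.4f}, held-out (balanced) {test_acc:.4f}")
print("the held-out value is near 1: a single exact 6-mer at a fixed position"
      " separates the classes almost perfectly")
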