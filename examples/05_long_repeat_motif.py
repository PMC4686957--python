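"""Reconstruct a 200-nt repeat motif by windowed fitting and stitching.

A direct POIM over 200-mers would need 4^200 rows; instead the order-2 POIM
is partitioned into ten 20-column windows, one length-20 PPM is fitted per
window, and the fitted PWMs are stitched back together in genomic order.
"""

from motifpoim import datasets, initeval, poim, wdsvm
from motifpoim.pipeline import fit_long_motif

data = datasets.make_s4(2000, seed=5)  # ~2 min: the embedding has ~15M entries
model = wdsvm.train(data, C=1.0, d=20, seed=5)
poims = [poim.poim_from_model(model, k) for k in (1, 2, 3)]

regions = initeval.estimate_regions(poim.differential_poim(poims))
print(f"detected region: start {regions[0].start}, length {regions[0].length}")

stitched, window_fits = fit_long_motif(
    poims[1], poims[0], regions[0].start, parts=10, part_length=20
)
consensus = initeval.consensus(stitched)
print(f"stitched {stitched.r.shape[1]}-column consensus:")
print(consensus)
print("matches (TCGGA)x40:", consensus == "TCGGA" * 40)
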