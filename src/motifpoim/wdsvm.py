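"""Weighted-degree string kernel, explicit sparse embedding, and linear SVM.

The weighted-degree (WD) kernel between two equal-length DNA sequences counts
matching positional substrings of every length l = 1..d,

    κ(x, x') = Σ_{l=1}^{d} Σ_{j=1}^{L−l+1} 1{x[j]^l = x'[j]^l},

and equals the inner product of binary feature maps indexed by positional
oligomers (l-mer, start). Because each sequence activates exactly one oligomer
per (l, position) window, the embedding is sparse and a primal linear SVM on
the explicit embedding is exactly equivalent to the dual WD-kernel SVM. The
trained weight vector, reorganized per oligomer length, is the input to POIM
computation.

Oligomers are encoded as base-4 integers (A=0, C=1, G=2, T=3), computed for
all windows at once by a shift-and-add recurrence over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from sklearn.svm import LinearSVC

from .datasets import ALPHABET, LabeledSequenceSet, _CODE

DEFAULT_C = 1.0
DEFAULT_DEGREE = 20
WEIGHT_DROP_TOL = 1e-12  # near-zero weights are pruned from the sparse vector


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 code vector (A=0, C=1, G=2, T=3)."""
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.uint8)
    except KeyError as e:
        raise ValueError(f"character {e} outside ACGT") from e


def decode_oligo(code: int, length: int) -> str:
    """Spell the base-4 ``code`` of an l-mer back into letters."""
    return "".join(ALPHABET[(code >> 2 * (length - 1 - t)) & 3] for t in range(length))


def po_code(seq, i: int, l: int) -> int:
    """Base-4 code of the l-mer starting at 1-based position ``i``.

    ``po_code(seq, i, l) = Σ_t code(seq[i+t]) · 4^(l−1−t)``.
    """
    codes = encode(seq) if isinstance(seq, str) else np.asarray(seq)
    L = len(codes)
    if not (1 <= i and i + l - 1 <= L):
        raise IndexError(f"window [{i}, {i + l - 1}] outside sequence of length {L}")
    val = 0
    for t in range(l):
        val = (val << 2) | int(codes[i - 1 + t])
    return val


def window_codes(codes: np.ndarray, l: int, prev: np.ndarray | None = None) -> np.ndarray:
    """Base-4 codes of all length-``l`` windows of each row of ``codes``.

    Returns an (n, L−l+1) int64 array. If ``prev`` holds the length-(l−1)
    window codes, the result is obtained by one shift-and-add step.
    """
    codes = np.atleast_2d(codes)
    L = codes.shape[1]
    if l > L:
        raise IndexError(f"window length {l} exceeds sequence length {L}")
    if prev is not None:
        return (prev[:, : L - l + 1] << 2) | codes[:, l - 1 :].astype(np.int64)
    out = codes[:, : L - l + 1].astype(np.int64)
    for t in range(1, l):
        out = (out << 2) | codes[:, t : L - l + 1 + t].astype(np.int64)
    return out


def wd_kernel(x, x2, k: int) -> int:
    """WD kernel value: count of matching positional substrings up to length k."""
    cx = encode(x) if isinstance(x, str) else np.asarray(x)
    cy = encode(x2) if isinstance(x2, str) else np.asarray(x2)
    if cx.shape != cy.shape:
        raise ValueError("sequences must have equal length")
    L = len(cx)
    if not 1 <= k <= L:
        raise ValueError("degree k must satisfy 1 <= k <= L")
    total, wx, wy = 0, None, None
    for l in range(1, k + 1):
        wx = window_codes(cx[None, :], l, wx)
        wy = window_codes(cy[None, :], l, wy)
        total += int(np.sum(wx == wy))
    return total


def _length_offsets(L: int, d: int) -> np.ndarray:
    """Cumulative key-space offsets so (l, position, code) packs into one int64."""
    sizes = [0] + [(4**l) * (L - l + 1) for l in range(1, d + 1)]
    off = np.cumsum(sizes)
    if off[-1] >= 2**62:
        raise ValueError("feature key space overflows int64; reduce degree")
    return off


def embed_keys(codes: np.ndarray, d: int) -> np.ndarray:
    """Active feature keys of every sequence, one row per sequence.

    Each of the Σ_l (L−l+1) windows contributes key
    ``offset[l] + (i−1)·4^l + code``; the WD kernel equals the intersection
    size of two sequences' key rows.
    """
    codes = np.atleast_2d(codes)
    n, L = codes.shape
    if d > L:
        raise ValueError("degree exceeds sequence length")
    off = _length_offsets(L, d)
    blocks, prev = [], None
    for l in range(1, d + 1):
        prev = window_codes(codes, l, prev)
        ncols = L - l + 1
        pos_term = (np.arange(ncols, dtype=np.int64) << (2 * l))
        blocks.append(off[l - 1] + pos_term[None, :] + prev)
    return np.concatenate(blocks, axis=1)


def embed(x, k: int) -> list[tuple[int, int, int]]:
    """Explicit sparse embedding as (length, 1-based position, code) triples."""
    cx = encode(x) if isinstance(x, str) else np.asarray(x)
    out = []
    prev = None
    for l in range(1, k + 1):
        prev = window_codes(cx[None, :], l, prev)
        for i0, c in enumerate(prev[0]):
            out.append((l, i0 + 1, int(c)))
    return out


@dataclass
class TrainedModel:
    """Linear WD-kernel SVM with its weight vector in sparse per-length form.

    ``weights[l]`` is a triple of aligned arrays ``(codes, positions, w)``
    holding the nonzero weights of all l-mer features; positions are 1-based.
    """

    weights: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]
    bias: float
    degree: int
    C: float
    L: int

    def nnz(self) -> int:
        return sum(len(w) for _, _, w in self.weights.values())

    def weight_norm(self) -> float:
        return float(
            np.sqrt(sum(np.sum(w**2) for _, _, w in self.weights.values()))
        )


def train(
    data: LabeledSequenceSet,
    C: float = DEFAULT_C,
    d: int = DEFAULT_DEGREE,
    seed: int = 0,
    tol: float = 1e-6,
) -> TrainedModel:
    """Fit an L2-regularized hinge-loss linear SVM on the explicit WD embedding.

    Parameters
    ----------
    data : LabeledSequenceSet
        Training sequences (equal length, both classes present).
    C : float
        SVM regularization constant (default 1).
    d : int
        WD-kernel degree — maximum oligomer length (default 20).
    seed : int
        Solver seed (liblinear dual coordinate descent).
    tol : float
        Solver stopping tolerance.
    """
    labels = np.asarray(data.labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    codes = data.codes()
    n, L = codes.shape
    if d > L:
        raise ValueError(f"degree {d} exceeds sequence length {L}")
    keys = embed_keys(codes, d)
    nfeat = keys.shape[1]
    vocab, col = np.unique(keys.ravel(), return_inverse=True)
    X = sparse.csr_matrix(
        (
            np.ones(n * nfeat, dtype=np.float64),
            col.astype(np.int32) if len(vocab) < 2**31 else col,
            np.arange(0, n * nfeat + 1, nfeat),
        ),
        shape=(n, len(vocab)),
    )
    clf = LinearSVC(
        C=C, loss="hinge", tol=tol, max_iter=20000, random_state=seed
    )
    clf.fit(X, labels)
    w = clf.coef_[0]
    bias = float(clf.intercept_[0])

    keep = np.abs(w) > WEIGHT_DROP_TOL
    vocab, w = vocab[keep], w[keep]
    off = _length_offsets(L, d)
    lengths = np.searchsorted(off, vocab, side="right")  # l such that off[l-1] <= key
    weights: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for l in range(1, d + 1):
        sel = lengths == l
        if not np.any(sel):
            continue
        rem = vocab[sel] - off[l - 1]
        i0 = rem >> (2 * l)
        code = rem & ((1 << (2 * l)) - 1)
        weights[l] = (code, (i0 + 1).astype(np.int64), w[sel])
    return TrainedModel(weights=weights, bias=bias, degree=d, C=C, L=L)


def score(model: TrainedModel, x) -> float:
    """SVM decision value s(x) = Σ_l Σ_i w_{(x[i]^l, i)} + bias."""
    cx = encode(x) if isinstance(x, str) else np.asarray(x)
    if cx.ndim == 1:
        return float(score_many(model, cx[None, :])[0])
    raise ValueError("score expects a single sequence; use score_many")


def score_many(model: TrainedModel, codes: np.ndarray) -> np.ndarray:
    """Decision values for an (n, L) code matrix."""
    codes = np.atleast_2d(codes)
    n, L = codes.shape
    if L != model.L:
        raise ValueError(f"sequence length {L} != model length {model.L}")
    out = np.full(n, model.bias, dtype=np.float64)
    prev = None
    for l in range(1, model.degree + 1):
        prev = window_codes(codes, l, prev)
        if l not in model.weights:
            continue
        code, pos1, w = model.weights[l]
        mkey = ((pos1 - 1) << (2 * l)) + code
        order = np.argsort(mkey)
        mkey, wl = mkey[order], w[order]
        ncols = L - l + 1
        qkey = (np.arange(ncols, dtype=np.int64) << (2 * l))[None, :] + prev
        qflat = qkey.ravel()
        idx = np.searchsorted(mkey, qflat)
        idx[idx == len(mkey)] = 0
        hit = mkey[idx] == qflat
        rows = np.repeat(np.arange(n), ncols)[hit]
        np.add.at(out, rows, wl[idx[hit]])
    return out


def accuracy(model: TrainedModel, data: LabeledSequenceSet) -> float:
    """Fraction of records whose decision-value sign matches the label."""
    s = score_many(model, data.codes())
    pred = np.where(s >= 0, 1, -1)
    return float(np.mean(pred == data.labels))


def save_model(model: TrainedModel, path: str) -> None:
    """Serialize as TSV: header comments (d, C, L, bias), then l/pos/oligo/weight rows."""
    with open(path, "w") as fh:
        fh.write(
            f"# degree={model.degree}\tC={float(model.C)!r}\tL={model.L}"
            f"\tbias={float(model.bias)!r}\n"
        )
        fh.write("l\tposition\toligomer\tweight\n")
        for l in sorted(model.weights):
            code, pos1, w = model.weights[l]
            for c, i, wi in zip(code, pos1, w):
                fh.write(f"{l}\t{int(i)}\t{decode_oligo(int(c), l)}\t{float(wi)!r}\n")


def load_model(path: str) -> TrainedModel:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(
            item.lstrip("# ").split("=") for item in header.strip().split("\t")
        )
        fh.readline()  # column names
        per_l: dict[int, list[tuple[int, int, float]]] = {}
        for line in fh:
            ls, ps, oligo, ws = line.rstrip("\n").split("\t")
            l = int(ls)
            per_l.setdefault(l, []).append(
                (po_code(oligo, 1, l), int(ps), float(ws))
            )
    weights = {}
    for l, rows in per_l.items():
        code = np.array([r[0] for r in rows], dtype=np.int64)
        pos1 = np.array([r[1] for r in rows], dtype=np.int64)
        w = np.array([r[2] for r in rows], dtype=np.float64)
        weights[l] = (code, pos1, w)
    return TrainedModel(
        weights=weights,
        bias=float(meta["bias"]),
        degree=int(meta["degree"]),
        C=float(meta["C"]),
        L=int(meta["L"]),
    )
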