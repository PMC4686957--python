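"""Positional oligomer importance matrices (POIMs) and differential POIMs.

A POIM of order k scores every positional k-mer (y, j) by how much the SVM
decision value is expected to move when that k-mer is observed:

    Q_{k,y,j} = E[s(X) | X[j]^k = y] − E[s(X)],   X ~ U({A,C,G,T}^L).

Both expectations are available in closed form because s is linear in the
sparse WD features: a weight w_{(z,i)} of an l-mer feature contributes

    w · (P(X[i]^l = z | X[j]^k = y) − 4^{−l}),

which is zero unless the two positional oligomers overlap, −w·4^{−l} if they
overlap but disagree on a shared position, and w·(4^{c}−1)·4^{−l} when they
agree on all c shared positions. ``poim_from_model`` aggregates every nonzero
weight exactly (no sampling) by bucketing, per overlap geometry, the overlap
substring of z into a marginal table and broadcasting over the unconstrained
positions of y at the end. ``poim_bruteforce`` is the literal 4^L enumeration
used as the independent oracle in the tests.

The differential POIM condenses orders 1..k_max into a (length × position)
map Ω_{l,j} = q^{l,j}_max − max(q^{l−1,j}_max, q^{l−1,j+1}_max) with
q^{l,j}_max = max_y |Q_{l,y,j}|, highlighting where importance keeps growing
with oligomer length — the signature of a planted motif of that extent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wdsvm import TrainedModel, score_many, window_codes

MAX_POIM_ORDER = 8  # 4^k · L memory guard


@dataclass
class Poim:
    """Order-k POIM: 4^k oligomer rows × (L−k+1) start-position columns."""

    order: int
    values: np.ndarray  # (4^k, L-k+1)
    L: int

    def __post_init__(self) -> None:
        expected = (4**self.order, self.L - self.order + 1)
        if self.values.shape != expected:
            raise ValueError(f"POIM shape {self.values.shape} != {expected}")

    def q_max(self) -> np.ndarray:
        """Per-column maximum absolute importance, max_y |Q_{k,y,j}|."""
        return np.max(np.abs(self.values), axis=0)

    def argmax(self) -> tuple[int, int]:
        """(oligomer code, 1-based start) of the largest entry."""
        flat = int(np.argmax(self.values))
        y, j0 = divmod(flat, self.values.shape[1])
        return y, j0 + 1


@dataclass
class DifferentialPoim:
    """Ω matrix, rows are oligomer lengths 1..k_max, columns positions 1..L."""

    values: np.ndarray  # (k_max, L), row index l-1
    L: int

    @property
    def k_max(self) -> int:
        return self.values.shape[0]

    def omega(self, l: int, j: int) -> float:
        return float(self.values[l - 1, j - 1])


def expected_score(model: TrainedModel) -> float:
    """E[s(X)] under uniform X: bias + Σ_{l,z,i} w_{(z,i)} / 4^l."""
    total = model.bias
    for l, (_, _, w) in model.weights.items():
        total += float(np.sum(w)) * 0.25**l
    return total


def conditional_probability(
    z: int, i: int, l: int, y: int, j: int, k: int
) -> float:
    """P(X[i]^l = z | X[j]^k = y) for two positional oligomers.

    Returns 4^{−l} when the oligomers share no position, 0 when they overlap
    but disagree somewhere, and 4^{c−l} when they agree on all c shared
    positions (c = min(i+l−1, j+k−1) − max(i, j) + 1).
    """
    lo, hi = max(i, j), min(i + l - 1, j + k - 1)
    if hi < lo:
        return 0.25**l
    c = hi - lo + 1
    zsub = (z >> 2 * (l - 1 - (hi - i))) & ((1 << 2 * c) - 1)
    ysub = (y >> 2 * (k - 1 - (hi - j))) & ((1 << 2 * c) - 1)
    if zsub != ysub:
        return 0.0
    return 4.0**c * 0.25**l


def poim_from_model(model: TrainedModel, k: int) -> Poim:
    """Exact order-k POIM of a trained model by marginal-table aggregation."""
    L = model.L
    if not 1 <= k <= L:
        raise ValueError(f"order {k} invalid for sequence length {L}")
    if k > MAX_POIM_ORDER:
        raise ValueError(
            f"order {k} exceeds the practical cap {MAX_POIM_ORDER} (4^k·L memory)"
        )
    ncols = L - k + 1
    Q = np.zeros((4**k, ncols))
    colsub = np.zeros(ncols)  # uniform −w/4^l over every dependent column
    tables: dict[tuple[int, int], np.ndarray] = {}
    for l, (code, pos1, w) in model.weights.items():
        i0 = pos1 - 1  # 0-based feature start
        inv4l = 0.25**l
        for delta in range(-(l - 1), k):  # delta = i0 − j0, overlap guaranteed
            j0 = i0 - delta
            valid = (j0 >= 0) & (j0 <= L - k)
            if not np.any(valid):
                continue
            jv, wv, cv = j0[valid], w[valid], code[valid]
            a = max(0, delta)  # overlap window in y coordinates
            b = min(k - 1, delta + l - 1)
            c = b - a + 1
            shift = l - 1 - (b - delta)  # z digits trailing the overlap
            sub = (cv >> (2 * shift)) & ((1 << (2 * c)) - 1)
            np.add.at(colsub, jv, wv * inv4l)
            T = tables.setdefault((a, b), np.zeros((4**c, ncols)))
            np.add.at(T, (sub, jv), wv * (4.0**c) * inv4l)
    for (a, b), T in tables.items():
        c = b - a + 1
        Qv = Q.reshape(4**a, 4**c, 4 ** (k - 1 - b), ncols)
        Qv += T[None, :, None, :]
    Q -= colsub[None, :]
    return Poim(order=k, values=Q, L=L)


def poim_bruteforce(model: TrainedModel, k: int) -> Poim:
    """Literal enumeration oracle: conditional means of s over all 4^L sequences."""
    L = model.L
    if L > 8:
        raise ValueError("brute force refuses L > 8 (4^L sequences)")
    n = 4**L
    grid = np.array(
        np.unravel_index(np.arange(n), (4,) * L), dtype=np.uint8
    ).T.copy()
    s = score_many(model, grid)
    mean = float(np.mean(s))
    ncols = L - k + 1
    wk = window_codes(grid, k)
    Q = np.empty((4**k, ncols))
    for j0 in range(ncols):
        sums = np.bincount(wk[:, j0], weights=s, minlength=4**k)
        counts = np.bincount(wk[:, j0], minlength=4**k)
        Q[:, j0] = sums / counts - mean
    return Poim(order=k, values=Q, L=L)


def differential_poim(poims: list[Poim]) -> DifferentialPoim:
    """Ω matrix from consecutive-order POIMs 1..k_max (row 1 is zero).

    At the right boundary, where column j+1 does not exist at order l−1, the
    inner max runs over the single in-range term.
    """
    orders = sorted(p.order for p in poims)
    k_max = orders[-1]
    if orders != list(range(1, k_max + 1)):
        raise ValueError(f"need consecutive orders 1..k_max, got {orders}")
    by_order = {p.order: p for p in poims}
    L = by_order[1].L
    omega = np.zeros((k_max, L))
    qmax = {l: by_order[l].q_max() for l in orders}
    for l in range(2, k_max + 1):
        ncols = L - l + 1
        prev = qmax[l - 1]  # length L-l+2
        inner = prev[:ncols].copy()
        np.maximum(inner, prev[1 : ncols + 1], out=inner)
        omega[l - 1, :ncols] = qmax[l][:ncols] - inner
    return DifferentialPoim(values=omega, L=L)


def save_poim(poim: Poim, path: str) -> None:
    """Gzipped TSV of (k, position, oligomer string, value) rows."""
    import gzip

    from .wdsvm import decode_oligo

    with gzip.open(path, "wt") as fh:
        fh.write("k\tposition\toligomer\tvalue\n")
        for y in range(4**poim.order):
            oligo = decode_oligo(y, poim.order)
            for j0 in range(poim.values.shape[1]):
                fh.write(
                    f"{poim.order}\t{j0 + 1}\t{oligo}\t{float(poim.values[y, j0])!r}\n"
                )


def load_poim(path: str) -> Poim:
    import gzip

    from .wdsvm import po_code

    rows = []
    with gzip.open(path, "rt") as fh:
        fh.readline()
        for line in fh:
            ks, js, oligo, vs = line.rstrip("\n").split("\t")
            rows.append((int(ks), int(js), oligo, float(vs)))
    k = rows[0][0]
    ncols = max(r[1] for r in rows)
    values = np.zeros((4**k, ncols))
    for _, j, oligo, v in rows:
        values[po_code(oligo, 1, k), j - 1] = v
    return Poim(order=k, values=values, L=ncols + k - 1)


def save_differential_poim(diff: DifferentialPoim, path: str) -> None:
    np.savetxt(path, diff.values, delimiter="\t")


def load_differential_poim(path: str) -> DifferentialPoim:
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    return DifferentialPoim(values=values, L=values.shape[1])
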