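"""Greedy initialization from differential POIMs and motif-quality scoring.

The differential POIM Ω concentrates high scores on the (length, position)
cells spanned by a planted motif: a motif of extent [s, s+k−1] produces, at
every oligomer length l, a run of high cells at starts s..s+k−l. Region
estimation thresholds Ω, takes the union of the sequence extents covered by
high cells, and reports one candidate region per contiguous extent; merged
regions produced by *overlapping* motifs are split at interior positions
where a fresh high run begins in the longer-oligomer rows (the visible
"drop" at the second motif's start).

PWM initialization is greedy: within the region, each column's leading
nucleotide is taken from the order-1 POIM and given probability 0.7 (0.1 for
the other three); μ starts at the region's left edge and σ = λ = 1.

Motif reconstruction quality (MRQ) is the JASPAR-style per-column similarity

    MRQ = Σ_{p=1}^{k} [ 1/k − (1/2k) · ‖t_p − r_p‖² ],

which is 1 for identical PWMs and 0 for one-hot PWMs disagreeing in every
column; a variant using the Euclidean distance ‖t_p − r_p‖ instead of its
square is available. Unequal lengths are compared at the best sliding offset
with overhanging columns scored zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import ALPHABET, LabeledSequenceSet
from .motifmodel import DEFAULT_EPS, Ppm
from .poim import DifferentialPoim, Poim


@dataclass
class MotifRegion:
    """Candidate motif location: 1-based start, length, accumulated Ω mass."""

    start: int
    length: int
    score: float


@dataclass
class MrqReport:
    """MRQ value with per-column contributions and the alignment offset used."""

    value: float
    per_column: np.ndarray
    offset: int = 0


def estimate_regions(
    diff: DifferentialPoim,
    rel_threshold: float = 0.25,
    min_run: int = 2,
) -> list[MotifRegion]:
    """Candidate motif regions from high-scoring differential-POIM cells.

    Cells with Ω ≥ ``rel_threshold`` times the global maximum are "high";
    within each row, runs shorter than ``min_run`` cells are discarded as
    isolated noise (a genuine motif of extent [s, s+k−1] produces, at every
    oligomer length l < k, a contiguous run of high cells at starts
    s..s+k−l). Surviving cells at (l, j) mark the sequence extent
    [j, j+l−1]; contiguous marked extents become candidate regions.

    Two *overlapping* motifs merge into one extent, but the longest
    signal-bearing row shows a one-cell drop at the first position whose
    l-mer crosses out of the first motif; that drop column marks the second
    motif's start, and the first motif ends l−2 positions after it. Merged
    extents are split accordingly.
    """
    omega = diff.values
    k_max, L = omega.shape
    global_max = float(omega.max(initial=0.0))
    if global_max <= 0:
        return []
    thr = rel_threshold * global_max
    high = np.zeros_like(omega, dtype=bool)
    informative: list[int] = []
    for l in range(2, k_max + 1):
        row = omega[l - 1, : L - l + 1] >= thr
        # drop isolated cells: keep runs of at least min_run
        keep = np.zeros_like(row)
        j0 = 0
        while j0 < row.size:
            if row[j0]:
                s = j0
                while j0 + 1 < row.size and row[j0 + 1]:
                    j0 += 1
                if j0 - s + 1 >= min_run:
                    keep[s : j0 + 1] = True
            j0 += 1
        if keep.any():
            high[l - 1, : L - l + 1] = keep
            informative.append(l)
    if not informative:
        return []

    covered = np.zeros(L + 2, dtype=bool)  # 1-based sequence positions
    mass = np.zeros(L + 2)
    for l in informative:
        for j0 in np.flatnonzero(high[l - 1]):
            covered[j0 + 1 : j0 + l + 1] = True
            mass[j0 + 1] += omega[l - 1, j0]

    regions: list[MotifRegion] = []
    j = 1
    while j <= L:
        if not covered[j]:
            j += 1
            continue
        end = j
        while end + 1 <= L and covered[end + 1]:
            end += 1
        regions.extend(_split_interval(high, mass, informative, j, end, L))
        j = end + 1
    return regions


def _split_interval(
    high: np.ndarray,
    mass: np.ndarray,
    informative: list[int],
    a: int,
    b: int,
    L: int,
) -> list[MotifRegion]:
    """Split one covered extent [a, b] at overlap drops of the longest row."""
    lbest = None
    for l in sorted(informative, reverse=True):
        row = high[l - 1]
        if any(row[j0] and a <= j0 + 1 and j0 + l <= b for j0 in range(L - l + 1)):
            lbest = l
            break
    if lbest is None:
        return [MotifRegion(start=a, length=b - a + 1, score=float(mass[a : b + 1].sum()))]
    row = high[lbest - 1]
    runs: list[tuple[int, int]] = []  # 1-based [start, end] of high runs
    j0 = a - 1
    while j0 <= min(b, L - lbest + 1) - 1:
        if row[j0]:
            s = j0
            while j0 + 1 <= min(b, L - lbest + 1) - 1 and row[j0 + 1]:
                j0 += 1
            runs.append((s + 1, j0 + 1))
        j0 += 1
    runs = [r for r in runs if r[1] - r[0] + 1 >= 2]  # 1-cell runs are noise
    if len(runs) <= 1:
        return [MotifRegion(start=a, length=b - a + 1, score=float(mass[a : b + 1].sum()))]
    starts = [a] + [runs[i][1] + 1 for i in range(len(runs) - 1)]  # drop columns
    ends = [starts[i + 1] + lbest - 2 for i in range(len(runs) - 1)] + [b]
    return [
        MotifRegion(start=s, length=e - s + 1, score=float(mass[s : e + 1].sum()))
        for s, e in zip(starts, ends)
    ]


def greedy_pwm_init(Q1: Poim, region: MotifRegion, sigma: float = 1.0, lam: float = 1.0) -> Ppm:
    """0.7/0.1 PWM from the order-1 POIM's per-column leading nucleotides."""
    if Q1.order != 1:
        raise ValueError("greedy initialization expects the order-1 POIM")
    ncols = Q1.values.shape[1]
    if not (1 <= region.start and region.start + region.length - 1 <= ncols):
        raise ValueError(f"region {region} outside POIM positions 1..{ncols}")
    cols = Q1.values[:, region.start - 1 : region.start - 1 + region.length]
    leaders = np.argmax(cols, axis=0)  # ties → smallest code → alphabetical
    r = np.full((4, region.length), 0.1)
    r[leaders, np.arange(region.length)] = 0.7
    return Ppm(r=r, mu=float(region.start), sigma=sigma, lam=lam)


def clamp_nonpolymorphic(ppm: Ppm, data: LabeledSequenceSet) -> Ppm:
    """One-hot any motif column whose aligned sequence position is invariant.

    A locus showing a single nucleotide in 100% of records carries no
    discriminative signal, so the SVM cannot recover it; it is placed into
    the PWM directly (probability 1 − 3ε under the ε floor).
    """
    if len(data) == 0:
        import warnings

        warnings.warn("empty dataset: nothing to clamp", stacklevel=2)
        return ppm
    codes = data.codes()
    start = int(round(ppm.mu))
    r = ppm.r.copy()
    for s in range(ppm.k):
        pos0 = start - 1 + s
        if not 0 <= pos0 < codes.shape[1]:
            continue
        col = codes[:, pos0]
        if np.all(col == col[0]):
            r[:, s] = DEFAULT_EPS
            r[col[0], s] = 1.0 - 3 * DEFAULT_EPS
    return Ppm(r=r, mu=ppm.mu, sigma=ppm.sigma, lam=ppm.lam)


def _check_simplex(pwm: np.ndarray) -> np.ndarray:
    pwm = np.asarray(pwm, dtype=np.float64)
    if pwm.ndim != 2 or pwm.shape[0] != 4:
        raise ValueError("PWM must be 4 x k")
    if np.any(pwm < -1e-12) or not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("PWM columns must be probability simplex points")
    return pwm


def _mrq_aligned(target: np.ndarray, cand: np.ndarray, sqrt: bool) -> np.ndarray:
    k = target.shape[1]
    d2 = np.sum((target - cand) ** 2, axis=0)
    dist = np.sqrt(d2) if sqrt else d2
    return 1.0 / k - dist / (2.0 * k)


def mrq(
    target: np.ndarray,
    candidate: np.ndarray,
    sqrt: bool = False,
    scale100: bool = False,
) -> MrqReport:
    """Motif reconstruction quality between two column-stochastic PWMs.

    Equal lengths: per-column squared-distance scoring (the default;
    ``sqrt=True`` selects the Euclidean-distance variant instead). Unequal
    lengths: the shorter PWM slides over the longer; overhanging columns
    score 0 and the best offset is reported. ``scale100`` returns the ×100
    presentation.
    """
    t = _check_simplex(target)
    c = _check_simplex(candidate)
    if t.shape[1] < c.shape[1]:
        long, short, swapped = c, t, True
    else:
        long, short, swapped = t, c, False
    k_long, k_short = long.shape[1], short.shape[1]
    best_val, best_cols, best_off = -np.inf, None, 0
    for off in range(k_long - k_short + 1):
        cols = np.zeros(k_long)
        seg = _mrq_aligned(long[:, off : off + k_short], short, sqrt)
        # rescale per-column terms to the longer length
        cols[off : off + k_short] = seg * k_short / k_long
        val = float(cols.sum())
        if val > best_val:
            best_val, best_cols, best_off = val, cols, off
    if scale100:
        best_val *= 100.0
        best_cols = best_cols * 100.0
    return MrqReport(value=best_val, per_column=best_cols, offset=best_off)


def consensus(pwm) -> str:
    """Per-column argmax spelling (ties resolved alphabetically)."""
    r = pwm.r if isinstance(pwm, Ppm) else np.asarray(pwm)
    return "".join(ALPHABET[int(b)] for b in np.argmax(r, axis=0))


def one_hot_pwm(motif: str) -> np.ndarray:
    """Exact one-hot PWM spelling ``motif`` (used as ground truth in scoring)."""
    from .datasets import _CODE

    r = np.zeros((4, len(motif)))
    for s, ch in enumerate(motif):
        r[_CODE[ch], s] = 1.0
    return r


def write_pfm(pwm, path: str, name: str = "motif") -> None:
    """JASPAR-style PFM text: header line then one row per nucleotide."""
    r = pwm.r if isinstance(pwm, Ppm) else np.asarray(pwm)
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for b, ch in enumerate(ALPHABET):
            vals = " ".join(f"{v:.6f}" for v in r[b])
            fh.write(f"{ch} [ {vals} ]\n")


def read_pfm(path: str) -> np.ndarray:
    rows = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            ch, rest = line[0], line[1:].strip().strip("[]").strip()
            rows[ch] = np.array([float(v) for v in rest.split()])
    r = np.vstack([rows[ch] for ch in ALPHABET])
    sums = r.sum(axis=0)
    return r / sums


def write_meme(pwm, path: str, name: str = "motif") -> None:
    """Minimal MEME motif text format (probability matrix, uniform background)."""
    r = pwm.r if isinstance(pwm, Ppm) else np.asarray(pwm)
    k = r.shape[1]
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {k}\n")
        for s in range(k):
            fh.write(" ".join(f"{r[b, s]:.6f}" for b in range(4)) + "\n")
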