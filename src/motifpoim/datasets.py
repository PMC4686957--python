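"""Synthetic planted-motif benchmarks and labeled-sequence file I/O.

Four generators build the controlled data sets used throughout:

* ``make_s1`` — a single exact motif (CCTATA) planted at a fixed position in a
  quarter of otherwise uniform random sequences,
* ``make_s2`` — the same motif with per-position point mutations at rate ``p``,
* ``make_s3`` — two *overlapping* motifs planted in disjoint sub-populations,
* ``make_s4`` — a 200-nt periodic repeat motif in length-400 sequences.

Sequences are uniform over {A,C,G,T}; positives are the motif-carrying records.
All randomness flows through a single ``numpy`` generator seeded explicitly, so
a fixed seed yields byte-identical data sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}

S1_MOTIF = "CCTATA"
S1_START = 11  # 1-based, inclusive
S3_MOTIF_A = "AATCTGGCGGT"
S3_START_A = 5
S3_MOTIF_B = "CAATAGCCTGATGGC"
S3_START_B = 10
S4_MOTIF = "TCGGA" * 40
S4_START = 21


@dataclass
class LabeledSequenceSet:
    """Equal-length DNA sequences with ±1 labels.

    Attributes
    ----------
    sequences : list of str
        DNA strings over {A,C,G,T}, all of identical length.
    labels : numpy.ndarray
        Vector of +1/−1 integers, one per sequence.
    seed : int or None
        Seed the set was generated with (None for file-loaded sets).
    """

    sequences: list[str]
    labels: np.ndarray
    seed: int | None = None
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sequences) != len(self.labels):
            raise ValueError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )
        if self.sequences:
            L = len(self.sequences[0])
            if L < 1:
                raise ValueError("sequences must be non-empty")
            for idx, s in enumerate(self.sequences):
                if len(s) != L:
                    raise ValueError(f"record {idx}: length {len(s)} != {L}")
        if self.labels.size and not np.all(np.isin(self.labels, (-1, 1))):
            raise ValueError("labels must be +1 or -1")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        """Common sequence length L."""
        if not self.sequences:
            raise ValueError("empty set has no length")
        return len(self.sequences[0])

    def codes(self) -> np.ndarray:
        """Sequences as an (n, L) uint8 matrix with A=0, C=1, G=2, T=3."""
        if self._codes is None:
            flat = "".join(self.sequences)
            arr = np.frombuffer(flat.encode("ascii"), dtype=np.uint8)
            lut = np.full(256, 255, dtype=np.uint8)
            for c, i in _CODE.items():
                lut[ord(c)] = i
            codes = lut[arr]
            if np.any(codes == 255):
                bad = int(np.argmax(codes == 255)) // self.length
                raise ValueError(f"record {bad}: character outside ACGT")
            self._codes = codes.reshape(len(self.sequences), self.length)
        return self._codes


def _decode(codes: np.ndarray) -> list[str]:
    lut = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)
    return [bytes(lut[row]).decode("ascii") for row in codes]


def _encode_motif(motif: str) -> np.ndarray:
    return np.array([_CODE[c] for c in motif], dtype=np.uint8)


def _uniform_codes(rng: np.random.Generator, n: int, L: int) -> np.ndarray:
    return rng.integers(0, 4, size=(n, L), dtype=np.uint8)


def _finish(
    codes: np.ndarray, labels: np.ndarray, rng: np.random.Generator, seed: int
) -> LabeledSequenceSet:
    # final record-order shuffle so class membership is not positional
    order = rng.permutation(len(labels))
    codes = codes[order]
    labels = labels[order]
    out = LabeledSequenceSet(_decode(codes), labels, seed=seed)
    out._codes = codes
    return out


def make_s1(n: int, seed: int) -> LabeledSequenceSet:
    """Single exact planted motif: CCTATA at positions 11–16 in 25% of records.

    Parameters
    ----------
    n : int
        Number of length-30 sequences (n ≥ 4 so a 25% subset exists).
    seed : int
        RNG seed; fixed seed reproduces the set exactly.
    """
    if n < 4:
        raise ValueError("n must be at least 4 to form a 25% positive subset")
    rng = np.random.default_rng(seed)
    codes = _uniform_codes(rng, n, 30)
    m = math.ceil(0.25 * n)
    pos_idx = rng.permutation(n)[:m]
    codes[pos_idx, S1_START - 1 : S1_START - 1 + len(S1_MOTIF)] = _encode_motif(
        S1_MOTIF
    )
    labels = np.full(n, -1, dtype=int)
    labels[pos_idx] = 1
    return _finish(codes, labels, rng, seed)


def make_s2(n: int, p: float, seed: int) -> LabeledSequenceSet:
    """S1 with each motif position independently mutated with probability p.

    A mutation replaces the nucleotide by a uniform draw over all four letters
    (so it may restore the original); at p=1 the motif region of positives is
    indistinguishable from background.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("mutation probability p must lie in [0, 1]")
    if n < 4:
        raise ValueError("n must be at least 4 to form a 25% positive subset")
    rng = np.random.default_rng(seed)
    codes = _uniform_codes(rng, n, 30)
    m = math.ceil(0.25 * n)
    pos_idx = rng.permutation(n)[:m]
    k = len(S1_MOTIF)
    codes[pos_idx, S1_START - 1 : S1_START - 1 + k] = _encode_motif(S1_MOTIF)
    mutate = rng.random((m, k)) < p
    replacement = rng.integers(0, 4, size=(m, k), dtype=np.uint8)
    region = codes[pos_idx, S1_START - 1 : S1_START - 1 + k]
    codes[pos_idx, S1_START - 1 : S1_START - 1 + k] = np.where(
        mutate, replacement, region
    )
    labels = np.full(n, -1, dtype=int)
    labels[pos_idx] = 1
    return _finish(codes, labels, rng, seed)


def make_s3(n: int, seed: int) -> LabeledSequenceSet:
    """Two overlapping motifs in disjoint 12.5% sub-populations.

    AATCTGGCGGT is planted at positions 5–15 and CAATAGCCTGATGGC at 10–24;
    together the 25% motif-carrying records are the positives.
    """
    if n < 8:
        raise ValueError("n must be at least 8 to form two 12.5% subsets")
    rng = np.random.default_rng(seed)
    codes = _uniform_codes(rng, n, 30)
    m = math.ceil(0.125 * n)
    perm = rng.permutation(n)
    idx_a, idx_b = perm[:m], perm[m : 2 * m]
    codes[idx_a, S3_START_A - 1 : S3_START_A - 1 + len(S3_MOTIF_A)] = _encode_motif(
        S3_MOTIF_A
    )
    codes[idx_b, S3_START_B - 1 : S3_START_B - 1 + len(S3_MOTIF_B)] = _encode_motif(
        S3_MOTIF_B
    )
    labels = np.full(n, -1, dtype=int)
    labels[perm[: 2 * m]] = 1
    return _finish(codes, labels, rng, seed)


def make_s4(n: int, seed: int) -> LabeledSequenceSet:
    """200-nt periodic repeat (TCGGA × 40) at positions 21–220, L=400, 25% positives."""
    if n < 4:
        raise ValueError("n must be at least 4 to form a 25% positive subset")
    rng = np.random.default_rng(seed)
    codes = _uniform_codes(rng, n, 400)
    m = math.ceil(0.25 * n)
    pos_idx = rng.permutation(n)[:m]
    codes[pos_idx, S4_START - 1 : S4_START - 1 + len(S4_MOTIF)] = _encode_motif(
        S4_MOTIF
    )
    labels = np.full(n, -1, dtype=int)
    labels[pos_idx] = 1
    return _finish(codes, labels, rng, seed)


def write_fasta_labeled(
    data: LabeledSequenceSet, path_fasta: str, path_labels: str
) -> None:
    """Write sequences as FASTA and labels as a two-column TSV (id, ±1)."""
    records = [
        SeqRecord(Seq(s), id=f"seq{i}", description="")
        for i, s in enumerate(data.sequences)
    ]
    SeqIO.write(records, path_fasta, "fasta")
    with open(path_labels, "w") as fh:
        for i, y in enumerate(data.labels):
            fh.write(f"seq{i}\t{int(y):+d}\n")


def read_fasta_labeled(path_fasta: str, path_labels: str) -> LabeledSequenceSet:
    """Read a FASTA file plus label sidecar into a :class:`LabeledSequenceSet`.

    Sequences are uppercased; any character outside ACGT, a length mismatch, or
    a record-count mismatch raises ``ValueError`` naming the record.
    """
    records = list(SeqIO.parse(path_fasta, "fasta"))
    sequences: list[str] = []
    for idx, rec in enumerate(records):
        s = str(rec.seq).upper()
        bad = set(s) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"record {idx} ({rec.id}): characters {sorted(bad)} outside ACGT"
            )
        sequences.append(s)
    if sequences:
        L = len(sequences[0])
        for idx, s in enumerate(sequences):
            if len(s) != L:
                raise ValueError(f"record {idx}: length {len(s)} != {L}")
    labels = []
    with open(path_labels) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"labels line {len(labels)}: expected two columns")
            labels.append(int(parts[1]))
    if len(labels) != len(sequences):
        raise ValueError(
            f"{len(sequences)} FASTA records but {len(labels)} labels"
        )
    return LabeledSequenceSet(sequences, np.asarray(labels, dtype=int))
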