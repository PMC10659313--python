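"""Core protein sequence types, encodings, distances and sequence analytics.

Conventions used throughout the package:

* Substitution positions are 0-based internally; all user-facing reports
  (mutation strings, TSV output) use the 1-based protein convention.
* The canonical amino-acid alphabet is ordered alphabetically by one-letter
  code: ``ACDEFGHIKLMNPQRSTVWY``.  This order is frozen; one-hot columns,
  entropy counts and random residue draws all use it.
* Site entropies are reported in bits (log base 2).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

#: Canonical 20-letter amino-acid alphabet, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Index lookup for :data:`AMINO_ACIDS` (a bijection).
AA_TO_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class LengthMismatchError(ValueError):
    """Raised when two sequences that must be aligned differ in length."""


def hamming_distance(a: str, b: str) -> int:
    """Number of positions at which two equal-length sequences differ.

    Raises
    ------
    LengthMismatchError
        If the sequences have different lengths.
    """
    if len(a) != len(b):
        raise LengthMismatchError(
            f"sequence lengths differ: {len(a)} vs {len(b)}"
        )
    return sum(x != y for x, y in zip(a, b))


def apply_substitutions(wild_type: str, substitutions: Iterable[tuple[int, str]]) -> str:
    """Apply a set of ``(position, amino_acid)`` substitutions to a sequence.

    Positions are 0-based.  Each substituted amino acid must differ from the
    wild-type residue at its position, and positions must be unique, so the
    result differs from ``wild_type`` at exactly ``len(substitutions)`` sites.
    """
    seq = list(wild_type)
    seen: set[int] = set()
    for pos, aa in substitutions:
        if not 0 <= pos < len(seq):
            raise IndexError(f"substitution position {pos} out of range for L={len(seq)}")
        if pos in seen:
            raise ValueError(f"duplicate substitution position {pos}")
        if seq[pos] == aa:
            raise ValueError(
                f"substitution at position {pos} equals wild-type residue {aa!r}"
            )
        if aa not in AA_TO_INDEX:
            raise ValueError(f"unknown amino acid {aa!r}")
        seen.add(pos)
        seq[pos] = aa
    return "".join(seq)


@dataclass(frozen=True)
class ProteinVariant:
    """A protein sequence expressed as wild type plus a substitution set.

    ``substitutions`` is a frozenset of ``(position, amino_acid)`` pairs with
    0-based positions.  The Hamming distance to the wild type equals the
    number of substitutions by construction.
    """

    wild_type: str
    substitutions: frozenset[tuple[int, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.substitutions]
        if len(positions) != len(set(positions)):
            raise ValueError("substitution positions must be unique")
        for pos, aa in self.substitutions:
            if not 0 <= pos < len(self.wild_type):
                raise IndexError(f"position {pos} out of range")
            if self.wild_type[pos] == aa:
                raise ValueError(
                    f"substitution {aa}{pos} equals the wild-type residue"
                )

    @property
    def sequence(self) -> str:
        return apply_substitutions(self.wild_type, self.substitutions)

    @property
    def n_mutations(self) -> int:
        """Hamming distance from the wild type."""
        return len(self.substitutions)

    @property
    def mutation_string(self) -> str:
        """1-based ``A23Y,K31M``-style representation; ``WT`` if unmutated."""
        if not self.substitutions:
            return "WT"
        subs = sorted(self.substitutions)
        return ",".join(
            f"{self.wild_type[p]}{p + 1}{aa}" for p, aa in subs
        )

    @classmethod
    def from_mutation_string(cls, wild_type: str, text: str) -> "ProteinVariant":
        """Parse a 1-based mutation string such as ``"A23Y,K31M"`` or ``"WT"``."""
        text = text.strip()
        if text in ("", "WT", "wt"):
            return cls(wild_type, frozenset())
        subs = []
        for token in text.split(","):
            m = _MUTATION_RE.match(token.strip())
            if m is None:
                raise ValueError(f"unparseable mutation token {token!r}")
            wt_aa, pos1, new_aa = m.group(1), int(m.group(2)), m.group(3)
            pos = pos1 - 1
            if not 0 <= pos < len(wild_type):
                raise ValueError(f"mutation position {pos1} out of range")
            if wild_type[pos] != wt_aa:
                raise ValueError(
                    f"token {token!r}: wild type has {wild_type[pos]!r} at "
                    f"position {pos1}, not {wt_aa!r}"
                )
            subs.append((pos, new_aa))
        return cls(wild_type, frozenset(subs))

    @classmethod
    def from_sequence(cls, wild_type: str, sequence: str) -> "ProteinVariant":
        if len(sequence) != len(wild_type):
            raise LengthMismatchError("variant sequence length differs from wild type")
        subs = frozenset(
            (i, aa) for i, (w, aa) in enumerate(zip(wild_type, sequence)) if w != aa
        )
        return cls(wild_type, subs)


def one_hot_encode(seq: str, alphabet: str = AMINO_ACIDS) -> np.ndarray:
    """Encode a sequence as an ``L x |alphabet|`` binary matrix.

    Each row has exactly one nonzero entry (the residue's alphabet index).
    """
    index = {aa: i for i, aa in enumerate(alphabet)}
    out = np.zeros((len(seq), len(alphabet)), dtype=np.float64)
    for i, aa in enumerate(seq):
        try:
            out[i, index[aa]] = 1.0
        except KeyError:
            raise ValueError(f"residue {aa!r} not in alphabet") from None
    return out


def one_hot_decode(matrix: np.ndarray, alphabet: str = AMINO_ACIDS) -> str:
    """Inverse of :func:`one_hot_encode`."""
    idx = np.asarray(matrix).argmax(axis=1)
    return "".join(alphabet[i] for i in idx)


def encode_batch(seqs: Sequence[str], alphabet: str = AMINO_ACIDS) -> np.ndarray:
    """One-hot encode many equal-length sequences into ``(n, L, A)``."""
    if len(seqs) == 0:
        raise ValueError("empty sequence collection")
    L = len(seqs[0])
    lut = np.full(128, -1, dtype=np.int64)
    for i, aa in enumerate(alphabet):
        lut[ord(aa)] = i
    codes = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    idx = lut[codes]
    if (idx < 0).any():
        bad = chr(codes[int(np.argmax(idx < 0))])
        raise ValueError(f"residue {bad!r} not in alphabet")
    idx = idx.reshape(len(seqs), L)
    out = np.zeros((len(seqs), L, len(alphabet)), dtype=np.float64)
    np.put_along_axis(out, idx[:, :, None], 1.0, axis=2)
    return out


def site_entropy(seqs: Sequence[str], base: float = 2.0) -> np.ndarray:
    """Per-position Shannon entropy of an aligned sequence collection.

    Entropy at each column is ``-sum_a p_a log(p_a)`` over the observed
    amino-acid frequencies, in bits by default.  Bounded by ``log2(20)``
    for the canonical alphabet.
    """
    if len(seqs) == 0:
        raise ValueError("empty sequence collection")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise LengthMismatchError("ragged sequence collection")
    onehot = encode_batch(seqs)
    freqs = onehot.mean(axis=0)  # (L, 20)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log(freqs), 0.0)
    return -terms.sum(axis=1) / np.log(base)


def find_kex2_sites(seq: str) -> list[int]:
    """0-based start positions of all ``[KR]R`` dipeptides, overlaps allowed.

    KEX2 is a yeast Golgi protease that cleaves secreted proteins at exposed
    Lys/Arg-Arg sites; unfolded displayed proteins carrying such a site tend
    to be cleaved and lost from the cell surface.  This scan is purely
    sequence-based: whether a site is structurally exposed is not evaluated.
    """
    return [
        i for i in range(len(seq) - 1) if seq[i] in "KR" and seq[i + 1] == "R"
    ]


def _classical_mds_init(d: np.ndarray, dim: int) -> np.ndarray:
    """Classical (Torgerson) MDS on a squared-distance matrix for initialization."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dim]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def _stress(d: np.ndarray, x: np.ndarray) -> float:
    diff = x[:, None, :] - x[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    iu = np.triu_indices(d.shape[0], k=1)
    return float(((d[iu] - dist[iu]) ** 2).sum())


def mds_embed(
    seqs: Sequence[str],
    dim: int = 2,
    *,
    max_iter: int = 300,
    tol: float = 1e-8,
    seed: int = 0,
    return_stress: bool = False,
):
    """Embed sequences in ``dim`` dimensions preserving Hamming distances.

    Metric MDS by SMACOF stress majorization (Guttman transform) initialized
    from classical MDS of the pairwise Hamming distance matrix.  The
    majorization update never increases the raw stress, so the returned
    stress trajectory is non-increasing.  Deterministic given ``seed``
    (the seed only matters for degenerate all-zero distance matrices, where
    a tiny random jitter breaks ties).

    Returns ``coords`` of shape ``(n, dim)``; with ``return_stress=True``
    also returns the per-iteration stress values.
    """
    n = len(seqs)
    if n < dim + 1:
        raise ValueError(f"need at least {dim + 1} sequences, got {n}")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = hamming_distance(seqs[i], seqs[j])
    x = _classical_mds_init(d, dim)
    if not np.any(d):
        coords = np.zeros((n, dim))
        return (coords, [0.0]) if return_stress else coords
    if np.allclose(x, 0):
        x = np.random.default_rng(seed).normal(scale=1e-4, size=(n, dim))
    stresses = [_stress(d, x)]
    for _ in range(max_iter):
        diff = x[:, None, :] - x[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=2))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, d / dist, 0.0)
        b = -ratio
        np.fill_diagonal(b, 0.0)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = (b @ x) / n
        stresses.append(_stress(d, x))
        if stresses[-2] - stresses[-1] < tol * max(stresses[-2], 1e-12):
            break
    return (x, stresses) if return_stress else x


def _codon_choices() -> dict[str, list[str]]:
    table = unambiguous_dna_by_id[1]
    choices: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        choices.setdefault(aa, []).append(codon)
    for aa in choices:
        choices[aa].sort()
    return choices


_CODONS = _codon_choices()


def reverse_translate(protein: str, variant_index: int = 0, seed: int = 0) -> str:
    """Deterministic synonymous reverse translation of a protein sequence.

    The standard-table codons for each residue are shuffled once with
    ``seed`` and the codon at ``variant_index`` (modulo the number of
    synonymous codons) is selected.  Distinct ``variant_index`` values give
    distinct nucleotide sequences whenever any residue has more than one
    codon, supporting synonymous-pair internal controls.
    """
    rng = np.random.default_rng(seed)
    order = {
        aa: list(rng.permutation(codons)) for aa, codons in sorted(_CODONS.items())
    }
    out = []
    for aa in protein:
        if aa not in order:
            raise ValueError(f"unknown amino acid {aa!r}")
        codons = order[aa]
        out.append(codons[variant_index % len(codons)])
    return "".join(out)


def translate(nucleotides: str) -> str:
    """Standard-table translation (no stop handling; length must be 3L)."""
    return str(Seq(nucleotides).translate())
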