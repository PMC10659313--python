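"""Synthetic ground-truth fitness landscapes and dataset generators.

The simulator emulates the statistical structure of dense local
mutagenesis data around a small protein domain: a complete single-mutant
scan plus a dense sample of double mutants, and a complete 4-site
combinatorial saturation library.  Fitness is modelled as

    f(v) = baseline + sum_additive(v) + sum_pairwise_epistasis(v)

where additive effects are drawn per (position, amino acid) with a negative
mean (most mutations are deleterious) and sparse pairwise epistatic terms
contribute only when both participating substitutions are present
(specific-epistasis convention).  Measurement noise is additive Gaussian on
the fitness scale; the sort-seq count simulator provides the count-level
alternative noise model.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sequences import AMINO_ACIDS, AA_TO_INDEX, ProteinVariant, apply_substitutions

SPLITS = ("train", "val", "test")


@dataclass
class TrueLandscape:
    """Ground-truth fitness oracle: baseline + additive + pairwise epistasis.

    ``additive`` has shape ``(L, 20)`` with zeros at each wild-type residue.
    ``epistasis`` maps ``((pos_i, aa_i), (pos_j, aa_j))`` with ``pos_i <
    pos_j`` to a real interaction term that is active only when both
    substitutions are present.
    """

    wild_type: str
    baseline: float = 0.0
    additive: np.ndarray = None
    epistasis: dict[tuple[tuple[int, str], tuple[int, str]], float] = field(
        default_factory=dict
    )
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        L = len(self.wild_type)
        if self.additive is None:
            self.additive = np.zeros((L, len(AMINO_ACIDS)))
        self.additive = np.asarray(self.additive, dtype=np.float64)
        if self.additive.shape != (L, len(AMINO_ACIDS)):
            raise ValueError("additive table must have shape (L, 20)")
        for p, wt_aa in enumerate(self.wild_type):
            if self.additive[p, AA_TO_INDEX[wt_aa]] != 0.0:
                raise ValueError(f"additive[{p}][wild-type residue] must be zero")
        for (si, sj) in self.epistasis:
            if si[0] >= sj[0]:
                raise ValueError("epistasis keys must have pos_i < pos_j")

    @property
    def L(self) -> int:
        return len(self.wild_type)

    def fitness_of_substitutions(
        self, substitutions: Sequence[tuple[int, str]]
    ) -> float:
        total = self.baseline
        for pos, aa in substitutions:
            total += self.additive[pos, AA_TO_INDEX[aa]]
        if self.epistasis:
            subs = sorted(substitutions)
            for si, sj in itertools.combinations(subs, 2):
                term = self.epistasis.get((si, sj))
                if term is not None:
                    total += term
        return float(total)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "wild_type": self.wild_type,
            "baseline": self.baseline,
            "additive": self.additive.tolist(),
            "epistasis": [
                [list(si), list(sj), v] for (si, sj), v in sorted(self.epistasis.items())
            ],
            "noise_sd": self.noise_sd,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrueLandscape":
        payload = json.loads(Path(path).read_text())
        epi = {
            ((int(si[0]), si[1]), (int(sj[0]), sj[1])): float(v)
            for si, sj, v in payload["epistasis"]
        }
        return cls(
            wild_type=payload["wild_type"],
            baseline=payload["baseline"],
            additive=np.asarray(payload["additive"]),
            epistasis=epi,
            noise_sd=payload["noise_sd"],
        )


def generate_landscape(
    wild_type: str,
    additive_sd: float = 1.0,
    additive_mean: float = -0.5,
    epistasis_density: float = 0.02,
    epistasis_sd: float = 1.0,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TrueLandscape:
    """Draw a random landscape with sparse pairwise epistasis.

    Each non-wild-type (position, amino acid) additive effect is drawn from
    ``Normal(additive_mean, additive_sd)``; the negative default mean mimics
    the empirical fact that most mutations destabilize proteins.  Each of
    the ``C(L,2) * 19^2`` candidate substitution pairs carries an epistatic
    term with probability ``epistasis_density``, drawn from
    ``Normal(0, epistasis_sd)``.
    """
    if additive_sd < 0 or epistasis_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    if not 0.0 <= epistasis_density <= 1.0:
        raise ValueError("epistasis_density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    L = len(wild_type)
    additive = rng.normal(additive_mean, additive_sd, size=(L, len(AMINO_ACIDS)))
    for p, wt_aa in enumerate(wild_type):
        additive[p, AA_TO_INDEX[wt_aa]] = 0.0
    epistasis: dict = {}
    if epistasis_density > 0:
        non_wt = [
            [aa for aa in AMINO_ACIDS if aa != wild_type[p]] for p in range(L)
        ]
        for pi, pj in itertools.combinations(range(L), 2):
            mask = rng.random((19, 19)) < epistasis_density
            if not mask.any():
                continue
            values = rng.normal(0.0, epistasis_sd, size=(19, 19))
            for ai, aj in zip(*np.nonzero(mask)):
                key = ((pi, non_wt[pi][ai]), (pj, non_wt[pj][aj]))
                epistasis[key] = float(values[ai, aj])
    return TrueLandscape(
        wild_type=wild_type,
        baseline=baseline,
        additive=additive,
        epistasis=epistasis,
        noise_sd=noise_sd,
    )


def true_fitness(landscape: TrueLandscape, variant: ProteinVariant) -> float:
    """Noise-free oracle fitness of a variant on the landscape."""
    if variant.wild_type != landscape.wild_type:
        raise ValueError("variant wild type does not match the landscape")
    return landscape.fitness_of_substitutions(sorted(variant.substitutions))


@dataclass
class FitnessDataset:
    """Variant/fitness records with mutation-count strata and split labels.

    Backed by a DataFrame with columns ``variant`` (1-based mutation string,
    ``WT`` for the wild type), ``sequence``, ``fitness``, ``n_mutations``
    and ``split`` (train/val/test).
    """

    wild_type: str
    frame: pd.DataFrame

    REQUIRED = ("variant", "sequence", "fitness", "n_mutations", "split")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"missing dataset columns: {missing}")
        if not np.isfinite(self.frame["fitness"]).all():
            raise ValueError("non-finite fitness scores")

    def __len__(self) -> int:
        return len(self.frame)

    def split_frame(self, split: str) -> pd.DataFrame:
        if split not in SPLITS:
            raise ValueError(f"unknown split {split!r}")
        return self.frame[self.frame["split"] == split]

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, wild_type: str, path: str | Path) -> "FitnessDataset":
        return cls(wild_type, pd.read_csv(path, sep="\t"))


def _assign_splits(
    n: int, rng: np.random.Generator, fractions: tuple[float, float, float]
) -> np.ndarray:
    labels = np.empty(n, dtype=object)
    perm = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    labels[perm[:n_train]] = "train"
    labels[perm[n_train : n_train + n_val]] = "val"
    labels[perm[n_train + n_val :]] = "test"
    return labels


def _records_from_variants(
    landscape: TrueLandscape,
    variants: list[ProteinVariant],
    noise_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    scores = np.array([true_fitness(landscape, v) for v in variants])
    if noise_sd > 0:
        scores = scores + rng.normal(0.0, noise_sd, size=len(scores))
    return pd.DataFrame(
        {
            "variant": [v.mutation_string for v in variants],
            "sequence": [v.sequence for v in variants],
            "fitness": scores,
            "n_mutations": [v.n_mutations for v in variants],
        }
    )


def sample_local_dataset(
    landscape: TrueLandscape,
    double_fraction: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> FitnessDataset:
    """Wild type + all single mutants + a random fraction of double mutants.

    Emulates a local deep-mutational-scanning dataset: the complete ``L*19``
    single-mutant scan and ``double_fraction`` of the ``C(L,2)*19^2``
    possible double mutants, uniformly sampled without replacement.  Scores
    are true fitness plus ``Normal(0, noise_sd)``.
    """
    if not 0.0 < double_fraction <= 1.0:
        raise ValueError("double_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    wt = landscape.wild_type
    L = len(wt)
    variants = [ProteinVariant(wt, frozenset())]
    for p in range(L):
        for aa in AMINO_ACIDS:
            if aa != wt[p]:
                variants.append(ProteinVariant(wt, frozenset({(p, aa)})))
    pairs = list(itertools.combinations(range(L), 2))
    total_doubles = len(pairs) * 19 * 19
    n_doubles = int(round(double_fraction * total_doubles))
    chosen = rng.choice(total_doubles, size=n_doubles, replace=False)
    non_wt = [[aa for aa in AMINO_ACIDS if aa != wt[p]] for p in range(L)]
    for flat in np.sort(chosen):
        pair_idx, rem = divmod(int(flat), 361)
        ai, aj = divmod(rem, 19)
        pi, pj = pairs[pair_idx]
        variants.append(
            ProteinVariant(wt, frozenset({(pi, non_wt[pi][ai]), (pj, non_wt[pj][aj])}))
        )
    frame = _records_from_variants(landscape, variants, noise_sd, rng)
    frame["split"] = _assign_splits(len(frame), rng, split_fractions)
    return FitnessDataset(wt, frame)


def combinatorial_dataset(
    landscape: TrueLandscape,
    sites: Sequence[int],
    coverage_fraction: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    split: str = "test",
) -> FitnessDataset:
    """Complete (or subsampled) combinatorial saturation library at 4 sites.

    At full coverage this enumerates all ``20^4 = 160,000`` site
    combinations, including the wild type; smaller ``coverage_fraction``
    subsamples uniformly, emulating a partially characterized library.
    All records carry the same ``split`` label (default ``test``), since
    the library is an extrapolation benchmark rather than training data.
    """
    sites = list(sites)
    if len(set(sites)) != len(sites):
        raise ValueError("duplicate sites")
    if not 0.0 < coverage_fraction <= 1.0:
        raise ValueError("coverage_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    wt = landscape.wild_type
    combos = list(itertools.product(AMINO_ACIDS, repeat=len(sites)))
    if coverage_fraction < 1.0:
        idx = np.sort(
            rng.choice(len(combos), int(round(coverage_fraction * len(combos))), replace=False)
        )
        combos = [combos[i] for i in idx]
    variants = []
    for combo in combos:
        subs = frozenset(
            (p, aa) for p, aa in zip(sites, combo) if wt[p] != aa
        )
        variants.append(ProteinVariant(wt, subs))
    frame = _records_from_variants(landscape, variants, noise_sd, rng)
    frame["split"] = split
    return FitnessDataset(wt, frame)


def simulate_sortseq_counts(
    design_ids: Sequence[str],
    display_prob: np.ndarray,
    bind_prob: np.ndarray,
    depth: int = 1_000_000,
    seed: int = 0,
    abundance: np.ndarray | None = None,
    wt_id: str | None = None,
    w_b: float = 0.6,
    w_d: float = 0.4,
):
    """Simulate read counts for unsorted / display-only / binding populations.

    Reads are multinomial draws of total ``depth`` per population with
    design weights:

    * unsorted ``u``      -- proportional to input abundance,
    * display-only ``d``  -- abundance * display * (1 - bind),
    * binding ``b``       -- abundance * display * bind.

    Returns a :class:`~fitland.sortseq.SortSeqCounts`.  A population whose
    weights are identically zero receives all-zero counts.
    """
    from .sortseq import SortSeqCounts

    display_prob = np.asarray(display_prob, dtype=np.float64)
    bind_prob = np.asarray(bind_prob, dtype=np.float64)
    if np.any((display_prob < 0) | (display_prob > 1)):
        raise ValueError("display probabilities must lie in [0, 1]")
    if np.any((bind_prob < 0) | (bind_prob > 1)):
        raise ValueError("bind probabilities must lie in [0, 1]")
    if depth <= 0:
        raise ValueError("depth must be positive")
    n = len(design_ids)
    if abundance is None:
        abundance = np.ones(n)
    abundance = np.asarray(abundance, dtype=np.float64)
    rng = np.random.default_rng(seed)
    weights = {
        "count_u": abundance,
        "count_d": abundance * display_prob * (1.0 - bind_prob),
        "count_b": abundance * display_prob * bind_prob,
    }
    counts = {}
    for pop, w in weights.items():
        total = w.sum()
        if total == 0:
            counts[pop] = np.zeros(n, dtype=np.int64)
        else:
            counts[pop] = rng.multinomial(depth, w / total)
    frame = pd.DataFrame(counts, index=pd.Index(design_ids, name="design_id"))
    return SortSeqCounts(frame, wt_id=wt_id or design_ids[0], w_b=w_b, w_d=w_d)


def random_variant(
    wild_type: str, n_mutations: int, rng: np.random.Generator
) -> ProteinVariant:
    """Uniform random variant at a fixed Hamming distance from wild type."""
    L = len(wild_type)
    if n_mutations > L:
        raise ValueError("more mutations than positions")
    positions = rng.choice(L, size=n_mutations, replace=False)
    subs = set()
    for p in positions:
        options = [aa for aa in AMINO_ACIDS if aa != wild_type[p]]
        subs.add((int(p), options[rng.integers(19)]))
    return ProteinVariant(wild_type, frozenset(subs))
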