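"""Simulated-annealing protein design at fixed mutational distance.

A design run keeps the number of mutations from wild type fixed at ``k`` and
searches amino-acid space with *exchange moves*: at each step ``m`` existing
substitutions (``m`` drawn from a zero-truncated Poisson, lambda = 1) are
reverted to wild type and ``m`` new substitutions are introduced at
currently wild-type positions (the just-reverted positions remain eligible,
which allows within-position amino-acid swaps).  Moves that increase the
model's predicted fitness are always accepted; others are accepted with
probability ``exp(dF / T)`` under a log-spaced temperature schedule from
``10^3`` down to ``10^-5``.

A campaign executes many independent runs, deduplicates the final designs,
clusters them with K-means on the one-hot encoding, and keeps the most fit
member of each cluster as a diverse representative set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.cluster import KMeans

from .sequences import AMINO_ACIDS, ProteinVariant, apply_substitutions, encode_batch


@dataclass
class AnnealConfig:
    """Settings for one simulated-annealing design run.

    ``T_start``/``T_end`` bound the logarithmic temperature gradient;
    ``move_size_mean`` is the (untruncated) Poisson mean of the number of
    substitutions exchanged per step.
    """

    k: int
    n_steps: int = 50_000
    T_start: float = 1e3
    T_end: float = 1e-5
    move_size_mean: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if not self.T_start > self.T_end > 0:
            raise ValueError("require T_start > T_end > 0")
        if self.move_size_mean <= 0:
            raise ValueError("move_size_mean must be positive")


#: Step counts used for combinations where long anneals over-converge
#: (fewer than the requested number of unique designs survive).
REDUCED_STEPS: dict[tuple[str, int], int] = {
    ("LR", 5): 10_000,
    ("FCN", 5): 10_000,
    ("LR", 10): 25_000,
    ("FCN", 10): 25_000,
    ("EnsM", 5): 25_000,
    ("EnsC", 5): 25_000,
}


def recommended_steps(model_tag: str, k: int, default: int = 50_000) -> int:
    """Default SA step count for a model/distance combination."""
    return REDUCED_STEPS.get((model_tag, k), default)


@dataclass
class DesignRun:
    """Outcome of one SA run: the best-so-far variant and optional trace."""

    variant: ProteinVariant
    predicted_fitness: float
    seed: int
    trace: pd.DataFrame | None = None


@dataclass
class Representative:
    variant: ProteinVariant
    predicted_fitness: float
    cluster_id: int
    run_id: int


@dataclass
class DesignCampaignResult:
    model_tag: str
    k: int
    runs: list[DesignRun]
    representatives: list[Representative] = field(default_factory=list)


def temperature_schedule(
    step: int, n_steps: int, T_start: float = 1e3, T_end: float = 1e-5
) -> float:
    """Geometric (log-linear) interpolation from ``T_start`` to ``T_end``."""
    if not 0 <= step < n_steps:
        raise ValueError(f"step {step} outside [0, {n_steps})")
    frac = step / (n_steps - 1)
    return float(
        10 ** (np.log10(T_start) + (np.log10(T_end) - np.log10(T_start)) * frac)
    )


def zero_truncated_poisson(rng: np.random.Generator, lam: float = 1.0) -> int:
    """Draw from Poisson(lam) conditioned on being >= 1 (by rejection)."""
    while True:
        m = int(rng.poisson(lam))
        if m >= 1:
            return m


def propose_exchange(
    current: ProteinVariant,
    k: int,
    rng: np.random.Generator,
    move_size_mean: float = 1.0,
) -> ProteinVariant:
    """Distance-preserving exchange move.

    Reverts ``m`` randomly chosen existing substitutions and introduces ``m``
    new ones (``m`` zero-truncated Poisson, clamped to ``k``).  New positions
    are drawn uniformly from positions that are wild type after the
    reversion -- including the just-reverted positions -- and new amino
    acids uniformly from the 19 non-wild-type residues.
    """
    wt = current.wild_type
    if len(current.substitutions) != k:
        raise ValueError("current variant does not have exactly k substitutions")
    if k > len(wt):
        raise ValueError("k exceeds the number of positions")
    m = min(zero_truncated_poisson(rng, move_size_mean), k)
    subs = sorted(current.substitutions)
    revert_idx = rng.choice(len(subs), size=m, replace=False)
    kept = {s for i, s in enumerate(subs) if i not in set(revert_idx.tolist())}
    occupied = {p for p, _ in kept}
    for _ in range(m):
        candidates = [p for p in range(len(wt)) if p not in occupied]
        pos = candidates[int(rng.integers(len(candidates)))]
        options = [aa for aa in AMINO_ACIDS if aa != wt[pos]]
        kept.add((pos, options[int(rng.integers(19))]))
        occupied.add(pos)
    return ProteinVariant(wt, frozenset(kept))


def accept_move(delta: float, temperature: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: accept improvements; otherwise with prob exp(dF/T)."""
    if delta > 0:
        return True
    with np.errstate(over="ignore"):
        return bool(rng.random() < np.exp(delta / temperature))


def _random_k_variant(wt: str, k: int, rng: np.random.Generator) -> ProteinVariant:
    positions = rng.choice(len(wt), size=k, replace=False)
    subs = set()
    for p in sorted(int(p) for p in positions):
        options = [aa for aa in AMINO_ACIDS if aa != wt[p]]
        subs.add((p, options[int(rng.integers(19))]))
    return ProteinVariant(wt, frozenset(subs))


def _run_chain_group(
    predict: Callable[[list[str]], np.ndarray],
    wt: str,
    config: AnnealConfig,
    seeds: Sequence[int],
    record_trace: bool = False,
) -> list[DesignRun]:
    """Run several SA chains in lockstep, batching model evaluations.

    Each chain owns its Generator, so chain trajectories depend only on the
    chain seed, the wild type and the (deterministic) model -- not on which
    other chains share the batch.
    """
    n = len(seeds)
    rngs = [np.random.default_rng(s) for s in seeds]
    current = [_random_k_variant(wt, config.k, r) for r in rngs]
    try:
        cur_fit = np.asarray(predict([v.sequence for v in current]), dtype=np.float64)
    except FloatingPointError as exc:
        raise FloatingPointError(
            f"non-finite model output at initialization (seeds {list(seeds)}): {exc}"
        ) from exc
    best = list(current)
    best_fit = cur_fit.copy()
    traces: list[list] | None = [[] for _ in range(n)] if record_trace else None

    for step in range(config.n_steps):
        T = temperature_schedule(step, config.n_steps, config.T_start, config.T_end)
        proposals = [
            propose_exchange(current[i], config.k, rngs[i], config.move_size_mean)
            for i in range(n)
        ]
        try:
            prop_fit = np.asarray(
                predict([v.sequence for v in proposals]), dtype=np.float64
            )
        except FloatingPointError as exc:
            raise FloatingPointError(
                f"non-finite model output at step {step} (seeds {list(seeds)}): {exc}"
            ) from exc
        for i in range(n):
            delta = prop_fit[i] - cur_fit[i]
            accepted = accept_move(delta, T, rngs[i])
            if accepted:
                current[i] = proposals[i]
                cur_fit[i] = prop_fit[i]
                if cur_fit[i] > best_fit[i]:
                    best_fit[i] = cur_fit[i]
                    best[i] = current[i]
            if traces is not None:
                traces[i].append(
                    (step, T, accepted, cur_fit[i], current[i].sequence)
                )

    runs = []
    for i in range(n):
        trace = None
        if traces is not None:
            trace = pd.DataFrame(
                traces[i],
                columns=["step", "temperature", "accepted", "current_fitness", "current_sequence"],
            )
        runs.append(DesignRun(best[i], float(best_fit[i]), int(seeds[i]), trace))
    return runs


def sa_design(
    model,
    wild_type: str,
    config: AnnealConfig,
    record_trace: bool = False,
) -> DesignRun:
    """One simulated-annealing design run; returns the best-so-far variant."""
    return _run_chain_group(
        model.predict, wild_type, config, [config.seed], record_trace
    )[0]


def run_campaign(
    model,
    wild_type: str,
    config: AnnealConfig,
    n_runs: int = 500,
    base_seed: int = 0,
    chunk_size: int = 50,
    n_jobs: int = 1,
) -> list[DesignRun]:
    """Execute ``n_runs`` independent SA runs (seed = base_seed + index).

    Chains are processed in fixed groups of ``chunk_size`` so model
    evaluations can be batched; the grouping depends only on the run index,
    so serial and joblib-parallel execution return identical results.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = [base_seed + i for i in range(n_runs)]
    groups = [seeds[i : i + chunk_size] for i in range(0, n_runs, chunk_size)]
    if n_jobs == 1:
        results = [
            _run_chain_group(model.predict, wild_type, config, g) for g in groups
        ]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_run_chain_group)(model.predict, wild_type, config, g)
            for g in groups
        )
    return [run for group in results for run in group]


def select_representatives(
    runs: Sequence[DesignRun],
    n_clusters: int = 41,
    seed: int = 0,
) -> list[Representative]:
    """Cluster unique final designs and keep the fittest member per cluster.

    K-means (k-means++ init, 10 restarts, fixed seed) on the flattened
    one-hot encodings of the deduplicated designs.  Raises if fewer unique
    designs than clusters exist; in that case rerun the campaign with fewer
    SA steps so the anneals converge less.
    """
    unique: dict[str, tuple[DesignRun, int]] = {}
    for run_id, run in enumerate(runs):
        seq = run.variant.sequence
        kept = unique.get(seq)
        if kept is None or run.predicted_fitness > kept[0].predicted_fitness:
            unique[seq] = (run, run_id)
    if len(unique) < n_clusters:
        raise ValueError(
            f"only {len(unique)} unique designs for {n_clusters} clusters; "
            "decrease the number of SA steps so runs converge less"
        )
    seqs = sorted(unique)
    X = encode_batch(seqs).reshape(len(seqs), -1)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    reps: list[Representative] = []
    for cluster in range(n_clusters):
        members = [i for i, lab in enumerate(labels) if lab == cluster]
        best_i = max(
            members,
            key=lambda i: (unique[seqs[i]][0].predicted_fitness, seqs[i]),
        )
        run, run_id = unique[seqs[best_i]]
        reps.append(
            Representative(run.variant, run.predicted_fitness, cluster, run_id)
        )
    return reps


def design_campaign(
    model,
    wild_type: str,
    config: AnnealConfig,
    model_tag: str = "model",
    n_runs: int = 500,
    n_clusters: int = 41,
    base_seed: int = 0,
    chunk_size: int = 50,
    n_jobs: int = 1,
) -> DesignCampaignResult:
    """Full pipeline: many SA runs, then cluster-based representative selection."""
    runs = run_campaign(
        model, wild_type, config, n_runs=n_runs, base_seed=base_seed,
        chunk_size=chunk_size, n_jobs=n_jobs,
    )
    reps = select_representatives(runs, n_clusters=n_clusters)
    return DesignCampaignResult(model_tag, config.k, runs, reps)
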