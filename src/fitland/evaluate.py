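"""Extrapolation metrics: stratified rank correlation, recall@budget, and
ensemble divergence along mutational trajectories.

A model trained on a local dataset (singles and doubles) is evaluated on
variants with more mutations than it ever saw.  ``stratified_spearman``
quantifies ranking accuracy separately within each mutation-count stratum;
``recall_at_budget`` measures how many of the true top variants a model
recovers when allowed to nominate N candidates; trajectory divergence
tracks how an ensemble's member predictions spread out as a mutational
pathway leaves the training regime.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr


@dataclass
class RecallQuery:
    """A design budget N evaluated against the true top ``top_size`` set."""

    budget: int
    top_size: int = 100

    def __post_init__(self) -> None:
        if self.budget < 1 or self.top_size < 1:
            raise ValueError("budget and top_size must be >= 1")


def stratified_spearman(
    predicted: Sequence[float],
    observed: Sequence[float],
    mutation_counts: Sequence[int],
    min_stratum_size: int = 3,
) -> pd.Series:
    """Spearman rho between predictions and observations per mutation count.

    Ties are handled by average ranks (the scipy convention).  Strata with
    fewer than ``min_stratum_size`` members are reported as NaN rather than
    silently dropped.
    """
    predicted = np.asarray(predicted, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    counts = np.asarray(mutation_counts)
    if not (len(predicted) == len(observed) == len(counts)):
        raise ValueError("input vectors must have equal length")
    out = {}
    for k in sorted(set(counts.tolist())):
        mask = counts == k
        if mask.sum() < min_stratum_size:
            out[k] = np.nan
            continue
        rho = spearmanr(predicted[mask], observed[mask]).statistic
        out[k] = float(rho)
    return pd.Series(out, name="spearman_rho").rename_axis("n_mutations")


def _top_indices(scores: np.ndarray, n: int, labels: Sequence[str]) -> set[int]:
    """Indices of the top-n scores; ties broken by (score desc, label asc)."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], labels[i]))
    return set(order[:n])


def recall_at_budget(
    predicted: Sequence[float],
    observed: Sequence[float],
    query: RecallQuery,
    labels: Sequence[str] | None = None,
) -> float:
    """Fraction of the true top ``top_size`` captured by the model's top N.

    The model ranks the population by predicted score and nominates its top
    ``query.budget``; recall is the size of the intersection with the
    observed top ``query.top_size``, divided by ``top_size``.  Ties are
    broken deterministically by a stable (score desc, label asc) sort.
    A budget larger than the population is clamped with a warning.
    """
    predicted = np.asarray(predicted, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    if len(predicted) != len(observed):
        raise ValueError("predicted and observed must align")
    n_pop = len(predicted)
    if query.top_size > n_pop:
        raise ValueError("top_size exceeds population size")
    budget = query.budget
    if budget > n_pop:
        import warnings

        warnings.warn(
            f"budget {budget} exceeds population size {n_pop}; clamping",
            stacklevel=2,
        )
        budget = n_pop
    if labels is None:
        labels = [f"{i:09d}" for i in range(n_pop)]
    model_top = _top_indices(predicted, budget, labels)
    true_top = _top_indices(observed, query.top_size, labels)
    return len(model_top & true_top) / query.top_size


def recall_curve(
    predicted: Sequence[float],
    observed: Sequence[float],
    budgets: Sequence[int],
    top_size: int = 100,
    labels: Sequence[str] | None = None,
) -> pd.Series:
    """Recall at each budget; non-decreasing in the budget."""
    return pd.Series(
        {
            n: recall_at_budget(predicted, observed, RecallQuery(n, top_size), labels)
            for n in budgets
        },
        name="recall",
    ).rename_axis("budget")


@dataclass
class TrajectorySpec:
    """An ordered mutational pathway with non-decreasing mutation counts."""

    variants: list

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("empty trajectory")
        counts = [v.n_mutations for v in self.variants]
        if any(b < a for a, b in zip(counts, counts[1:])):
            raise ValueError("mutation counts must be non-decreasing")

    @property
    def sequences(self) -> list[str]:
        return [v.sequence for v in self.variants]

    @property
    def mutation_counts(self) -> list[int]:
        return [v.n_mutations for v in self.variants]


def trajectory_divergence(models: Sequence, trajectory: TrajectorySpec) -> dict:
    """Member predictions and their dispersion along a mutational pathway.

    Returns a dict with the raw ``(model, step)`` prediction matrix, the
    per-step population std and IQR, and the per-step median and lower 5th
    percentile rows (the average-case and conservative ensemble readouts).
    """
    if len(models) < 2:
        raise ValueError("need at least two models")
    seqs = trajectory.sequences
    matrix = np.vstack([m.predict(seqs) for m in models])
    return {
        "predictions": matrix,
        "mutation_counts": np.asarray(trajectory.mutation_counts),
        "std": matrix.std(axis=0),
        "iqr": np.subtract(*np.percentile(matrix, [75, 25], axis=0)),
        "median": np.median(matrix, axis=0),
        "percentile5": np.percentile(matrix, 5, axis=0, method="lower"),
    }


def ensemble_disagreement(models: Sequence, seqs: Sequence[str]) -> pd.DataFrame:
    """Per-sequence spread statistics over member predictions."""
    if len(models) < 2:
        raise ValueError("need at least two models")
    matrix = np.vstack([m.predict(seqs) for m in models])
    return pd.DataFrame(
        {
            "std": matrix.std(axis=0),
            "iqr": np.subtract(*np.percentile(matrix, [75, 25], axis=0)),
            "min": matrix.min(axis=0),
            "max": matrix.max(axis=0),
        }
    )
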