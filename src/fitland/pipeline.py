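"""End-to-end campaign plumbing: model panels and design-campaign grids.

A "campaign grid" reproduces the full design workflow: a panel of predictors
(a linear model, a fully connected network, three convolutional networks
with different initializations, a graph-convolutional network, and the two
CNN-ensemble readouts EnsM/EnsC sharing one member pool) is trained on a
local dataset, and each model designs variants at several fixed mutation
distances via simulated annealing, followed by K-means representative
selection.
"""

from __future__ import annotations

import numpy as np

from .design import AnnealConfig, DesignCampaignResult, design_campaign
from .landscape import FitnessDataset
from .models import (
    ConvFitnessRegressor,
    DenseFitnessRegressor,
    FitnessEnsemble,
    GraphConvFitnessRegressor,
    LinearFitnessRegressor,
    contact_graph,
    train,
)

#: Model tags of the standard eight-member design panel.
PANEL_TAGS = ("LR", "FCN", "CNN0", "CNN1", "CNN2", "GCN", "EnsM", "EnsC")


def synthetic_contact_coords(L: int, seed: int = 0) -> np.ndarray:
    """A compact random 3-D chain with 3.8-Angstrom steps.

    Stands in for alpha-carbon coordinates when no structure is available;
    the random-walk chain folds back on itself, giving the contact graph
    both sequential and long-range edges.
    """
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(L - 1, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    coords = np.vstack([np.zeros(3), np.cumsum(3.8 * steps, axis=0)])
    # gentle compaction toward the centroid to create long-range contacts
    return coords * 0.7


def build_model_panel(
    dataset: FitnessDataset,
    seed: int = 0,
    n_ensemble_members: int = 5,
    contact_threshold: float = 8.0,
    **train_overrides,
) -> dict[str, object]:
    """Train the eight-model design panel on a fitness dataset.

    The ensembles EnsM (median) and EnsC (5th percentile, conservative)
    share a single pool of ``n_ensemble_members`` CNNs that differ only in
    their initialization seed.  Training hyperparameters can be overridden
    via keyword arguments (``learning_rate``, ``max_epochs``, ...).
    """
    L = len(dataset.wild_type)
    kwargs = dict(learning_rate=0.01, max_epochs=15, batch_size=256, patience=15)
    kwargs.update(train_overrides)
    graph = contact_graph(synthetic_contact_coords(L, seed), contact_threshold)

    panel: dict[str, object] = {}
    lin_kwargs = dict(kwargs, learning_rate=max(kwargs["learning_rate"], 0.05))
    panel["LR"] = train(LinearFitnessRegressor(random_state=seed, **lin_kwargs), dataset)
    panel["FCN"] = train(
        DenseFitnessRegressor(hidden_layer_sizes=(64, 64), random_state=seed, **kwargs),
        dataset,
    )
    for i in range(3):
        panel[f"CNN{i}"] = train(
            ConvFitnessRegressor(random_state=seed + 10 + i, **kwargs), dataset
        )
    panel["GCN"] = train(
        GraphConvFitnessRegressor(adjacency=graph, random_state=seed, **kwargs),
        dataset,
    )
    members = [
        train(ConvFitnessRegressor(random_state=seed + 100 + i, **kwargs), dataset)
        for i in range(n_ensemble_members)
    ]
    panel["EnsM"] = FitnessEnsemble(members, aggregation="median")
    panel["EnsC"] = FitnessEnsemble(members, aggregation="percentile", percentile=5)
    return panel


def run_campaign_grid(
    models: dict[str, object],
    wild_type: str,
    distances: tuple[int, ...] = (5, 10, 20, 30, 40, 50),
    n_runs: int = 500,
    n_steps: int = 25_000,
    n_clusters: int = 41,
    base_seed: int = 0,
    chunk_size: int = 100,
) -> list[DesignCampaignResult]:
    """Design campaigns for every model/distance combination.

    Each combination gets its own seed stream (derived from ``base_seed``
    and the combination index) so campaigns are independent and the whole
    grid is reproducible.
    """
    campaigns = []
    for m_idx, (tag, model) in enumerate(models.items()):
        for d_idx, k in enumerate(distances):
            combo_seed = base_seed + 10_000 * m_idx + 1_000 * d_idx
            config = AnnealConfig(k=k, n_steps=n_steps, seed=combo_seed)
            campaigns.append(
                design_campaign(
                    model, wild_type, config, model_tag=tag, n_runs=n_runs,
                    n_clusters=n_clusters, base_seed=combo_seed,
                    chunk_size=chunk_size,
                )
            )
    return campaigns
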