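"""Bipartite drug-target interaction (DTI) network model.

The network is V = (D, T, A): an ordered drug set D, an ordered target
set T, and a 0/1 adjacency A indexed [drug, target]. Operations here
cover the dataset statistics (drug/target/interaction counts and
sparsity), degree-based target filtering, and the fresh-molecule
simulation that deletes one drug's edges together with any target left
without interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError

__all__ = [
    "DTINetwork",
    "NetworkSummary",
    "summarize",
    "target_degree",
    "filter_by_degree",
    "remove_drug",
]


@dataclass(frozen=True)
class DTINetwork:
    """A bipartite 0/1 interaction network over drug and target ids."""

    drug_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    adjacency: np.ndarray  # shape (n_drugs, n_targets), entries 0/1

    def __post_init__(self) -> None:
        drugs = tuple(self.drug_ids)
        targets = tuple(self.target_ids)
        if len(set(drugs)) != len(drugs):
            raise DataError("duplicate drug ids in network")
        if len(set(targets)) != len(targets):
            raise DataError("duplicate target ids in network")
        adj = np.asarray(self.adjacency, dtype=np.uint8)
        if adj.shape != (len(drugs), len(targets)):
            raise DataError(
                f"adjacency shape {adj.shape} does not match "
                f"({len(drugs)} drugs, {len(targets)} targets)"
            )
        orig = np.asarray(self.adjacency)
        if not ((orig == 0) | (orig == 1)).all():
            raise DataError("adjacency entries must be 0 or 1")
        adj.setflags(write=False)
        object.__setattr__(self, "drug_ids", drugs)
        object.__setattr__(self, "target_ids", targets)
        object.__setattr__(self, "adjacency", adj)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def n_interactions(self) -> int:
        return int(self.adjacency.sum())

    def drug_index(self, drug_id: str) -> int:
        try:
            return self.drug_ids.index(drug_id)
        except ValueError:
            raise DataError(f"unknown drug id {drug_id!r}") from None

    def target_index(self, target_id: str) -> int:
        try:
            return self.target_ids.index(target_id)
        except ValueError:
            raise DataError(f"unknown target id {target_id!r}") from None

    def target_members(self, target_id: str) -> list[str]:
        """Drug ids interacting with a target, in input order."""
        j = self.target_index(target_id)
        return [self.drug_ids[i] for i in np.flatnonzero(self.adjacency[:, j])]

    def target_degrees(self) -> np.ndarray:
        """Degree (number of interacting drugs) of every target."""
        return self.adjacency.sum(axis=0).astype(np.int64)

    def edges(self) -> list[tuple[str, str]]:
        """All (drug_id, target_id) interaction pairs."""
        rows, cols = np.nonzero(self.adjacency)
        return [(self.drug_ids[i], self.target_ids[j]) for i, j in zip(rows, cols)]


@dataclass(frozen=True)
class NetworkSummary:
    """Dataset statistics: counts and sparsity percentage.

    ``sparsity_percent`` = 100 * (1 - interactions / (drugs * targets)),
    i.e. the fraction of the drug-target grid with no observed edge.
    """

    n_drugs: int
    n_targets: int
    n_interactions: int
    sparsity_percent: float

    @property
    def sparsity_display(self) -> float:
        """Sparsity rounded to 2 decimals, the conventional display form."""
        return round(self.sparsity_percent, 2)


def summarize(net: DTINetwork) -> NetworkSummary:
    """Count drugs, targets and interactions and compute sparsity."""
    cells = net.n_drugs * net.n_targets
    sparsity = 100.0 * (1.0 - net.n_interactions / cells) if cells else 0.0
    return NetworkSummary(
        n_drugs=net.n_drugs,
        n_targets=net.n_targets,
        n_interactions=net.n_interactions,
        sparsity_percent=sparsity,
    )


def target_degree(net: DTINetwork, target_id: str) -> int:
    """Number of drugs interacting with ``target_id`` (the x in S1/S2)."""
    return int(net.adjacency[:, net.target_index(target_id)].sum())


def filter_by_degree(net: DTINetwork, theta: int) -> DTINetwork:
    """Keep only targets with degree >= theta; drugs are untouched.

    theta must be >= 2: a target with a single member drug has no member
    pairs, so its local-network mean similarity S1 is undefined and it
    can never be scored.
    """
    if theta < 2:
        raise DataError(
            f"theta must be >= 2 (got {theta}): S1 averages over x(x-1)/2 "
            "member pairs, which is empty for single-member targets"
        )
    keep = np.flatnonzero(net.target_degrees() >= theta)
    return DTINetwork(
        drug_ids=net.drug_ids,
        target_ids=tuple(net.target_ids[j] for j in keep),
        adjacency=net.adjacency[:, keep].copy(),
    )


def remove_drug(net: DTINetwork, drug_id: str) -> tuple[DTINetwork, int, int]:
    """Delete a drug, its edges, and any target thereby orphaned.

    Simulates a "fresh" molecule: the drug's interactions are erased
    from the network, and targets that interacted only with this drug
    (degree 0 afterwards) are dropped as well.

    Returns ``(new_network, removed_interactions, removed_targets)``.
    """
    i = net.drug_index(drug_id)
    removed_edges = int(net.adjacency[i].sum())
    rest = np.delete(net.adjacency, i, axis=0)
    orphaned = np.flatnonzero((rest.sum(axis=0) == 0) & (net.adjacency[i] == 1))
    keep = np.setdiff1d(np.arange(net.n_targets), orphaned)
    new = DTINetwork(
        drug_ids=tuple(d for d in net.drug_ids if d != drug_id),
        target_ids=tuple(net.target_ids[j] for j in keep),
        adjacency=rest[:, keep].copy(),
    )
    return new, removed_edges, int(orphaned.size)
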