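"""Synthetic DTI networks with chemical cluster structure.

The generator encodes the working assumption behind ligand-based
target fishing: drugs binding the same target look alike. Each target
gets a random seed fingerprint; each member drug is a bit-flip-noised
copy of that seed, so within-target Tanimoto similarity is high and
tunable via ``flip_rate``. Decoy drugs are drawn independently and
carry no edges. Everything is deterministic given the seed, and the
generating truth (edge set, per-drug degrees) is returned alongside the
network so tests can assert against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import FP_LENGTH, Fingerprint
from .errors import DataError
from .network import DTINetwork, remove_drug

__all__ = [
    "SyntheticSpec",
    "generate",
    "holdout_scenario",
    "network_with_counts",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generated network.

    members_per_target may be an int or an inclusive (low, high) range;
    bit_density is the expected fraction of set bits in a seed
    fingerprint; flip_rate the per-bit noise applied to each member
    copy; overlap_rate the probability that a member drug also joins
    one extra random target (creating cross-cluster edges).
    """

    n_targets: int = 8
    members_per_target: int | tuple[int, int] = 10
    n_decoy_drugs: int = 0
    bit_density: float = 0.2
    flip_rate: float = 0.02
    overlap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_rate < 0.5:
            raise DataError(f"flip_rate must be in [0, 0.5), got {self.flip_rate}")
        if not 0.0 < self.bit_density < 1.0:
            raise DataError(f"bit_density must be in (0, 1), got {self.bit_density}")
        if not 0.0 <= self.overlap_rate <= 1.0:
            raise DataError(f"overlap_rate must be in [0, 1], got {self.overlap_rate}")
        if self.n_targets < 1 or self.n_decoy_drugs < 0:
            raise DataError("n_targets must be >= 1 and n_decoy_drugs >= 0")
        m = self.members_per_target
        if isinstance(m, int):
            if m < 2:
                raise DataError("members_per_target must be >= 2")
        else:
            lo, hi = m
            if lo < 2 or hi < lo:
                raise DataError(f"invalid members_per_target range {m}")


def _draw_bits(rng: np.random.Generator, density: float) -> np.ndarray:
    bits = (rng.random(FP_LENGTH) < density).astype(np.uint8)
    bits[0] = 0  # placeholder position stays clear
    return bits


def _flip(rng: np.random.Generator, bits: np.ndarray, rate: float) -> np.ndarray:
    flips = rng.random(FP_LENGTH) < rate
    out = np.where(flips, 1 - bits, bits).astype(np.uint8)
    out[0] = 0
    return out


def generate(
    spec: SyntheticSpec,
) -> tuple[DTINetwork, dict[str, Fingerprint], set[tuple[str, str]]]:
    """Build (network, fingerprints, truth edge set) from a spec.

    Targets are ``T0..``; member drugs ``T<j>_D<i>``; decoys ``X<i>``.
    Member fingerprints are noised copies of their target's seed; with
    probability ``overlap_rate`` a member additionally joins one other
    random target.
    """
    rng = np.random.default_rng(spec.seed)
    target_ids = [f"T{j}" for j in range(spec.n_targets)]
    seeds = {t: _draw_bits(rng, spec.bit_density) for t in target_ids}
    drug_ids: list[str] = []
    fingerprints: dict[str, Fingerprint] = {}
    edges: set[tuple[str, str]] = set()
    for j, t in enumerate(target_ids):
        m = spec.members_per_target
        x = m if isinstance(m, int) else int(rng.integers(m[0], m[1] + 1))
        for i in range(x):
            d = f"T{j}_D{i}"
            drug_ids.append(d)
            fingerprints[d] = Fingerprint(
                bits=_flip(rng, seeds[t], spec.flip_rate), molecule_id=d
            )
            edges.add((d, t))
            if spec.overlap_rate > 0 and rng.random() < spec.overlap_rate:
                other = target_ids[int(rng.integers(spec.n_targets))]
                if other != t:
                    edges.add((d, other))
    for i in range(spec.n_decoy_drugs):
        d = f"X{i}"
        drug_ids.append(d)
        fingerprints[d] = Fingerprint(
            bits=_draw_bits(rng, spec.bit_density), molecule_id=d
        )
    adjacency = np.zeros((len(drug_ids), len(target_ids)), dtype=np.uint8)
    d_index = {d: i for i, d in enumerate(drug_ids)}
    t_index = {t: j for j, t in enumerate(target_ids)}
    for d, t in edges:
        adjacency[d_index[d], t_index[t]] = 1
    net = DTINetwork(
        drug_ids=tuple(drug_ids), target_ids=tuple(target_ids), adjacency=adjacency
    )
    return net, fingerprints, edges


def holdout_scenario(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[DTINetwork, dict[str, Fingerprint], Fingerprint, list[str]]:
    """End-to-end cold-start fixture: a network minus one member drug.

    Generates a network, picks one member drug (seeded), removes it and
    its edges (plus any orphaned target), and returns
    ``(train_net, fingerprints, query_fingerprint, true_target_ids)``
    where the true targets are those the removed drug interacted with
    that are still present in the training network.
    """
    if seed is not None:
        spec = SyntheticSpec(**{**spec.__dict__, "seed": seed})
    net, fingerprints, edges = generate(spec)
    rng = np.random.default_rng(spec.seed + 1)
    members = [d for d in net.drug_ids if not d.startswith("X")]
    query_drug = members[int(rng.integers(len(members)))]
    true_targets = [t for d, t in edges if d == query_drug]
    train_net, _, _ = remove_drug(net, query_drug)
    remaining = [t for t in true_targets if t in train_net.target_ids]
    return train_net, fingerprints, fingerprints[query_drug], remaining


def _sample_without_replacement(
    rng: np.random.Generator, n: int, size: int
) -> np.ndarray:
    """Distinct uniform draws from range(n) without a full permutation.

    For sparse draws (size << n) rejection sampling beats the permutation
    that Generator.choice(replace=False) builds; falls back to choice
    when the draw is dense.
    """
    if size > n:
        raise DataError(f"cannot draw {size} distinct values from {n}")
    if size * 4 > n:
        return rng.choice(n, size=size, replace=False)
    picked = np.unique(rng.integers(0, n, size=int(size * 1.1) + 16))
    while picked.size < size:
        extra = rng.integers(0, n, size=size)
        picked = np.unique(np.concatenate([picked, extra]))
    idx = rng.choice(picked.size, size=size, replace=False)
    return picked[idx]


def network_with_counts(
    n_drugs: int,
    n_targets: int,
    n_interactions: int,
    query_degree: int = 0,
    exclusive_targets: int = 0,
    seed: int = 0,
    query_id: str = "QUERY",
) -> tuple[DTINetwork, str]:
    """Random network with exact global counts and one designated drug.

    Builds a 0/1 network with exactly ``n_interactions`` edges over
    ``n_drugs`` x ``n_targets`` in which ``query_id`` has exactly
    ``query_degree`` edges, ``exclusive_targets`` of them to targets no
    other drug touches. Useful for reconstructing published dataset
    shapes (counts and sparsity depend only on these totals, not on
    where the edges sit). Fingerprints are not generated.
    """
    if exclusive_targets > query_degree:
        raise DataError("exclusive_targets cannot exceed query_degree")
    if query_degree > n_targets:
        raise DataError("query_degree cannot exceed n_targets")
    rest = n_interactions - query_degree
    capacity = (n_drugs - 1) * (n_targets - exclusive_targets)
    if rest < 0 or rest > capacity:
        raise DataError("interaction count infeasible for the given shape")
    rng = np.random.default_rng(seed)
    adjacency = np.zeros((n_drugs, n_targets), dtype=np.uint8)
    # row 0 is the designated drug; columns [0, exclusive_targets) are its
    # exclusive targets, the rest of its edges go to shared columns
    adjacency[0, :exclusive_targets] = 1
    shared = rng.choice(
        n_targets - exclusive_targets,
        size=query_degree - exclusive_targets,
        replace=False,
    )
    adjacency[0, exclusive_targets + shared] = 1
    flat = _sample_without_replacement(rng, capacity, rest)
    rows = flat // (n_targets - exclusive_targets) + 1
    cols = flat % (n_targets - exclusive_targets) + exclusive_targets
    adjacency[rows, cols] = 1
    drug_ids = tuple([query_id] + [f"D{i}" for i in range(1, n_drugs)])
    target_ids = tuple(f"T{j}" for j in range(n_targets))
    net = DTINetwork(drug_ids=drug_ids, target_ids=target_ids, adjacency=adjacency)
    assert net.n_interactions == n_interactions
    return net, query_id
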