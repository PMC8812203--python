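"""Readers, writers and run configuration.

Two adjacency dialects are supported. "goldstandard" is the layout of
the classic DTI benchmark matrices: a whitespace/tab-separated table
whose header row lists drug ids, whose row labels are target ids, and
whose cells are 0/1 (rows = targets, columns = drugs; pass
``transpose=True`` for the opposite convention). "generic" is a
two-column TSV edge list ``drug_id<TAB>target_id``; duplicate edges
collapse to a single interaction.

All readers validate and reject malformed input with the offending
location rather than silently repairing it; every writer produces files
its paired reader accepts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .chem import FP_LENGTH, Fingerprint
from .errors import DataError, ParseError
from .network import DTINetwork
from .scoring import ScreeningResult

__all__ = [
    "RunConfig",
    "read_adjacency",
    "write_adjacency",
    "read_fingerprints",
    "write_fingerprints",
    "read_smiles",
    "write_results",
    "write_truth_edges",
]

ADJACENCY_DIALECTS = ("goldstandard", "generic")


@dataclass
class RunConfig:
    """Run-wide settings with documented defaults.

    Loaded from YAML or JSON; unknown keys are rejected so typos fail
    loudly instead of silently falling back to defaults.
    """

    cosine_variant: str = "standard"      # "standard" | "paper_literal"
    w1_grid: list[float] = field(default_factory=lambda: [i / 100 for i in range(101)])
    theta_candidates: list[int] = field(default_factory=lambda: [2, 3, 4, 5])
    neg_ratio: float = 1.0                # negatives sampled per positive
    k_folds: int = 10
    seed: int = 0
    metric: str = "auroc"                 # threshold-selection metric
    normalize_ratio: bool = False         # min-max rescale S2/S1 before combining
    top_k: int | None = None
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        doc = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        ) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise DataError(f"unknown config keys in {path}: {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return asdict(self)


def _tokenize_matrix(path) -> list[list[str]]:
    rows = []
    for raw in Path(path).read_text().splitlines():
        if raw.strip():
            rows.append(raw.split())
    if not rows:
        raise ParseError(f"empty adjacency file {path}")
    return rows


def read_adjacency(
    path, dialect: str = "goldstandard", transpose: bool = False
) -> DTINetwork:
    """Read a DTI network from disk.

    goldstandard: labelled 0/1 matrix, rows = targets, columns = drugs
    (``transpose=True`` swaps the convention). generic: TSV edge list
    ``drug_id<TAB>target_id``, duplicates collapsed.
    """
    if dialect not in ADJACENCY_DIALECTS:
        raise DataError(f"unknown dialect {dialect!r}; choose from {ADJACENCY_DIALECTS}")
    if dialect == "generic":
        return _read_edge_list(path)
    rows = _tokenize_matrix(path)
    header = rows[0]
    body = rows[1:]
    if not body:
        raise ParseError(f"adjacency file {path} has a header but no data rows")
    n_cols = len(header)
    row_ids: list[str] = []
    cells = np.zeros((len(body), n_cols), dtype=np.uint8)
    for r, row in enumerate(body):
        if len(row) != n_cols + 1:
            raise ParseError(
                f"{path}: row {r + 2} has {len(row) - 1} cells, expected {n_cols}"
            )
        row_ids.append(row[0])
        for c, cell in enumerate(row[1:]):
            if cell not in ("0", "1"):
                raise ParseError(
                    f"{path}: non-0/1 cell {cell!r} at row {r + 2}, column {c + 2}"
                )
            cells[r, c] = int(cell)
    if transpose:
        drug_ids, target_ids, adj = row_ids, header, cells
    else:
        drug_ids, target_ids, adj = header, row_ids, cells.T
    return DTINetwork(
        drug_ids=tuple(drug_ids), target_ids=tuple(target_ids), adjacency=adj.copy()
    )


def _read_edge_list(path) -> DTINetwork:
    drugs: list[str] = []
    targets: list[str] = []
    edges: set[tuple[str, str]] = set()
    lines = Path(path).read_text().splitlines()
    if not any(line.strip() for line in lines):
        raise ParseError(f"empty adjacency file {path}")
    for ln, raw in enumerate(lines, start=1):
        if not raw.strip():
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ParseError(
                f"{path}: line {ln}: expected 'drug_id<TAB>target_id', got {raw!r}"
            )
        d, t = parts
        if d not in drugs:
            drugs.append(d)
        if t not in targets:
            targets.append(t)
        edges.add((d, t))
    adjacency = np.zeros((len(drugs), len(targets)), dtype=np.uint8)
    di = {d: i for i, d in enumerate(drugs)}
    ti = {t: j for j, t in enumerate(targets)}
    for d, t in edges:
        adjacency[di[d], ti[t]] = 1
    return DTINetwork(
        drug_ids=tuple(drugs), target_ids=tuple(targets), adjacency=adjacency
    )


def write_adjacency(net: DTINetwork, path, dialect: str = "goldstandard") -> None:
    """Write a network in either dialect accepted by :func:`read_adjacency`."""
    if dialect not in ADJACENCY_DIALECTS:
        raise DataError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if dialect == "generic":
        lines = [f"{d}\t{t}" for d, t in net.edges()]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        return
    out = ["\t".join(net.drug_ids)]
    for j, t in enumerate(net.target_ids):
        out.append(t + "\t" + "\t".join(str(int(v)) for v in net.adjacency[:, j]))
    path.write_text("\n".join(out) + "\n")


def read_fingerprints(path) -> dict[str, Fingerprint]:
    """Read a TSV of ``drug_id`` followed by 167 0/1 columns."""
    out: dict[str, Fingerprint] = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        drug_id, cells = parts[0], parts[1:]
        if len(cells) != FP_LENGTH:
            raise ParseError(
                f"{path}: line {ln}: {len(cells)} fingerprint columns, "
                f"expected {FP_LENGTH}"
            )
        if any(c not in ("0", "1") for c in cells):
            raise ParseError(f"{path}: line {ln}: non-binary fingerprint cell")
        if drug_id in out:
            raise ParseError(f"{path}: line {ln}: duplicate drug id {drug_id!r}")
        bits = np.array([int(c) for c in cells], dtype=np.uint8)
        try:
            out[drug_id] = Fingerprint(bits=bits, molecule_id=drug_id)
        except DataError as exc:
            raise ParseError(f"{path}: line {ln}: {exc}") from exc
    if not out:
        raise ParseError(f"empty fingerprint file {path}")
    return out


def write_fingerprints(fingerprints: Mapping[str, Fingerprint], path) -> None:
    lines = [
        d + "\t" + "\t".join(str(int(b)) for b in fp.bits)
        for d, fp in fingerprints.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_smiles(path) -> dict[str, str]:
    """Read a two-column TSV ``drug_id<TAB>smiles``."""
    out: dict[str, str] = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ParseError(
                f"{path}: line {ln}: expected 'drug_id<TAB>smiles', got {raw!r}"
            )
        if parts[0] in out:
            raise ParseError(f"{path}: line {ln}: duplicate drug id {parts[0]!r}")
        out[parts[0]] = parts[1]
    if not out:
        raise ParseError(f"empty SMILES file {path}")
    return out


def write_results(results: Iterable[ScreeningResult], path) -> None:
    """Write screening results as TSV with full-precision scores."""
    df = pd.DataFrame(
        [
            {
                "rank": r.rank,
                "target_id": r.target_id,
                "score": r.score,
                "s_cos": r.s_cos,
                "s1": r.s1,
                "s2": r.s2,
                "ratio": r.ratio,
            }
            for r in results
        ],
        columns=["rank", "target_id", "score", "s_cos", "s1", "s2", "ratio"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_truth_edges(edges: Iterable[tuple[str, str]], path) -> None:
    lines = [f"{d}\t{t}" for d, t in sorted(edges)]
    Path(path).write_text("\n".join(lines) + "\n")
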