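"""Ligand-receptor pair databases and gene-level adjacency construction.

A curated L-R database maps pairs of genes (or multi-subunit complexes) that
mediate intercellular signaling. Tables arrive as TSV/CSV with at least
``ligand`` and ``receptor`` columns; multiple sources are merged and
deduplicated under a canonical key, and the result induces a symmetric
gene-level adjacency matrix: genes i and j are connected iff some pair
relates them on opposite sides.

Canonicalization: symbols are uppercased and trimmed; complex subunits are
sorted within each side; the ligand->receptor direction is preserved in the
key (so an A->B pair and a B->A pair are distinct database entries, while the
induced adjacency is symmetric regardless).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .spatial_graph import Adjacency

SPECIES = ("human", "mouse")
DEFAULT_SUBUNIT_DELIMITER = "_"


class FormatError(ValueError):
    """A table is missing required structure (e.g. a mandatory column)."""


def _split_side(symbol: str, delimiter: str) -> tuple[str, ...]:
    parts = tuple(p.strip() for p in str(symbol).split(delimiter))
    if any(not p for p in parts):
        raise ValueError(f"empty subunit symbol in {symbol!r}")
    return parts


@dataclass(frozen=True)
class LRPair:
    """One ligand-receptor interaction; either side may be a complex."""

    ligand: tuple[str, ...]
    receptor: tuple[str, ...]
    species: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.ligand or not self.receptor:
            raise ValueError("ligand and receptor must be non-empty")
        if any(not s for s in self.ligand) or any(not s for s in self.receptor):
            raise ValueError("subunit symbols must be non-empty")
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}, got {self.species!r}")

    @property
    def key(self) -> tuple:
        """Canonical dedup key: (species, sorted upper ligand side, sorted
        upper receptor side). Direction L->R is preserved."""
        lig = tuple(sorted(s.strip().upper() for s in self.ligand))
        rec = tuple(sorted(s.strip().upper() for s in self.receptor))
        return (self.species, lig, rec)

    @property
    def genes(self) -> set[str]:
        return {s.strip().upper() for s in self.ligand + self.receptor}


@dataclass
class LRDatabase:
    """Ordered, duplicate-free collection of LRPair records."""

    pairs: list[LRPair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __eq__(self, other) -> bool:
        return isinstance(other, LRDatabase) and [p.key for p in self.pairs] == [
            p.key for p in other.pairs
        ]

    @property
    def species_counts(self) -> dict[str, int]:
        return dict(Counter(p.species for p in self.pairs))

    def to_frame(self, delimiter: str = DEFAULT_SUBUNIT_DELIMITER) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ligand": [delimiter.join(p.ligand) for p in self.pairs],
                "receptor": [delimiter.join(p.receptor) for p in self.pairs],
                "species": [p.species for p in self.pairs],
                "source": [p.source for p in self.pairs],
            }
        )


def load_lr_table(
    path,
    species: str | None = None,
    delimiter: str = DEFAULT_SUBUNIT_DELIMITER,
    sep: str = "\t",
) -> LRDatabase:
    """Read an L-R pair table (one pair per row) into an LRDatabase.

    The file must contain ``ligand`` and ``receptor`` columns; ``species``
    and ``source`` columns are optional, with the species falling back to the
    ``species`` argument. Complex sides are split on ``delimiter``. The rows
    are kept in file order and NOT deduplicated here (see merge_and_dedup).
    """
    df = pd.read_csv(path, sep=sep)
    for col in ("ligand", "receptor"):
        if col not in df.columns:
            raise FormatError(f"L-R table {path} is missing required column {col!r}")
    pairs = []
    for row in df.itertuples(index=False):
        sp = getattr(row, "species", None) or species
        if sp is None:
            raise ValueError("no species column in table and no species argument given")
        sp = str(sp).strip().lower()
        if sp not in SPECIES:
            raise ValueError(f"unknown species {sp!r}; expected one of {SPECIES}")
        pairs.append(
            LRPair(
                ligand=_split_side(row.ligand, delimiter),
                receptor=_split_side(row.receptor, delimiter),
                species=sp,
                source=str(getattr(row, "source", "") or ""),
            )
        )
    return LRDatabase(pairs)


def merge_and_dedup(dbs: Sequence[LRDatabase]) -> LRDatabase:
    """Union of databases with canonical-key duplicates collapsed; first
    occurrence wins, ordering stable."""
    if not dbs:
        raise ValueError("at least one database required")
    seen: dict[tuple, LRPair] = {}
    for db in dbs:
        for p in db:
            seen.setdefault(p.key, p)
    return LRDatabase(list(seen.values()))


def build_gene_adjacency(gene_ids: Sequence[str], db: LRDatabase) -> Adjacency:
    """Symmetric 0/1 gene adjacency over ``gene_ids``.

    A[i, j] = 1 iff some pair in ``db`` puts gene i and gene j on opposite
    sides (either direction); complexes contribute an edge between every
    ligand-side subunit and every receptor-side subunit. Diagonal is zero.
    """
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValueError("gene_ids must be non-empty")
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("gene_ids must be unique")
    index = {g.strip().upper(): i for i, g in enumerate(gene_ids)}
    n = len(gene_ids)
    A = np.zeros((n, n))
    for p in db:
        for lg in p.ligand:
            i = index.get(lg.strip().upper())
            if i is None:
                continue
            for rc in p.receptor:
                j = index.get(rc.strip().upper())
                if j is None or i == j:
                    continue
                A[i, j] = A[j, i] = 1
    return Adjacency(A, node_ids=gene_ids)
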