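"""Seeded synthetic data: tissues, multi-slice stacks, and L-R databases.

Everything the pipeline consumes can be generated here offline:

* :func:`generate_tissue` — a 2D tissue of spatially clustered cell
  communities whose expression carries the community signal, so the spatial
  graph is statistically recoverable from the features (the property the
  autoencoder exploits). Emulates seqFISH/MERFISH-style input; it does NOT
  model counts, dropout curves or platform artifacts.
* :func:`generate_multislice` — consecutive sections of one tissue under
  planted cumulative rigid transforms with jitter and dropout, emulating
  serial Visium sections for alignment benchmarks.
* :func:`generate_toy_lr_db` — a random ligand-receptor database over given
  genes, a configurable fraction encoded as 2-subunit complexes.
* :func:`generate_reference_lr_tables` — synthetic stand-ins for the curated
  human/mouse reference L-R tables: the planted number of unique canonical
  pairs matches the published database sizes (5786 human, 4806 mouse), and
  redundant variant rows (duplicates, case/whitespace, subunit order) are
  interleaved so that loading + dedup must actually do its job.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import RigidTransform
from .lr_database import LRDatabase, LRPair
from .preprocess import ExpressionMatrix
from .spatial_graph import (
    Adjacency,
    SpatialCoords,
    euclidean_distance_matrix,
    knn_adjacency,
)

REFERENCE_PAIR_COUNTS = {"human": 5786, "mouse": 4806}


@dataclass
class TissueFixture:
    """A synthetic tissue: coordinates, expression, ground-truth graph."""

    coords: SpatialCoords
    expression: ExpressionMatrix
    true_adjacency: Adjacency
    communities: np.ndarray
    generator_config: dict

    def __post_init__(self) -> None:
        rebuilt = knn_adjacency(
            euclidean_distance_matrix(self.coords),
            self.generator_config["n_neighbors"],
        )
        if not np.array_equal(rebuilt.matrix, self.true_adjacency.matrix):
            raise AssertionError("true_adjacency inconsistent with coordinates")


def generate_tissue(
    n_cells: int = 200,
    n_genes: int = 50,
    n_communities: int = 4,
    n_neighbors: int = 6,
    signal_strength: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> TissueFixture:
    """Spatially separated community blobs with community-driven expression.

    Cells are assigned (round-robin) to ``n_communities`` equally sized
    communities whose centers sit at evenly spaced angles but strongly
    unequal radii (8 to 15.5 for the default four); coordinates are center +
    isotropic Gaussian scatter (sd 2). The radius spread gives the blob
    constellation a unique best rigid registration — equal radii would make
    the layout rotationally near-symmetric and slice alignment ill-posed,
    which real tissue is not. Expression is a community-specific factor
    loading (drawn once per community, scaled by ``signal_strength``) plus
    N(0, noise_sd^2) per-cell noise. The ground-truth adjacency is the
    symmetrized kNN graph of the coordinates.
    """
    if not n_cells >= n_communities >= 1:
        raise ValueError("need n_cells >= n_communities >= 1")
    if n_neighbors >= n_cells:
        raise ValueError("n_neighbors must be < n_cells")
    rng = np.random.default_rng(seed)
    idx = np.arange(n_communities)
    angles = 2 * np.pi * idx / max(n_communities, 1)
    radii = 8.0 + 7.5 * idx / max(n_communities - 1, 1)
    centers = radii[:, None] * np.column_stack([np.cos(angles), np.sin(angles)])
    communities = np.arange(n_cells) % n_communities
    coords_arr = centers[communities] + rng.normal(0, 2.0, size=(n_cells, 2))
    coords = SpatialCoords(coords_arr, [f"cell{i}" for i in range(n_cells)])

    loadings = rng.normal(0, 1.0, size=(n_communities, n_genes)) * signal_strength
    values = loadings[communities] + rng.normal(0, noise_sd, size=(n_cells, n_genes))
    expression = ExpressionMatrix(
        values, coords.cell_ids, [f"gene{j}" for j in range(n_genes)]
    )
    adjacency = knn_adjacency(euclidean_distance_matrix(coords), n_neighbors)
    adjacency.node_ids = list(coords.cell_ids)
    config = dict(
        n_cells=n_cells, n_genes=n_genes, n_communities=n_communities,
        n_neighbors=n_neighbors, signal_strength=signal_strength,
        noise_sd=noise_sd, seed=seed,
    )
    return TissueFixture(coords, expression, adjacency, communities, config)


@dataclass
class MultiSliceFixture:
    """Serial sections of one tissue with planted rigid transforms.

    ``transforms[s]`` maps base coordinates into slice s's frame (slice 0 is
    the identity); ``kept[s]`` lists the base indices surviving dropout in
    slice s; counterpart pairs between slices s and r are the intersection
    of ``kept[s]`` and ``kept[r]``.
    """

    slices: list[SpatialCoords]
    expressions: list[ExpressionMatrix]
    transforms: list[RigidTransform]
    kept: list[np.ndarray]
    generator_config: dict

    def counterparts(self, s: int, r: int) -> tuple[np.ndarray, np.ndarray]:
        """Positional indices into slices s and r of the shared base cells."""
        common = np.intersect1d(self.kept[s], self.kept[r])
        pos_s = {b: i for i, b in enumerate(self.kept[s])}
        pos_r = {b: i for i, b in enumerate(self.kept[r])}
        return (np.array([pos_s[b] for b in common], int),
                np.array([pos_r[b] for b in common], int))


def _rot2d(deg: float) -> np.ndarray:
    a = np.radians(deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


def generate_multislice(
    base: TissueFixture,
    n_slices: int = 3,
    rotation_deg: float = 15.0,
    translation: tuple[float, float] = (3.0, -2.0),
    jitter_sd: float = 0.01,
    dropout_frac: float = 0.05,
    seed: int = 0,
) -> MultiSliceFixture:
    """Sections under cumulative planted rigid motion + jitter + dropout.

    Slice s applies rotation s*rotation_deg and translation s*translation to
    the base coordinates, adds N(0, jitter_sd^2) positional jitter, and drops
    a seeded ``dropout_frac`` fraction of cells. Expression rows follow the
    surviving cells unchanged.
    """
    if n_slices < 2:
        raise ValueError("need at least 2 slices")
    if not 0 <= dropout_frac < 1:
        raise ValueError("dropout_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = base.coords.n_cells
    slices, exprs, transforms, kept = [], [], [], []
    for s in range(n_slices):
        tr = RigidTransform(R=_rot2d(s * rotation_deg),
                            t=s * np.asarray(translation, float))
        pts = tr.apply(base.coords.coords)
        if jitter_sd > 0:
            pts = pts + rng.normal(0, jitter_sd, size=pts.shape)
        n_drop = int(round(dropout_frac * n))
        drop = rng.choice(n, size=n_drop, replace=False) if n_drop else np.array([], int)
        keep = np.setdiff1d(np.arange(n), drop)
        slices.append(SpatialCoords(
            pts[keep], [f"s{s}_{base.coords.cell_ids[i]}" for i in keep]
        ))
        exprs.append(ExpressionMatrix(
            base.expression.values[keep],
            slices[-1].cell_ids,
            list(base.expression.gene_ids),
        ))
        transforms.append(tr)
        kept.append(keep)
    config = dict(n_slices=n_slices, rotation_deg=rotation_deg,
                  translation=tuple(translation), jitter_sd=jitter_sd,
                  dropout_frac=dropout_frac, seed=seed,
                  base_config=dict(base.generator_config))
    return MultiSliceFixture(slices, exprs, transforms, kept, config)


def generate_toy_lr_db(
    gene_ids: list[str],
    n_pairs: int,
    complex_frac: float = 0.0,
    seed: int = 0,
) -> LRDatabase:
    """Random unique L-R pairs over ``gene_ids``; ``complex_frac`` of them
    get a second subunit on the ligand side."""
    genes = list(gene_ids)
    max_pairs = len(genes) * (len(genes) - 1)
    if n_pairs > max_pairs:
        raise ValueError(f"n_pairs={n_pairs} exceeds possible ordered pairs {max_pairs}")
    rng = np.random.default_rng(seed)
    pairs: list[LRPair] = []
    seen: set = set()
    while len(pairs) < n_pairs:
        i, j = rng.choice(len(genes), size=2, replace=False)
        lig: tuple[str, ...] = (genes[i],)
        if rng.random() < complex_frac:
            others = [k for k in range(len(genes)) if k not in (i, j)]
            if others:
                lig = (genes[i], genes[int(rng.choice(others))])
        p = LRPair(ligand=lig, receptor=(genes[j],), species="human", source="toy")
        if p.key in seen:
            continue
        seen.add(p.key)
        pairs.append(p)
    return LRDatabase(pairs)


def _reference_pairs(species: str, n_pairs: int, rng: np.random.Generator,
                     complex_frac: float = 0.1) -> list[LRPair]:
    prefix = "HS" if species == "human" else "MM"
    n_lig, n_rec = 420, 420
    ligands = [f"{prefix}LG{i:04d}" for i in range(n_lig)]
    receptors = [f"{prefix}RC{i:04d}" for i in range(n_rec)]
    combos = rng.choice(n_lig * n_rec, size=n_pairs, replace=False)
    pairs = []
    for c in combos:
        i, j = divmod(int(c), n_rec)
        lig: tuple[str, ...] = (ligands[i],)
        rec: tuple[str, ...] = (receptors[j],)
        # complexes get a deterministic partner subunit so keys stay unique
        if rng.random() < complex_frac:
            lig = (ligands[i], f"{prefix}CPX{i:04d}")
        pairs.append(LRPair(ligand=lig, receptor=rec, species=species, source="synthetic"))
    return pairs


def generate_reference_lr_tables(
    out_dir,
    seed: int = 0,
    redundancy_frac: float = 0.15,
) -> dict[str, Path]:
    """Write synthetic human/mouse reference L-R tables (TSV).

    Stand-ins for the curated reference database files: each species table
    contains exactly the published number of unique canonical pairs
    (5786 human, 4806 mouse) plus ``redundancy_frac`` redundant variant rows
    — verbatim duplicates, case/whitespace-mangled copies, and copies with
    complex subunits reordered — shuffled into the file, so that dedup is
    required to recover the planted counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}
    for species, count in REFERENCE_PAIR_COUNTS.items():
        pairs = _reference_pairs(species, count, rng)
        rows = [("_".join(p.ligand), "_".join(p.receptor), p.species, p.source)
                for p in pairs]
        n_red = int(round(redundancy_frac * count))
        for idx in rng.choice(count, size=n_red, replace=True):
            lig, rec, sp, _ = rows[idx]
            style = rng.integers(3)
            if style == 0:  # verbatim duplicate
                rows.append((lig, rec, sp, "dup"))
            elif style == 1:  # case + whitespace variant
                rows.append((f" {lig.lower()}", rec.lower() + " ", sp, "case-variant"))
            else:  # reorder complex subunits (no-op for monomers)
                rows.append(("_".join(reversed(lig.split("_"))), rec, sp, "reordered"))
        order = rng.permutation(len(rows))
        df = pd.DataFrame([rows[i] for i in order],
                          columns=["ligand", "receptor", "species", "source"])
        path = out_dir / f"synthetic_reference_lr_{species}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[species] = path
    return paths
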