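"""Tumor lesion calling from phenotyped cell centroids.

Within each sample, tumor cells are nodes of a proximity graph with an edge
whenever their Euclidean distance is at most 200 um (inclusive); connected
components of that graph are the lesions. Every non-tumor cell within
200 um of any tumor cell of a lesion is assigned to that lesion — a
non-tumor cell can belong to zero, one, or several lesions. Lesions of 1-8
tumor cells are classed dormant, larger ones proliferative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

DEFAULT_RADIUS_UM = 200.0
DORMANT_MAX_SIZE = 8


@dataclass
class Lesion:
    """A connected component of tumor cells plus its assigned immune cells."""

    lesion_id: int
    sample_id: str
    genotype: str
    tumor_cell_ids: np.ndarray
    immune_member_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    immune_member_types: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    @property
    def size(self) -> int:
        return len(self.tumor_cell_ids)

    @property
    def dormancy_class(self) -> str:
        return "dormant" if self.size <= DORMANT_MAX_SIZE else "proliferative"

    def composition(self) -> pd.Series:
        return pd.Series(self.immune_member_types).value_counts()


def build_lesions(
    cells: pd.DataFrame,
    calls: pd.DataFrame,
    tumor_type: str = "tumor",
    radius: float = DEFAULT_RADIUS_UM,
) -> list[Lesion]:
    """Partition tumor cells into lesions via the <= radius proximity graph.

    Distances are 2D Euclidean on centroids, within each sample only; the
    boundary is inclusive (a pair exactly ``radius`` apart is connected).
    The KD-tree neighbor query is exact, so components equal the all-pairs
    definition. Lesions are numbered in order of their smallest tumor cell
    id, so output is independent of row order.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    merged = cells.merge(calls[["cell_id", "assigned_type"]], on="cell_id")
    lesions: list[Lesion] = []
    next_id = 0
    for sample, grp in merged.groupby("sample_id", sort=True):
        tumor = grp[grp["assigned_type"] == tumor_type]
        if tumor.empty:
            logger.info("sample %s has no tumor cells; zero lesions", sample)
            continue
        genotype = grp["genotype"].iloc[0] if "genotype" in grp else "unknown"
        ids = tumor["cell_id"].to_numpy()
        order = np.argsort(ids)           # determinism w.r.t. row order
        ids = ids[order]
        xy = tumor[["x_um", "y_um"]].to_numpy()[order]
        tree = cKDTree(xy)
        pairs = tree.query_pairs(radius, output_type="ndarray")  # inclusive
        n = len(ids)
        if len(pairs):
            adj = coo_matrix(
                (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
            )
        else:
            adj = coo_matrix((n, n))
        _, comp = connected_components(adj, directed=False)
        # relabel components by smallest member cell id (ids already sorted)
        seen: dict[int, int] = {}
        for c in comp:
            if c not in seen:
                seen[c] = next_id
                next_id += 1
        for c, local in sorted(seen.items(), key=lambda kv: kv[1]):
            lesions.append(Lesion(
                lesion_id=local,
                sample_id=sample,
                genotype=genotype,
                tumor_cell_ids=ids[comp == c],
            ))
    return lesions


def assign_immune(
    cells: pd.DataFrame,
    calls: pd.DataFrame,
    lesions: list[Lesion],
    tumor_type: str = "tumor",
    radius: float = DEFAULT_RADIUS_UM,
) -> list[Lesion]:
    """Attach every phenotyped non-tumor cell within ``radius`` of a lesion.

    Membership multiplicity is preserved: a cell within ``radius`` of tumor
    cells from k lesions is counted once in each of those k lesions.
    Excluded cells (no assigned type) are never members.
    """
    merged = cells.merge(calls[["cell_id", "assigned_type"]], on="cell_id")
    by_sample = dict(tuple(merged.groupby("sample_id")))
    for lesion in lesions:
        grp = by_sample[lesion.sample_id]
        immune = grp[grp["assigned_type"].notna()
                     & (grp["assigned_type"] != tumor_type)]
        if immune.empty:
            continue
        tumor_xy = grp.set_index("cell_id").loc[
            lesion.tumor_cell_ids, ["x_um", "y_um"]
        ].to_numpy()
        tree = cKDTree(tumor_xy)
        d, _ = tree.query(immune[["x_um", "y_um"]].to_numpy(), k=1)
        inside = d <= radius
        order = np.argsort(immune["cell_id"].to_numpy()[inside])
        lesion.immune_member_ids = immune["cell_id"].to_numpy()[inside][order]
        lesion.immune_member_types = immune["assigned_type"].to_numpy()[inside][order]
    return lesions


def lesion_table(lesions: list[Lesion], immune_types=None) -> pd.DataFrame:
    """One row per lesion with size, dormancy class and member counts."""
    if immune_types is None:
        immune_types = sorted({t for l in lesions for t in l.immune_member_types})
    rows = []
    for l in lesions:
        comp = l.composition()
        rows.append({
            "lesion_id": l.lesion_id,
            "sample_id": l.sample_id,
            "genotype": l.genotype,
            "size": l.size,
            "dormancy_class": l.dormancy_class,
            **{f"n_{t}": int(comp.get(t, 0)) for t in immune_types},
        })
    return pd.DataFrame(rows)


def membership_edges(lesions: list[Lesion]) -> pd.DataFrame:
    """Cell-to-lesion edge list (tumor and immune members)."""
    rows = []
    for l in lesions:
        for cid in l.tumor_cell_ids:
            rows.append((int(cid), l.lesion_id, "tumor"))
        for cid, t in zip(l.immune_member_ids, l.immune_member_types):
            rows.append((int(cid), l.lesion_id, t))
    return pd.DataFrame(rows, columns=["cell_id", "lesion_id", "member_type"])


def classify_and_summarize(lesions: list[Lesion]) -> dict[str, pd.DataFrame]:
    """Per-sample and per-genotype lesion summaries.

    Per sample: lesion count, percent dormant (NaN when a sample has no
    lesions), mean/median size. Per genotype: pooled lesion count, mean
    size pooled over lesions, and the mean of per-sample mean sizes.
    """
    df = lesion_table(lesions)
    if df.empty:
        return {"per_sample": pd.DataFrame(), "per_genotype": pd.DataFrame()}
    per_sample = (
        df.groupby(["sample_id", "genotype"])
        .agg(
            n_lesions=("lesion_id", "size"),
            pct_dormant=("dormancy_class", lambda s: 100.0 * (s == "dormant").mean()),
            mean_size=("size", "mean"),
            median_size=("size", "median"),
        )
        .reset_index()
    )
    per_genotype = (
        df.groupby("genotype")
        .agg(n_lesions=("lesion_id", "size"),
             mean_size=("size", "mean"),
             pct_dormant=("dormancy_class", lambda s: 100.0 * (s == "dormant").mean()))
        .reset_index()
    )
    sample_means = per_sample.groupby("genotype")["mean_size"].mean()
    per_genotype["mean_of_sample_means"] = per_genotype["genotype"].map(sample_means)
    return {"per_sample": per_sample, "per_genotype": per_genotype}
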