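"""Cell phenotyping from per-cell marker intensities.

Three-stage classifier for multiplex immunofluorescence cell tables:

1. Per-marker "elbow" thresholds binarize each marker into +/-, and each
   cell's binary profile is matched against a panel of expected profiles
   for known cell types. Uniquely matching cells are assigned, and their
   mean MFI vectors become representative quantitative profiles per type.
2. Cells left unmatched (no profile, or ambiguous) are modeled as mixtures
   of the representative profiles by per-cell multivariate linear
   regression; the significant positive contributor with the largest
   coefficient wins. Cells with no significant contributor are excluded.
3. Excluded cells are k-means clustered as a report-only triage for
   unexpected cell types; clusters dominated by a single marker flag
   leftover imaging noise. Excluded cells stay excluded.

Finally, types on the panel's exclusion list (e.g. gamma-delta T cells
compromised by channel spillover) are dropped from downstream analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

MFI_PREFIX = "mfi_"

STAGE_PROFILE = "profile_match"
STAGE_REGRESSION = "regression"
STAGE_EXCL_UNMATCHED = "excluded_unmatched"
STAGE_EXCL_LISTED = "excluded_listed"


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

@dataclass
class PhenotypePanel:
    """Known cell types with expected +/-/any marker profiles."""

    profiles: dict[str, dict[str, str]]
    tumor_type_name: str
    exclusion_list: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.tumor_type_name not in self.profiles:
            raise ValueError(f"tumor type {self.tumor_type_name!r} not in panel")
        seen = {}
        for name, prof in self.profiles.items():
            key = tuple(sorted((m, s) for m, s in prof.items() if s != "any"))
            if key in seen:
                raise ValueError(f"profiles for {seen[key]!r} and {name!r} coincide")
            seen[key] = name
            for m, s in prof.items():
                if s not in ("+", "-", "any"):
                    raise ValueError(f"bad profile symbol {s!r} for {name}/{m}")

    @property
    def markers(self) -> list[str]:
        out: list[str] = []
        for prof in self.profiles.values():
            for m in prof:
                if m not in out:
                    out.append(m)
        return out

    def immune_types(self) -> list[str]:
        return [t for t in self.profiles if t != self.tumor_type_name]

    def to_dict(self) -> dict:
        return {
            "cell_types": self.profiles,
            "tumor_type_name": self.tumor_type_name,
            "exclusion_list": list(self.exclusion_list),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhenotypePanel":
        return cls(
            profiles={t: dict(p) for t, p in d["cell_types"].items()},
            tumor_type_name=d["tumor_type_name"],
            exclusion_list=list(d.get("exclusion_list", [])),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhenotypePanel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_panel() -> PhenotypePanel:
    """Mouse lung metastasis panel: GFP+ tumor cells plus ten immune types.

    Thirteen markers; every profile is fully specified so a clean cell
    matches exactly one type at stage 1. Gamma-delta T cells are excluded
    downstream (CD11b spillover into the gdTCR channel).
    """
    markers = ["gfp", "cd45", "cd3", "cd4", "cd8", "nk11", "cd11b", "cd11c",
               "cd103", "siglecf", "f480", "ly6g", "gdtcr"]

    def prof(pos: Sequence[str]) -> dict[str, str]:
        return {m: ("+" if m in pos else "-") for m in markers}

    profiles = {
        "tumor": prof(["gfp"]),
        "cd4_t": prof(["cd45", "cd3", "cd4"]),
        "cd8_t": prof(["cd45", "cd3", "cd8"]),
        "gd_t": prof(["cd45", "cd3", "gdtcr"]),
        "nk": prof(["cd45", "nk11"]),
        "nkt": prof(["cd45", "cd3", "nk11"]),
        "cd103_cdc": prof(["cd45", "cd11c", "cd103"]),
        "cdc2": prof(["cd45", "cd11c", "cd11b"]),
        "alveolar_macrophage": prof(["cd45", "cd11c", "siglecf", "f480"]),
        "macrophage": prof(["cd45", "cd11b", "f480"]),
        "mono_neutrophil": prof(["cd45", "cd11b", "ly6g"]),
    }
    return PhenotypePanel(
        profiles=profiles, tumor_type_name="tumor", exclusion_list=["gd_t"],
    )


# ---------------------------------------------------------------------------
# stage 1: elbow thresholds and profile matching
# ---------------------------------------------------------------------------

def elbow_threshold(values: np.ndarray) -> float:
    """Threshold at the elbow of the sorted expression curve.

    Values are sorted ascending and the elbow is the point of maximum
    perpendicular distance from the chord joining (first, min) to
    (last, max) — the kneedle construction. The chord is drawn on the log
    scale because fluorescence intensities are right-skewed: on the raw
    scale the log-normal upper tail, not the negative/positive boundary,
    would be the farthest point from the chord whenever positives are
    common. The construction is exactly scale-equivariant: multiplying all
    values by c multiplies the threshold by c.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 50:
        raise ValueError(f"need >= 50 values for an elbow threshold, got {n}")
    if v[0] == v[-1]:
        warnings.warn("constant marker values; all cells will be negative")
        return float(v[0])
    # floor at half the smallest positive value so zeros stay finite while
    # preserving scale equivariance (the floor scales with the data)
    floor = v[v > 0].min() / 2.0 if (v > 0).any() else 1.0
    z = np.log(np.maximum(v, floor))
    idx = np.arange(n, dtype=float)
    # |numerator| of the point-to-chord distance; the denominator is the
    # same for every point, so the argmax is unaffected by dropping it
    dist = np.abs((z[-1] - z[0]) * idx - (n - 1) * (z - z[0]))
    i_star = int(np.argmax(dist))
    # the chord elbow sits on the shoulder of a component, a few percent
    # into it; re-center the threshold in the negative/positive valley by
    # taking the widest log-spacing within a window around the elbow
    w = max(1, n // 10)
    lo, hi = max(0, i_star - w), min(n - 1, i_star + w)
    seg = z[lo:hi + 1]
    gaps = np.diff(seg)
    if gaps.size == 0 or gaps.max() == 0:
        return float(v[i_star])
    j = int(np.argmax(gaps))
    return float(np.exp(0.5 * (seg[j] + seg[j + 1])))


def compute_thresholds(
    cells: pd.DataFrame,
    markers: Sequence[str],
    overrides: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Per-marker elbow thresholds over all cells, with manual overrides."""
    overrides = overrides or {}
    out = {}
    for m in markers:
        if m in overrides:
            out[m] = float(overrides[m])
        else:
            out[m] = elbow_threshold(cells[MFI_PREFIX + m].to_numpy())
    return out


def binarize(cells: pd.DataFrame, thresholds: Mapping[str, float]) -> pd.DataFrame:
    """Binary +/- calls per marker: positive iff MFI strictly above threshold."""
    return pd.DataFrame(
        {m: cells[MFI_PREFIX + m].to_numpy() > t for m, t in thresholds.items()},
        index=cells.index,
    )


def match_profiles(
    cells: pd.DataFrame,
    panel: PhenotypePanel,
    thresholds: Mapping[str, float],
    min_matched: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stage 1: unique binary-profile matches and representative profiles.

    Returns ``(representatives, calls)``. ``representatives`` is a
    type-by-marker mean-MFI matrix over matched cells, restricted to types
    with at least ``min_matched`` matches. ``calls`` holds one row per cell:
    stage ``profile_match`` with the assigned type, or stage ``None`` for
    cells matching zero or >= 2 profiles (left for stage 2).
    """
    for t, prof in panel.profiles.items():
        for m, s in prof.items():
            if s != "any" and m not in thresholds:
                raise ValueError(f"no threshold for marker {m!r} used by {t!r}")
    binary = binarize(cells, thresholds)
    n = len(cells)
    match_count = np.zeros(n, dtype=int)
    assigned = np.array([None] * n, dtype=object)
    for t, prof in panel.profiles.items():
        mask = np.ones(n, dtype=bool)
        for m, s in prof.items():
            if s == "+":
                mask &= binary[m].to_numpy()
            elif s == "-":
                mask &= ~binary[m].to_numpy()
        assigned[mask & (match_count == 0)] = t
        match_count += mask
    unique = match_count == 1
    assigned[~unique] = None

    calls = pd.DataFrame({
        "cell_id": cells["cell_id"].to_numpy(),
        "stage": np.where(unique, STAGE_PROFILE, None),
        "assigned_type": assigned,
        "coef": np.nan,
        "pval": np.nan,
    })

    markers = panel.markers
    mfi = cells[[MFI_PREFIX + m for m in markers]].to_numpy()
    reps, counts = {}, {}
    for t in panel.profiles:
        sel = unique & (assigned == t)
        counts[t] = int(sel.sum())
        if counts[t] >= min_matched:
            reps[t] = mfi[sel].mean(axis=0)
        else:
            logger.warning(
                "type %s matched only %d cells (< %d); dropped from the "
                "regression dictionary", t, counts[t], min_matched,
            )
    representatives = pd.DataFrame(reps, index=markers).T
    representatives.columns = markers
    representatives["n_matched"] = [counts[t] for t in representatives.index]
    return representatives, calls


# ---------------------------------------------------------------------------
# stage 2: regression-mixture rescue
# ---------------------------------------------------------------------------

def regress_unmatched(
    cells: pd.DataFrame,
    representatives: pd.DataFrame,
    calls: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Stage 2: model each unmatched cell as a mixture of representatives.

    Per cell, OLS of its MFI vector (one observation per marker) on the
    representative-profile matrix (one column per type), no intercept.
    Significant contributors have two-sided t-test p < alpha and a positive
    coefficient; the largest significant coefficient assigns the type.
    Cells with no significant contributor become ``excluded_unmatched``.
    """
    markers = [c for c in representatives.columns if c != "n_matched"]
    types = list(representatives.index)
    if len(types) < 2:
        raise ValueError("need >= 2 representative profiles for regression")
    if len(markers) < len(types):
        raise ValueError("need at least as many markers as types")
    X = representatives[markers].to_numpy().T  # markers x types
    if np.linalg.matrix_rank(X) < len(types):
        corr = np.corrcoef(X.T)
        pairs = [
            (types[i], types[j])
            for i in range(len(types)) for j in range(i + 1, len(types))
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"representative profiles are collinear: {pairs}")

    calls = calls.copy()
    todo = calls.index[calls["stage"].isna()]
    mfi = cells.set_index("cell_id").loc[
        calls.loc[todo, "cell_id"], [MFI_PREFIX + m for m in markers]
    ].to_numpy()
    for row_pos, idx in enumerate(todo):
        res = sm.OLS(mfi[row_pos], X).fit()
        sig = (res.pvalues < alpha) & (res.params > 0)
        if sig.any():
            k = int(np.argmax(np.where(sig, res.params, -np.inf)))
            calls.loc[idx, ["stage", "assigned_type", "coef", "pval"]] = (
                STAGE_REGRESSION, types[k], res.params[k], res.pvalues[k],
            )
        else:
            calls.loc[idx, "stage"] = STAGE_EXCL_UNMATCHED
    return calls


# ---------------------------------------------------------------------------
# stage 3: triage of excluded cells (report only)
# ---------------------------------------------------------------------------

def triage_unmatched(
    cells: pd.DataFrame,
    calls: pd.DataFrame,
    markers: Sequence[str],
    k: int = 5,
    seed: int = 0,
    dominance_ratio: float = 2.0,
) -> pd.DataFrame:
    """K-means triage of excluded cells, searching for unexpected types.

    Clusters standardized MFIs of ``excluded_unmatched`` cells and reports
    per-cluster mean profiles with a single-marker-dominance flag (one
    marker's standardized mean exceeding the runner-up by
    ``dominance_ratio`` marks the cluster as likely noise). Report only:
    excluded cells remain excluded.
    """
    excl_ids = calls.loc[calls["stage"] == STAGE_EXCL_UNMATCHED, "cell_id"]
    if len(excl_ids) < k:
        raise ValueError(f"k={k} exceeds the {len(excl_ids)} excluded cells")
    mfi = cells.set_index("cell_id").loc[
        excl_ids, [MFI_PREFIX + m for m in markers]
    ].to_numpy()
    mu, sd = mfi.mean(axis=0), mfi.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (mfi - mu) / sd
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(z)
    rows = []
    for c in range(k):
        mean_prof = z[km.labels_ == c].mean(axis=0)
        order = np.argsort(mean_prof)[::-1]
        top, second = mean_prof[order[0]], mean_prof[order[1]]
        dominant = top > 0 and (second <= 0 or top / max(second, 1e-12) >= dominance_ratio)
        rows.append({
            "cluster": c,
            "n_cells": int((km.labels_ == c).sum()),
            "top_marker": markers[order[0]],
            "single_marker_dominant": bool(dominant),
            **{f"z_{m}": mean_prof[i] for i, m in enumerate(markers)},
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exclusions + orchestration
# ---------------------------------------------------------------------------

def apply_exclusions(calls: pd.DataFrame, panel: PhenotypePanel) -> pd.DataFrame:
    """Move types on the panel's exclusion list to stage ``excluded_listed``."""
    calls = calls.copy()
    total = len(calls)
    for t in panel.exclusion_list:
        sel = calls["assigned_type"] == t
        n = int(sel.sum())
        calls.loc[sel, "stage"] = STAGE_EXCL_LISTED
        calls.loc[sel, "assigned_type"] = None
        logger.info("excluded %d/%d cells (%.2f%%) typed %s",
                    n, total, 100.0 * n / max(total, 1), t)
    return calls


def classify_cells(
    cells: pd.DataFrame,
    panel: PhenotypePanel | None = None,
    alpha: float = 0.05,
    min_matched: int = 20,
    threshold_overrides: Mapping[str, float] | None = None,
    triage_k: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Run the full three-stage classifier.

    Returns ``(calls, report)`` where calls has one row per cell and report
    carries thresholds, representative profiles, excluded fractions, and
    the k-means triage table (when enough cells were excluded).
    """
    panel = panel or default_panel()
    thresholds = compute_thresholds(cells, panel.markers, threshold_overrides)
    representatives, calls = match_profiles(cells, panel, thresholds, min_matched)
    calls = regress_unmatched(cells, representatives, calls, alpha=alpha)
    n_excl = int((calls["stage"] == STAGE_EXCL_UNMATCHED).sum())
    triage = None
    if n_excl >= triage_k:
        triage = triage_unmatched(cells, calls, panel.markers, k=triage_k, seed=seed)
    calls = apply_exclusions(calls, panel)
    report = {
        "thresholds": thresholds,
        "representatives": representatives,
        "fraction_unmatched_excluded": n_excl / len(calls),
        "fraction_listed_excluded":
            float((calls["stage"] == STAGE_EXCL_LISTED).mean()),
        "triage": triage,
    }
    return calls, report
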