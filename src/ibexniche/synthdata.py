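"""Synthetic multiplex-imaging datasets with known ground truth.

Generates multi-sample, two-genotype cell tables (and optional rasterized
image stacks) that mirror the statistical assumptions of the downstream
pipeline: lesion sizes are zero-truncated negative binomial with a
genotype-specific mean, tumor cells cluster tightly around well-separated
lesion centers, lesion-associated immune cells are placed in an annulus
around each lesion with type frequencies drawn from that lesion's niche
profile, and each cell's marker intensities are log-normal conditioned on
its true type's binary expression profile.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .phenotype import PhenotypePanel, default_panel

MFI_PREFIX = "mfi_"

#: genotype labels used throughout; "control" is the reference arm
GENOTYPES = ("control", "ko")

#: lesion size classes; 1-8 tumor cells is dormant, >8 proliferative
DORMANT_MAX_SIZE = 8


# ---------------------------------------------------------------------------
# zero-truncated negative binomial sampling
# ---------------------------------------------------------------------------

def nb_p0(mu: float, theta: float) -> float:
    """P(Y=0) for NB2 with mean mu and dispersion theta."""
    return float(np.exp(theta * (np.log(theta) - np.log(theta + mu))))


def ztnb_rvs(mu, theta: float, size: int | None = None, rng=None) -> np.ndarray:
    """Sample a zero-truncated NB2 with *underlying* NB mean ``mu``.

    The observed (truncated) mean is ``mu / (1 - p0)`` which exceeds ``mu``.
    ``mu`` may be a scalar or an array broadcast against ``size``.
    """
    rng = np.random.default_rng(rng)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (size,) if size else np.shape(mu)).copy()
    n = mu.size
    out = np.zeros(n, dtype=np.int64)
    # NB2 as Gamma-Poisson; redraw zeros (truncation by rejection)
    pending = np.arange(n)
    while pending.size:
        lam = rng.gamma(theta, mu[pending] / theta)
        draw = rng.poisson(lam)
        out[pending] = draw
        pending = pending[draw == 0]
    return out


def underlying_mean_for_truncated(target_mean: float, theta: float) -> float:
    """Solve the underlying NB mean whose zero-truncated mean equals target.

    The truncated mean mu/(1-p0) is strictly > max(mu, 1); a target <= 1 is
    unattainable.
    """
    if target_mean <= 1.0:
        raise ValueError(f"truncated mean must exceed 1, got {target_mean}")

    def gap(mu):
        return mu / (1.0 - nb_p0(mu, theta)) - target_mean

    return float(optimize.brentq(gap, 1e-9, target_mean, xtol=1e-12))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults emulate the two-genotype mouse design: 3 mice per arm, lesions
    whose observed mean size is 16.8 tumor cells in controls versus 3.8 in
    the myeloid-knockout arm, and two immune niches whose prevalence depends
    on genotype and on whether a lesion is dormant (1-8 cells) or
    proliferative (>8 cells).
    """

    n_samples_per_genotype: int = 3
    n_lesions_per_sample: int = 30
    lesion_size_mean_control: float = 16.8   # observed (truncated) mean
    lesion_size_mean_ko: float = 3.8
    lesion_size_dispersion: float = 2.0      # NB2 theta
    tumor_spread_sigma: float = 25.0         # um
    immune_ring_radius: float = 150.0        # um, outer annulus radius
    immune_per_lesion_mean: float = 80.0     # Poisson mean immune cells/lesion
    n_background_cells: int = 2000
    field_size: tuple[float, float] = (5000.0, 5000.0)  # um
    min_lesion_separation: float = 600.0     # um, 3x the 200 um lesion radius
    niche_profiles: dict[str, dict[str, float]] | None = None
    niche_assignment_rule: dict[tuple[str, str], dict[str, float]] | None = None
    background_composition: dict[str, float] | None = None
    marker_panel: PhenotypePanel | None = None
    mfi_lognormal_params: dict[str, tuple[float, float, float, float]] | None = None
    spillover: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.marker_panel is None:
            self.marker_panel = default_panel()
        if self.niche_profiles is None:
            self.niche_profiles = default_niche_profiles(self.marker_panel)
        if self.niche_assignment_rule is None:
            self.niche_assignment_rule = default_niche_rule()
        if self.background_composition is None:
            self.background_composition = default_background(self.marker_panel)
        if self.mfi_lognormal_params is None:
            self.mfi_lognormal_params = {
                m: (np.log(500.0), 0.35, np.log(20.0), 0.35)
                for m in self.marker_panel.markers
            }
        self.validate()

    def validate(self) -> None:
        if self.lesion_size_mean_control <= 1 or self.lesion_size_mean_ko <= 1:
            raise ValueError("lesion size means must exceed 1 (truncated means)")
        if self.lesion_size_dispersion <= 0 or self.tumor_spread_sigma <= 0:
            raise ValueError("dispersion and tumor_spread_sigma must be positive")
        for name, prof in self.niche_profiles.items():
            total = sum(prof.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"niche profile {name!r} sums to {total}, not 1")
        for m, (mp, sp, mn, sn) in self.mfi_lognormal_params.items():
            if sp <= 0 or sn <= 0:
                raise ValueError(f"sigma for marker {m!r} must be positive")

    def to_yaml(self, path) -> None:
        def plain(x):
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [plain(v) for v in x]
            if isinstance(x, np.floating):
                return float(x)
            if isinstance(x, np.integer):
                return int(x)
            return x

        d = plain(dataclasses.asdict(self))
        d["marker_panel"] = self.marker_panel.to_dict()
        d["niche_assignment_rule"] = {
            f"{g}|{s}": v for (g, s), v in self.niche_assignment_rule.items()
        }
        d["field_size"] = list(self.field_size)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["marker_panel"] = PhenotypePanel.from_dict(d["marker_panel"])
        d["niche_assignment_rule"] = {
            tuple(k.split("|")): v for k, v in d["niche_assignment_rule"].items()
        }
        d["field_size"] = tuple(d["field_size"])
        d["mfi_lognormal_params"] = {
            m: tuple(v) for m, v in d["mfi_lognormal_params"].items()
        }
        d["spillover"] = [tuple(s) for s in d.get("spillover", [])]
        return cls(**d)


def default_niche_profiles(panel: PhenotypePanel) -> dict[str, dict[str, float]]:
    """Two immune niches over the panel's immune types.

    Niche 1 is T-cell / macrophage / cDC2 rich (proliferative-lesion-like);
    niche 2 is CD103+ cDC / NK / NKT / monocyte-neutrophil rich
    (dormant-lesion-like).
    """
    niche1 = {
        "cd4_t": 0.22, "cd8_t": 0.22, "alveolar_macrophage": 0.16,
        "macrophage": 0.16, "cdc2": 0.14, "cd103_cdc": 0.02, "nk": 0.02,
        "nkt": 0.02, "mono_neutrophil": 0.04,
    }
    niche2 = {
        "cd4_t": 0.03, "cd8_t": 0.03, "alveolar_macrophage": 0.04,
        "macrophage": 0.04, "cdc2": 0.02, "cd103_cdc": 0.24, "nk": 0.22,
        "nkt": 0.16, "mono_neutrophil": 0.22,
    }
    for prof in (niche1, niche2):
        assert set(prof) <= set(panel.immune_types())
        s = sum(prof.values())
        for k in prof:
            prof[k] /= s
    return {"niche1": niche1, "niche2": niche2}


def default_niche_rule() -> dict[tuple[str, str], dict[str, float]]:
    """P(niche | genotype, size class): dormant and KO lesions lean niche 2.

    Both ties are strong on purpose — the study this emulates found clear
    niche shifts with both lesion size and genotype, so the planted effects
    are sized to be unambiguous at a few hundred lesions.
    """
    return {
        ("control", "dormant"): {"niche1": 0.45, "niche2": 0.55},
        ("control", "proliferative"): {"niche1": 0.95, "niche2": 0.05},
        ("ko", "dormant"): {"niche1": 0.05, "niche2": 0.95},
        ("ko", "proliferative"): {"niche1": 0.50, "niche2": 0.50},
    }


def default_background(panel: PhenotypePanel) -> dict[str, float]:
    """Parenchymal background composition: mostly myeloid, a trace of gdT."""
    types = [t for t in panel.immune_types() if t != "gd_t"]
    w = {t: 1.0 for t in types}
    for t in ("macrophage", "mono_neutrophil"):
        if t in w:
            w[t] = 2.0
    comp = {t: v / sum(w.values()) for t, v in w.items()}
    if "gd_t" in panel.immune_types():
        comp = {t: v * 0.995 for t, v in comp.items()}
        comp["gd_t"] = 0.005
    return comp


# ---------------------------------------------------------------------------
# ground truth container
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """True per-cell phenotype/lesion labels and per-lesion niche labels."""

    cells: pd.DataFrame    # cell_id, true_type, true_lesion_id (-1 = none)
    lesions: pd.DataFrame  # lesion_id, sample_id, genotype, niche, size


# ---------------------------------------------------------------------------
# cell placement
# ---------------------------------------------------------------------------

def _place_lesion_centers(n, field, min_sep, margin, rng, max_tries=20000):
    w, h = field
    if w - 2 * margin <= 0 or h - 2 * margin <= 0:
        raise ValueError(
            f"field {field} too small for margin {margin} um around lesions"
        )
    centers = np.empty((0, 2))
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise ValueError(
                f"field {field} too small to place {n} lesions with "
                f"minimum separation {min_sep} um (after {max_tries} tries)"
            )
        pt = rng.uniform([margin, margin], [w - margin, h - margin])
        if centers.size and np.min(np.hypot(*(centers - pt).T)) <= min_sep:
            tries += 1
            continue
        centers = np.vstack([centers, pt])
    return centers


def _annulus_points(n, center, r_inner, r_outer, rng):
    # uniform by area on the annulus
    u = rng.uniform(r_inner**2, r_outer**2, n)
    r = np.sqrt(u)
    ang = rng.uniform(0, 2 * np.pi, n)
    return center + np.column_stack([r * np.cos(ang), r * np.sin(ang)])


def _draw_mfi(types: Sequence[str], config: SimConfig, rng) -> pd.DataFrame:
    panel = config.marker_panel
    n = len(types)
    type_idx = pd.Index(types)
    cols = {}
    for m in panel.markers:
        mu_pos, sd_pos, mu_neg, sd_neg = config.mfi_lognormal_params[m]
        pos_types = {t for t, prof in panel.profiles.items() if prof.get(m) == "+"}
        is_pos = type_idx.isin(pos_types)
        mu = np.where(is_pos, mu_pos, mu_neg)
        sd = np.where(is_pos, sd_pos, sd_neg)
        cols[MFI_PREFIX + m] = rng.lognormal(mu, sd, n)
    df = pd.DataFrame(cols)
    # shared-background spillover: one latent log-normal term added to both
    # channels of a pair, emulating autofluorescence / bleed-through
    for a, b, scale in config.spillover:
        shared = rng.lognormal(np.log(150.0), 0.3, n)
        df[MFI_PREFIX + a] += scale * shared
        df[MFI_PREFIX + b] += shared
    return df


def simulate_cells(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the full multi-sample cell table plus its ground truth.

    Returns a table with columns ``sample_id, genotype, cell_id, x_um, y_um,
    nucleus_area_um2, mfi_<marker>...`` (no phenotype — that is the
    classifier's job) and a :class:`GroundTruth` sidecar.
    """
    rng = np.random.default_rng(config.seed)
    panel = config.marker_panel
    theta = config.lesion_size_dispersion
    mu_by_geno = {
        "control": underlying_mean_for_truncated(config.lesion_size_mean_control, theta),
        "ko": underlying_mean_for_truncated(config.lesion_size_mean_ko, theta),
    }
    bg_types = list(config.background_composition)
    bg_probs = np.array([config.background_composition[t] for t in bg_types])
    bg_probs = bg_probs / bg_probs.sum()

    rows, truth_rows, lesion_rows = [], [], []
    lesion_id = 0
    for genotype in GENOTYPES:
        for si in range(config.n_samples_per_genotype):
            sample = f"{genotype}_{si + 1}"
            xs, ys, types, les_ids = [], [], [], []
            n_les = config.n_lesions_per_sample
            if n_les > 0:
                sizes = ztnb_rvs(mu_by_geno[genotype], theta, n_les, rng)
                centers = _place_lesion_centers(
                    n_les, config.field_size, config.min_lesion_separation,
                    config.immune_ring_radius + 4 * config.tumor_spread_sigma,
                    rng,
                )
                for k in range(n_les):
                    size = int(sizes[k])
                    size_class = "dormant" if size <= DORMANT_MAX_SIZE else "proliferative"
                    probs = config.niche_assignment_rule[(genotype, size_class)]
                    niche_names = list(probs)
                    niche = niche_names[
                        rng.choice(len(niche_names), p=np.array([probs[n] for n in niche_names]))
                    ]
                    pos = centers[k] + rng.normal(0, config.tumor_spread_sigma, (size, 2))
                    xs.extend(pos[:, 0]); ys.extend(pos[:, 1])
                    types.extend([panel.tumor_type_name] * size)
                    les_ids.extend([lesion_id] * size)
                    # lesion-associated immune cells in the annulus
                    prof = config.niche_profiles[niche]
                    imm_types = list(prof)
                    n_imm = rng.poisson(config.immune_per_lesion_mean)
                    imm_draw = rng.choice(
                        len(imm_types), n_imm, p=np.array([prof[t] for t in imm_types])
                    )
                    ipos = _annulus_points(
                        n_imm, centers[k],
                        0.2 * config.immune_ring_radius, config.immune_ring_radius, rng,
                    )
                    xs.extend(ipos[:, 0]); ys.extend(ipos[:, 1])
                    types.extend([imm_types[i] for i in imm_draw])
                    les_ids.extend([-1] * n_imm)
                    lesion_rows.append((lesion_id, sample, genotype, niche, size))
                    lesion_id += 1
            # background immune cells anywhere in the field
            nbg = config.n_background_cells
            bgpos = rng.uniform([0, 0], list(config.field_size), (nbg, 2))
            bgdraw = rng.choice(len(bg_types), nbg, p=bg_probs)
            xs.extend(bgpos[:, 0]); ys.extend(bgpos[:, 1])
            types.extend([bg_types[i] for i in bgdraw])
            les_ids.extend([-1] * nbg)

            n = len(xs)
            sample_df = pd.DataFrame({
                "sample_id": sample,
                "genotype": genotype,
                "x_um": np.asarray(xs, dtype=float),
                "y_um": np.asarray(ys, dtype=float),
                "nucleus_area_um2": rng.lognormal(np.log(35.0), 0.15, n),
            })
            sample_df = pd.concat([sample_df, _draw_mfi(types, config, rng)], axis=1)
            rows.append(sample_df)
            truth_rows.append(pd.DataFrame({
                "true_type": types,
                "true_lesion_id": np.asarray(les_ids, dtype=np.int64),
            }))

    cells = pd.concat(rows, ignore_index=True)
    cells.insert(2, "cell_id", np.arange(len(cells), dtype=np.int64))
    truth_cells = pd.concat(truth_rows, ignore_index=True)
    truth_cells.insert(0, "cell_id", cells["cell_id"].to_numpy())
    truth_lesions = pd.DataFrame(
        lesion_rows, columns=["lesion_id", "sample_id", "genotype", "niche", "size"]
    )
    return cells, GroundTruth(cells=truth_cells, lesions=truth_lesions)


def simulate_flat_field(
    n_cells: int,
    field_size: tuple[float, float] = (400.0, 400.0),
    min_separation: float = 15.0,
    panel: PhenotypePanel | None = None,
    mfi_params: Mapping[str, tuple[float, float, float, float]] | None = None,
    spillover: Sequence[tuple[str, str, float]] = (),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scatter ``n_cells`` of random types with a minimum pairwise separation.

    Intended for imaging round-trip tests where nuclei must not overlap.
    Returns (cell table, truth table with true_type).
    """
    rng = np.random.default_rng(seed)
    panel = panel or default_panel()
    cfg = SimConfig(marker_panel=panel, spillover=list(spillover), seed=seed)
    if mfi_params is not None:
        cfg.mfi_lognormal_params = dict(mfi_params)
    margin = min_separation
    pts = np.empty((0, 2))
    tries = 0
    while len(pts) < n_cells:
        if tries > 200000:
            raise ValueError(
                f"field {field_size} too small for {n_cells} cells at "
                f"separation {min_separation} um"
            )
        pt = rng.uniform([margin, margin],
                         [field_size[0] - margin, field_size[1] - margin])
        if pts.size and np.min(np.hypot(*(pts - pt).T)) < min_separation:
            tries += 1
            continue
        pts = np.vstack([pts, pt])
    all_types = list(panel.profiles)
    types = [all_types[i] for i in rng.choice(len(all_types), n_cells)]
    cells = pd.DataFrame({
        "sample_id": "flat_1",
        "genotype": "control",
        "cell_id": np.arange(n_cells, dtype=np.int64),
        "x_um": pts[:, 0],
        "y_um": pts[:, 1],
        "nucleus_area_um2": rng.lognormal(np.log(35.0), 0.10, n_cells),
    })
    cells = pd.concat([cells, _draw_mfi(types, cfg, rng)], axis=1)
    truth = pd.DataFrame({"cell_id": cells["cell_id"], "true_type": types})
    return cells, truth


def simulate_tumor_flags(
    p_control: float = 0.05,
    p_ko: float = 0.02,
    n_samples_per_genotype: int = 3,
    cells_per_sample: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bernoulli tumor-cell indicators for the logistic genotype model."""
    rng = np.random.default_rng(seed)
    frames = []
    for genotype, p in (("control", p_control), ("ko", p_ko)):
        for si in range(n_samples_per_genotype):
            frames.append(pd.DataFrame({
                "sample_id": f"{genotype}_{si + 1}",
                "genotype": genotype,
                "is_tumor": rng.random(cells_per_sample) < p,
            }))
    return pd.concat(frames, ignore_index=True)


def simulate_lesion_sizes(
    mu_control: float,
    mu_ko: float,
    theta: float,
    lesions_per_arm: int,
    n_samples_per_genotype: int = 3,
    seed: int = 0,
    truncated_means: bool = False,
) -> pd.DataFrame:
    """ZTNB lesion sizes for two genotype arms, spread over samples.

    ``mu_*`` are underlying NB means unless ``truncated_means`` is set, in
    which case they are the observed means and the underlying means are
    solved for.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for genotype, mu in (("control", mu_control), ("ko", mu_ko)):
        if truncated_means:
            mu = underlying_mean_for_truncated(mu, theta)
        sizes = ztnb_rvs(mu, theta, lesions_per_arm, rng)
        samples = [
            f"{genotype}_{1 + (i % n_samples_per_genotype)}"
            for i in range(lesions_per_arm)
        ]
        frames.append(pd.DataFrame({
            "sample_id": samples, "genotype": genotype, "size": sizes,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_lesion_compositions(
    n_lesions: int = 150,
    config: SimConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Lesion-by-immune-type count table drawn directly from niche profiles.

    A fast alternative to the full spatial generator for niche-analysis
    studies: lesion sizes, genotypes and niche labels follow the same laws
    as :func:`simulate_cells`, but immune counts are multinomial draws
    without spatial placement.

    Columns: lesion_id, sample_id, genotype, size, true_niche, n_<type>...
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    theta = cfg.lesion_size_dispersion
    rows = []
    imm_types = sorted({t for p in cfg.niche_profiles.values() for t in p})
    for i in range(n_lesions):
        genotype = GENOTYPES[i % 2]
        tgt = (cfg.lesion_size_mean_control if genotype == "control"
               else cfg.lesion_size_mean_ko)
        mu = underlying_mean_for_truncated(tgt, theta)
        size = int(ztnb_rvs(mu, theta, 1, rng)[0])
        size_class = "dormant" if size <= DORMANT_MAX_SIZE else "proliferative"
        probs = cfg.niche_assignment_rule[(genotype, size_class)]
        names = list(probs)
        niche = names[rng.choice(len(names), p=np.array([probs[n] for n in names]))]
        prof = cfg.niche_profiles[niche]
        n_imm = rng.poisson(cfg.immune_per_lesion_mean)
        counts = rng.multinomial(n_imm, [prof.get(t, 0.0) for t in imm_types])
        sample = f"{genotype}_{1 + (i // 2) % cfg.n_samples_per_genotype}"
        rows.append([i, sample, genotype, size, niche, *counts])
    return pd.DataFrame(
        rows,
        columns=["lesion_id", "sample_id", "genotype", "size", "true_niche"]
                + [f"n_{t}" for t in imm_types],
    )


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def rasterize(
    cells: pd.DataFrame,
    markers: Sequence[str],
    field_size: tuple[float, float],
    pixel_size: float = 0.284,
    nuclear_intensity: float = 200.0,
    blur_sigma_px: float = 1.0,
    sample_id: str = "synthetic",
):
    """Render a cell table into a multichannel image stack.

    The nuclear channel holds one disk per cell (radius from nucleus area);
    each marker channel holds the same disks scaled by the cell's MFI, then
    Gaussian-blurred. Returns an :class:`~ibexniche.imaging.ImageStack`.
    """
    from scipy import ndimage

    from .imaging import ImageStack

    w_px = int(np.ceil(field_size[0] / pixel_size))
    h_px = int(np.ceil(field_size[1] / pixel_size))
    shape = (h_px, w_px)
    nuclear = np.zeros(shape, dtype=np.float32)
    chans = {m: np.zeros(shape, dtype=np.float32) for m in markers}

    yy, xx = np.mgrid[0:h_px, 0:w_px]
    for _, cell in cells.iterrows():
        r_um = np.sqrt(cell["nucleus_area_um2"] / np.pi)
        r_px = max(2.0, r_um / pixel_size)
        cx = cell["x_um"] / pixel_size
        cy = cell["y_um"] / pixel_size
        x0, x1 = int(max(0, cx - r_px - 2)), int(min(w_px, cx + r_px + 3))
        y0, y1 = int(max(0, cy - r_px - 2)), int(min(h_px, cy + r_px + 3))
        if x0 >= x1 or y0 >= y1:
            continue
        disk = ((xx[y0:y1, x0:x1] - cx) ** 2 + (yy[y0:y1, x0:x1] - cy) ** 2
                <= r_px**2)
        nuclear[y0:y1, x0:x1][disk] = nuclear_intensity
        for m in markers:
            chans[m][y0:y1, x0:x1][disk] = cell[MFI_PREFIX + m]

    channels = {"nuclear": ndimage.gaussian_filter(nuclear, blur_sigma_px)}
    for m in markers:
        channels[m] = ndimage.gaussian_filter(chans[m], blur_sigma_px)
    return ImageStack(channels=channels, pixel_size=pixel_size, sample_id=sample_id)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def format_table(df: pd.DataFrame) -> pd.DataFrame:
    """Round floats to 9 significant digits for byte-stable CSV output."""
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            vals = out[c].to_numpy()
            with np.errstate(divide="ignore", invalid="ignore"):
                mag = np.where(vals != 0, np.floor(np.log10(np.abs(vals))), 0.0)
            factor = np.power(10.0, 8.0 - mag)
            out[c] = np.round(vals * factor) / factor
    return out


def write_cell_table(cells: pd.DataFrame, path_csv, path_parquet=None) -> None:
    fixed = format_table(cells)
    fixed.to_csv(path_csv, index=False)
    if path_parquet is not None:
        fixed.to_parquet(path_parquet, index=False)


def write_ground_truth(truth: GroundTruth, cells_path, lesions_path) -> None:
    truth.cells.to_csv(cells_path, index=False)
    truth.lesions.to_csv(lesions_path, index=False)


def cells_to_csv_bytes(cells: pd.DataFrame) -> bytes:
    buf = io.StringIO()
    format_table(cells).to_csv(buf, index=False)
    return buf.getvalue().encode()
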