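"""Seed-based resting-state connectivity and hypoxia-normoxia contrasts.

Eight seeds — left/right Motor and Somatosensory (anterior macrocluster),
Retrosplenial and Visual (posterior macrocluster) — are 3-pixel-radius
disks around the region centroids.  Seed time courses are correlated
pairwise (Pearson) inside analysis windows (hypoxia: minutes 12.5-17.5;
normoxia: minutes 2.5-7.5), Fisher z-transformed, and the per-subject
z-difference (hypoxia minus normoxia) is tested pair-wise with an exact
Wilcoxon signed-rank test under Benjamini-Hochberg FDR.  Within- versus
between-macrocluster per-subject mean changes are compared with paired
t-tests (after normality/variance checks).  Global signal regression is
available for seed-pixel correlation maps only; quantitative statistics
run on data without GSR.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as hstats

logger = logging.getLogger(__name__)

__all__ = [
    "Seed",
    "SeedSet",
    "ConnectivityMatrix",
    "EpochContrast",
    "global_signal_regression",
    "extract_seeds",
    "seed_timecourse",
    "seed_pixel_correlation_map",
    "connectivity_matrix",
    "fisher_z",
    "epoch_contrast",
    "longitudinal_normoxia_screen",
]

SEED_RADIUS_PX = 3
#: analysis windows in minutes
HYPOXIA_WINDOW_MIN = (12.5, 17.5)
NORMOXIA_WINDOW_MIN = (2.5, 7.5)

Z_CLIP = 1.0 - 1e-12


@dataclass(frozen=True)
class Seed:
    name: str
    macrocluster: str
    centroid: tuple[int, int]            # (row, col)
    pixels: tuple[tuple[int, int], ...]  # lattice disk ∩ brain mask


@dataclass
class SeedSet:
    seeds: list[Seed]
    atlas_id: str = "synthetic"

    def __iter__(self):
        return iter(self.seeds)

    def __len__(self) -> int:
        return len(self.seeds)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.seeds]

    def pairs(self) -> list[tuple[int, int]]:
        return list(itertools.combinations(range(len(self.seeds)), 2))

    def pair_kind(self, i: int, j: int) -> str:
        a, b = self.seeds[i], self.seeds[j]
        return "within" if a.macrocluster == b.macrocluster else "between"


@dataclass
class ConnectivityMatrix:
    modality: str                  # "gcamp" or "hbo"
    window_s: tuple[float, float]
    r: np.ndarray                  # seed x seed Pearson correlations
    z: np.ndarray                  # Fisher-transformed copy
    seed_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.seed_names, columns=self.seed_names)


@dataclass
class EpochContrast:
    """Per-subject Fisher-z differences (hypoxia minus normoxia) and tests."""

    modality: str
    dz: np.ndarray                       # (n_subjects, n_seeds, n_seeds)
    seed_names: list[str]
    pair_stats: pd.DataFrame             # seed_a, seed_b, kind, mean_dz, p, q
    cluster_means: pd.DataFrame          # subject x {within, between}
    cluster_test: dict


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilising Fisher transform, z = atanh(r), |r| clipped."""
    return np.arctanh(np.clip(r, -Z_CLIP, Z_CLIP))


def global_signal_regression(maps: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Remove the global signal from every pixel trace by linear regression.

    The global signal g(t) is the in-mask spatial mean per frame; each pixel
    trace is replaced by its OLS residual from the fit on (1, g), so the
    residuals are exactly orthogonal to g.  Used for seed-pixel correlation
    maps only — quantitative statistics run on un-regressed data.
    """
    if not mask.any():
        raise ValueError("mask is empty")
    maps = np.asarray(maps, dtype=np.float64)
    g = maps[:, mask].mean(axis=1)
    gc = g - g.mean()
    denom = gc @ gc
    if denom == 0:
        logger.warning("global signal has zero variance; returning input unchanged")
        return maps.copy()
    y = maps[:, mask]                       # (t, n_pix)
    beta = (gc @ y) / denom                 # slope per pixel
    mean_y = y.mean(axis=0)
    resid = y - mean_y - np.outer(gc, beta)
    out = maps.copy()
    out[:, mask] = resid
    return out


def _disk_offsets(radius: int = SEED_RADIUS_PX) -> np.ndarray:
    span = np.arange(-radius, radius + 1)
    dr, dc = np.meshgrid(span, span, indexing="ij")
    keep = dr**2 + dc**2 <= radius**2
    return np.stack([dr[keep], dc[keep]], axis=1)   # 29 offsets for r=3


def extract_seeds(
    regions: pd.DataFrame,
    brain_mask: np.ndarray,
    radius: int = SEED_RADIUS_PX,
    atlas_id: str = "synthetic",
) -> SeedSet:
    """Build the 8 seed disks from region centroids and the brain mask.

    Each seed is the lattice disk of the given radius (squared distance
    <= radius^2; 29 pixels at radius 3) around the integer-rounded region
    centroid, intersected with the brain mask.  A centroid falling outside
    the mask is moved to the nearest in-mask pixel (logged).
    """
    offsets = _disk_offsets(radius)
    rows, cols = brain_mask.shape
    seeds = []
    for _, reg in regions.iterrows():
        r0, c0 = int(reg["centroid_row"]), int(reg["centroid_col"])
        if not brain_mask[r0, c0]:
            rr, cc = np.nonzero(brain_mask)
            k = np.argmin((rr - r0) ** 2 + (cc - c0) ** 2)
            logger.warning(
                "seed %s centroid (%d, %d) outside mask; moved to (%d, %d)",
                reg["name"], r0, c0, rr[k], cc[k],
            )
            r0, c0 = int(rr[k]), int(cc[k])
        pix = []
        for dr, dc in offsets:
            r, c = r0 + dr, c0 + dc
            if 0 <= r < rows and 0 <= c < cols and brain_mask[r, c]:
                pix.append((int(r), int(c)))
        if not pix:
            raise ValueError(f"seed {reg['name']} has no in-mask pixels")
        seeds.append(
            Seed(
                name=reg["name"],
                macrocluster=reg["macrocluster"],
                centroid=(r0, c0),
                pixels=tuple(pix),
            )
        )
    return SeedSet(seeds=seeds, atlas_id=atlas_id)


def seed_timecourse(maps: np.ndarray, seed: Seed) -> np.ndarray:
    """Unweighted mean trace over the seed's pixel set."""
    if not seed.pixels:
        raise ValueError(f"seed {seed.name} has an empty pixel set")
    rr = [p[0] for p in seed.pixels]
    cc = [p[1] for p in seed.pixels]
    return np.asarray(maps[:, rr, cc], dtype=float).mean(axis=1)


def _window_slice(window_min: tuple[float, float], fps: float, n_frames: int) -> slice:
    i0 = int(np.floor(window_min[0] * 60.0 * fps))
    i1 = int(np.floor(window_min[1] * 60.0 * fps))
    if i0 >= i1 or i1 > n_frames:
        raise ValueError(
            f"window {window_min} min outside acquisition of {n_frames / fps / 60.0:.2f} min"
        )
    return slice(i0, i1)


def seed_pixel_correlation_map(
    maps: np.ndarray,
    seed: Seed,
    mask: np.ndarray,
    fps: float,
    window_min: tuple[float, float] = HYPOXIA_WINDOW_MIN,
    gsr: bool = False,
) -> np.ndarray:
    """Pearson correlation of the seed trace with every in-mask pixel trace.

    Returns an image of r values (NaN outside the mask and at zero-variance
    pixels), computed over the analysis window, optionally after GSR.
    """
    sl = _window_slice(window_min, fps, len(maps))
    data = maps[sl]
    if gsr:
        data = global_signal_regression(data, mask)
    trace = seed_timecourse(data, seed)
    tc = trace - trace.mean()
    t_norm = np.sqrt(tc @ tc)

    y = np.asarray(data[:, mask], dtype=np.float64)
    yc = y - y.mean(axis=0)
    y_norm = np.sqrt((yc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (tc @ yc) / (t_norm * y_norm)
    r[y_norm == 0] = np.nan
    out = np.full(mask.shape, np.nan)
    out[mask] = r
    return out


def connectivity_matrix(
    maps: np.ndarray,
    seeds: SeedSet,
    fps: float,
    window_min: tuple[float, float],
    modality: str = "gcamp",
    min_frames: int = 30,
) -> ConnectivityMatrix:
    """Pairwise Pearson correlations between seed traces over a window."""
    sl = _window_slice(window_min, fps, len(maps))
    if sl.stop - sl.start < min_frames:
        raise ValueError(
            f"window {window_min} min holds {sl.stop - sl.start} frames; need >= {min_frames}"
        )
    traces = np.stack([seed_timecourse(maps[sl], s) for s in seeds], axis=1)
    r = np.corrcoef(traces.T)
    return ConnectivityMatrix(
        modality=modality,
        window_s=(window_min[0] * 60.0, window_min[1] * 60.0),
        r=r,
        z=fisher_z(r),
        seed_names=seeds.names,
    )


def epoch_contrast(
    hypoxia: list[ConnectivityMatrix],
    normoxia: list[ConnectivityMatrix],
    seeds: SeedSet,
    min_subjects_for_tests: int = 5,
) -> EpochContrast:
    """Fisher-z epoch differences across a subject cohort, with statistics.

    Per subject, dz = z(hypoxia) - z(normoxia).  Each of the 28 unique seed
    pairs is tested across subjects with the exact Wilcoxon signed-rank test
    and BH-FDR; within- vs between-macrocluster per-subject mean changes are
    compared with a paired t-test per condition (normality checked by KS,
    logged when violated) under BH-FDR.  With fewer than
    ``min_subjects_for_tests`` subjects the tests are skipped with a warning
    and only the estimates are reported.
    """
    if len(hypoxia) != len(normoxia):
        raise ValueError("need matched hypoxia/normoxia matrices per subject")
    n_sub = len(hypoxia)
    dz = np.stack([h.z - n.z for h, n in zip(hypoxia, normoxia)])

    pairs = seeds.pairs()
    names = seeds.names
    run_tests = n_sub >= min_subjects_for_tests
    if not run_tests:
        logger.warning("only %d subjects; pairwise tests skipped", n_sub)

    records = []
    pvals = []
    for i, j in pairs:
        diffs = dz[:, i, j]
        rec = {
            "seed_a": names[i],
            "seed_b": names[j],
            "kind": seeds.pair_kind(i, j),
            "mean_dz": float(diffs.mean()),
        }
        if run_tests:
            if np.all(diffs == 0):  # identical epochs: no evidence of change
                rec["p"] = 1.0
            else:
                rec["p"] = hstats.wilcoxon_signed_rank(diffs).p
            pvals.append(rec["p"])
        records.append(rec)
    pair_stats = pd.DataFrame.from_records(records)
    if run_tests:
        pair_stats["q"] = hstats.benjamini_hochberg(np.asarray(pvals))

    within_idx = [(i, j) for i, j in pairs if seeds.pair_kind(i, j) == "within"]
    between_idx = [(i, j) for i, j in pairs if seeds.pair_kind(i, j) == "between"]
    cluster_means = pd.DataFrame(
        {
            "within": [dz[s][tuple(zip(*within_idx))].mean() for s in range(n_sub)],
            "between": [dz[s][tuple(zip(*between_idx))].mean() for s in range(n_sub)],
        }
    )

    cluster_test: dict = {}
    if run_tests:
        d = cluster_means["within"] - cluster_means["between"]
        norm = hstats.ks_normality(d.to_numpy())
        if norm.p < 0.05:
            logger.warning("cluster-mean differences look non-normal (KS p=%.3g)", norm.p)
        t_res = hstats.paired_t_test(
            cluster_means["within"].to_numpy(), cluster_means["between"].to_numpy()
        )
        cluster_test = {"t": t_res.statistic, "p": t_res.p, "n": t_res.n, "ks_p": norm.p}

    return EpochContrast(
        modality=hypoxia[0].modality,
        dz=dz,
        seed_names=names,
        pair_stats=pair_stats,
        cluster_means=cluster_means,
        cluster_test=cluster_test,
    )


def longitudinal_normoxia_screen(
    weekly: dict[str, list[ConnectivityMatrix]],
    seeds: SeedSet,
) -> pd.DataFrame:
    """Screen for chronic week-to-week connectivity drift under normoxia.

    ``weekly`` maps week label -> per-subject matrices over the normoxia
    window (minutes 2.5-7.5), subjects matched across weeks.  Each unique
    seed pair is tested with a Friedman test across weeks (BH-FDR over the
    28 pairs); for pairs significant at q < 0.05, each later week is
    compared to the first with a Kruskal-Wallis test.
    """
    weeks = list(weekly)
    if len(weeks) < 3:
        raise ValueError(f"need >= 3 weeks, got {len(weeks)}")
    n_sub = len(weekly[weeks[0]])
    for w in weeks:
        if len(weekly[w]) != n_sub:
            raise ValueError(f"week {w} has {len(weekly[w])} subjects; expected {n_sub}")

    pairs = seeds.pairs()
    names = seeds.names
    records = []
    for i, j in pairs:
        blocks = np.array([[weekly[w][s].z[i, j] for w in weeks] for s in range(n_sub)])
        res = hstats.friedman(blocks)
        records.append(
            {
                "seed_a": names[i],
                "seed_b": names[j],
                "friedman_stat": res.statistic,
                "p": res.p,
                "_blocks": blocks,
            }
        )
    df = pd.DataFrame.from_records(records)
    df["q"] = hstats.benjamini_hochberg(df["p"].to_numpy())

    followups = []
    for _, row in df.iterrows():
        if row["q"] < 0.05:
            blocks = row["_blocks"]
            week1 = blocks[:, 0]
            ps = {}
            for k, w in enumerate(weeks[1:], start=1):
                ps[w] = hstats.kruskal_wallis([week1, blocks[:, k]]).p
            followups.append(ps)
        else:
            followups.append({})
    df["kruskal_vs_week1"] = followups
    return df.drop(columns="_blocks")
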