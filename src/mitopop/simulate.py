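"""Synthetic tile and cohort generation with known ground truth.

Tiles emulate three-channel confocal fields of a monocyte primary culture:
a transmitted-light channel in which each cell appears as a disk with a
dark rim on a bright background, a MitoTracker channel whose per-cell
intensity is drawn from a two-component log-normal mixture (low/high
membrane potential), and a PpIX channel positive for every intact cell.
Cohorts carry a planted across-subject mixture of MitoTracker-low
proportions and a planted (negative) linear effect of that proportion on
LPS-induced TNF secretion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .imio import Tile

__all__ = [
    "SceneSpec",
    "SubjectSpec",
    "CohortSpec",
    "ObjectTruth",
    "GroundTruth",
    "render_tile",
    "render_subject",
    "generate_cohort",
    "FCCP_ATTENUATION",
]

# Transmitted-light rendering levels (counts), chosen so the rim step
# dominates shot noise by more than an order of magnitude.
TRANS_BACKGROUND = 28000.0
TRANS_INTERIOR = 25500.0
TRANS_RIM = 12000.0
RIM_WIDTH_PX = 2.0

# Dark-offset baselines of the fluorescence detectors (counts).
MT_OFFSET = 80.0
PPIX_OFFSET = 80.0

# Multiplicative within-cell texture (log-normal speckle, ~10% SD).
SPECKLE_SD = 0.10

# Attenuation of the low-component intensity under ablated membrane potential.
FCCP_ATTENUATION = 0.1

# Minimum clearance between object footprints so that distinct objects
# never merge after smoothing + morphological closing (px).
_MIN_GAP_PX = 12.0
# Guard band for the ground-truth border flag (px); the segmented mask can
# extend a few px beyond the rendered disk, so the flag is conservative.
_BORDER_GUARD_PX = 6.0

# Clump geometry: sub-disks are cell-sized scaled by this factor and sit on
# a ring around the anchor, keeping the union area above the singlet window.
_CLUMP_SUBDISK_SCALE = 1.35
_CLUMP_RING_SCALE = 1.1


@dataclass(frozen=True)
class SceneSpec:
    """Geometry, density and noise of one rendered field of view."""

    tile_px: int = 512
    um_per_px: float = 0.4395
    cells_per_tile_mean: float = 40.0
    frac_clump: float = 0.08
    frac_debris: float = 0.10
    radius_log_mean: float = math.log(7.0)  # ln of radius in um
    radius_log_sd: float = 0.12
    noise_read_sd: float = 30.0
    photon_scale: float = 0.1  # <=0 disables shot noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tile_px <= 0 or self.um_per_px <= 0:
            raise ValueError("tile_px and um_per_px must be positive")
        if self.cells_per_tile_mean < 0:
            raise ValueError("cells_per_tile_mean must be >= 0")
        if not (0 <= self.frac_clump and 0 <= self.frac_debris
                and self.frac_clump + self.frac_debris < 1):
            raise ValueError("require frac_clump + frac_debris < 1, both >= 0")
        if self.radius_log_sd < 0 or self.noise_read_sd < 0:
            raise ValueError("scale parameters must be non-negative")

    @property
    def tile_um(self) -> float:
        return self.tile_px * self.um_per_px


@dataclass(frozen=True)
class SubjectSpec:
    """Per-subject generative parameters.

    Intensity parameters are log10 of per-pixel mean counts; the drawn
    per-cell intensity is that mean times the rasterized pixel count.
    """

    subject_id: int
    group: int = 0
    n_tiles: int = 27
    pi_low: float = 0.2
    mt_low_log_mean: float = 2.2
    mt_high_log_mean: float = 3.4
    mt_log_sd: float = 0.18
    ppix_log_mean: float = 2.8
    ppix_log_sd: float = 0.25
    fccp_mode: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi_low <= 1.0:
            raise ValueError("pi_low must lie in [0, 1]")
        if self.mt_low_log_mean >= self.mt_high_log_mean:
            raise ValueError("mt_low_log_mean must be < mt_high_log_mean")
        if self.n_tiles < 1:
            raise ValueError("n_tiles must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generative parameters.

    ``pi_mix`` is a two-component Beta mixture ((weight, alpha, beta), ...)
    for the across-subject MitoTracker-low proportion.  ``beta_tnf`` is the
    linear effect (pg/mL per unit proportion) of that proportion on
    LPS-induced TNF; the planted default is negative.
    """

    n_young: int = 5
    n_old_healthy: int = 7
    n_athero: int = 24
    pi_mix: tuple = ((0.6, 6.0, 34.0), (0.4, 18.0, 22.0))
    beta_tnf: float = -3300.0
    tnf_lps_intercept: float = 3650.0
    tnf_basal_mean: float = 850.0
    tnf_basal_sd: float = 250.0
    tnf_noise_sd: float = 600.0
    tnf_floor: float = 10.0
    plaque_effect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_young, self.n_old_healthy, self.n_athero) < 0:
            raise ValueError("group sizes must be >= 0")
        w = sum(c[0] for c in self.pi_mix)
        if not math.isclose(w, 1.0, abs_tol=1e-9):
            raise ValueError("mixture weights must sum to 1")

    @property
    def n_subjects(self) -> int:
        return self.n_young + self.n_old_healthy + self.n_athero


@dataclass
class ObjectTruth:
    """Ground truth for one rendered object."""

    centroid_x: float
    centroid_y: float
    radius_px: float
    kind: str  # singlet | clump | debris
    subpop: str | None  # low | high, singlets only
    mt_mean: float  # drawn per-pixel mean (counts above offset)
    mt_total: float  # mt_mean * rasterized pixel count
    ppix_mean: float
    ppix_total: float
    n_px: int
    touches_border: bool


@dataclass
class GroundTruth:
    subject_id: int
    tile_index: int
    objects: list[ObjectTruth] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = ["centroid_x", "centroid_y", "radius_px", "kind", "subpop",
                "mt_mean", "mt_total", "ppix_mean", "ppix_total", "n_px",
                "touches_border"]
        rows = [{c: getattr(o, c) for c in cols} for o in self.objects]
        df = pd.DataFrame(rows, columns=cols)
        df.insert(0, "tile_index", self.tile_index)
        df.insert(0, "patient_id", self.subject_id)
        return df


def _tile_rng(scene: SceneSpec, subject: SubjectSpec, tile_index: int):
    """Disjoint substream keyed by (seed, subject_id, tile_index)."""
    return np.random.default_rng(
        np.random.SeedSequence((scene.seed, int(subject.subject_id), tile_index))
    )


def _draw_radius_px(rng, scene: SceneSpec) -> float:
    r_um = float(rng.lognormal(scene.radius_log_mean, scene.radius_log_sd))
    r_um = min(max(r_um, 4.8), 10.5)  # keep singlet areas inside the class window
    return r_um / scene.um_per_px


def _place_centers(rng, scene: SceneSpec, radii: np.ndarray) -> np.ndarray:
    """Rejection-sample centers so footprints keep a minimum clearance."""
    n = len(radii)
    centers = np.empty((n, 2))
    placed = 0
    for i in range(n):
        for _ in range(300):
            c = rng.uniform(0, scene.tile_px, size=2)
            if placed == 0:
                break
            d = np.hypot(*(centers[:placed] - c).T)
            if np.all(d > radii[:placed] + radii[i] + _MIN_GAP_PX):
                break
        else:
            centers[i] = np.nan
            continue
        centers[i] = c
        placed = i + 1
    return centers


def _disk_patch(scene, cx, cy, r):
    """Bounding-box coordinate grids and distance field for one disk."""
    pad = int(math.ceil(r + RIM_WIDTH_PX + 2))
    x0, x1 = max(0, int(cx) - pad), min(scene.tile_px, int(cx) + pad + 1)
    y0, y1 = max(0, int(cy) - pad), min(scene.tile_px, int(cy) + pad + 1)
    if x0 >= x1 or y0 >= y1:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - cx, yy - cy)
    return (slice(y0, y1), slice(x0, x1)), d


def _paint_trans(trans, sl, d, r):
    # dark rim occupies [r - RIM_WIDTH, r]; interior slightly dimmer than bg
    cov = np.clip(r + 0.5 - d, 0.0, 1.0)
    val = np.where(d < r - RIM_WIDTH_PX, TRANS_INTERIOR, TRANS_RIM)
    painted = TRANS_BACKGROUND + cov * (val - TRANS_BACKGROUND)
    trans[sl] = np.minimum(trans[sl], painted)


def _paint_fluor(channel, sl, d, r, per_px_mean, rng):
    """Add speckled fluorescence; returns (total painted, pixel count).

    The speckle is renormalized so the integrated (noiseless) intensity
    equals per_px_mean * n_px exactly, where n_px counts pixels with
    coverage >= 0.5.
    """
    cov = np.clip(r + 0.5 - d, 0.0, 1.0)
    if not np.any(cov > 0):
        return 0.0, 0
    n_px = int(np.count_nonzero(cov >= 0.5))
    if n_px == 0:
        return 0.0, 0
    speckle = rng.lognormal(0.0, SPECKLE_SD, size=cov.shape)
    w = cov * speckle
    total = per_px_mean * n_px
    w *= total / w.sum()
    channel[sl] += w
    return total, n_px


def _poisson_const(rng, lam: float, n: int) -> np.ndarray:
    """Exact Poisson(lam) draws for a constant rate via inverse-CDF lookup.

    Much faster than elementwise rejection for the (large, constant-rate)
    background regions of a channel.
    """
    from scipy.stats import poisson as _pois
    k_max = int(lam + 12.0 * math.sqrt(lam) + 20)
    cdf = _pois.cdf(np.arange(k_max + 1), lam)
    return np.searchsorted(cdf, rng.random(n), side="left")


def _apply_noise(field_arr, scene: SceneSpec, rng,
                 baseline: float | None = None) -> np.ndarray:
    """Poisson shot noise (scaled) plus Gaussian read noise, quantized.

    At rates >= 30 photons the Poisson component is approximated by a
    normal with matched mean/variance and fused with the read noise into a
    single draw; low-rate pixels get exact Poisson draws (a fast lookup
    path handles the constant-``baseline`` background).
    """
    ps = scene.photon_scale
    read_sd = scene.noise_read_sd
    out = field_arr
    if ps > 0:
        lam = np.maximum(out, 0.0) * ps
        if float(lam.min()) >= 30.0:
            sd = np.sqrt(lam / ps ** 2 + read_sd ** 2)
            return np.clip(np.rint(rng.normal(lam / ps, sd)), 0,
                           65535).astype(np.uint16)
        shot = np.empty_like(lam)
        if baseline is not None:
            base_lam = max(baseline, 0.0) * ps
            const = lam == base_lam
            shot[const] = _poisson_const(rng, base_lam, int(const.sum()))
            var = ~const
            lv = lam[var]
        else:
            var = np.ones(lam.shape, dtype=bool)
            lv = lam.ravel()
        big = lv >= 30.0
        sv = np.empty_like(lv)
        sv[big] = np.rint(rng.normal(lv[big], np.sqrt(lv[big])))
        sv[~big] = rng.poisson(lv[~big])
        shot[var] = sv.reshape(shot[var].shape)
        out = shot / ps
    if read_sd > 0:
        out = out + rng.normal(0.0, read_sd, size=field_arr.shape)
    return np.clip(np.rint(out), 0, 65535).astype(np.uint16)


def render_tile(scene: SceneSpec, subject: SubjectSpec,
                tile_index: int) -> tuple[Tile, GroundTruth]:
    """Render one three-channel 16-bit tile plus its ground truth."""
    if tile_index < 0:
        raise ValueError("tile_index must be >= 0")
    mean_r_px = math.exp(scene.radius_log_mean + scene.radius_log_sd ** 2 / 2) / scene.um_per_px
    expected_area = scene.cells_per_tile_mean * math.pi * mean_r_px ** 2
    if expected_area > 0.4 * scene.tile_px ** 2:
        raise ValueError(
            "expected object area exceeds 40% of the tile; placement would fail")

    rng = _tile_rng(scene, subject, tile_index)
    size = scene.tile_px

    trans = np.full((size, size), TRANS_BACKGROUND, dtype=float)
    mt = np.zeros((size, size), dtype=float)
    ppix = np.zeros((size, size), dtype=float)
    truth = GroundTruth(subject_id=subject.subject_id, tile_index=tile_index)

    n_obj = int(rng.poisson(scene.cells_per_tile_mean))
    kinds = rng.choice(
        ["singlet", "clump", "debris"],
        size=n_obj,
        p=[1.0 - scene.frac_clump - scene.frac_debris,
           scene.frac_clump, scene.frac_debris],
    ) if n_obj else np.array([], dtype=object)

    base_radii = np.array([
        _draw_radius_px(rng, scene) if k != "debris"
        else rng.uniform(1.2, 3.2) / scene.um_per_px
        for k in kinds
    ])
    # placement clearance uses the full footprint (clumps span a disk ring)
    footprint = np.where(
        kinds == "clump",
        base_radii * _CLUMP_SUBDISK_SCALE * (1.0 + _CLUMP_RING_SCALE),
        base_radii)
    centers = _place_centers(rng, scene, footprint)

    for k, r, fp, (cx, cy) in zip(kinds, base_radii, footprint, centers):
        if not np.isfinite(cx):
            continue  # could not be placed without overlap; skip
        if k == "singlet":
            low = bool(rng.random() < subject.pi_low) or subject.fccp_mode
            log_mu = subject.mt_low_log_mean if low else subject.mt_high_log_mean
            mt_mean = 10.0 ** rng.normal(log_mu, subject.mt_log_sd)
            if subject.fccp_mode:
                mt_mean *= FCCP_ATTENUATION
            ppix_mean = 10.0 ** rng.normal(subject.ppix_log_mean, subject.ppix_log_sd)
            patch = _disk_patch(scene, cx, cy, r)
            if patch is None:
                continue
            sl, d = patch
            _paint_trans(trans, sl, d, r)
            mt_total, n_px = _paint_fluor(mt, sl, d, r, mt_mean, rng)
            ppix_total, _ = _paint_fluor(ppix, sl, d, r, ppix_mean, rng)
            if n_px == 0:
                continue
            truth.objects.append(ObjectTruth(
                centroid_x=cx, centroid_y=cy, radius_px=r, kind="singlet",
                subpop="low" if low else "high",
                mt_mean=mt_mean, mt_total=mt_total,
                ppix_mean=ppix_mean, ppix_total=ppix_total, n_px=n_px,
                touches_border=_is_border(cx, cy, r, size),
            ))
        elif k == "clump":
            # aggregate of 3-4 cell-sized disks on a jittered ring
            n_sub = int(rng.integers(3, 5))
            sub_r = r * _CLUMP_SUBDISK_SCALE
            ring = _CLUMP_RING_SCALE * sub_r
            angle0 = rng.uniform(0, 2 * math.pi)
            mt_total = ppix_total = 0.0
            n_px_total = 0
            for j in range(n_sub):
                ang = angle0 + 2 * math.pi * j / n_sub + rng.normal(0, 0.15)
                scx = cx + ring * math.cos(ang)
                scy = cy + ring * math.sin(ang)
                low = rng.random() < subject.pi_low or subject.fccp_mode
                log_mu = subject.mt_low_log_mean if low else subject.mt_high_log_mean
                m = 10.0 ** rng.normal(log_mu, subject.mt_log_sd)
                if subject.fccp_mode:
                    m *= FCCP_ATTENUATION
                p = 10.0 ** rng.normal(subject.ppix_log_mean, subject.ppix_log_sd)
                patch = _disk_patch(scene, scx, scy, sub_r)
                if patch is None:
                    continue
                sl, d = patch
                _paint_trans(trans, sl, d, sub_r)
                t, n = _paint_fluor(mt, sl, d, sub_r, m, rng)
                tp, _ = _paint_fluor(ppix, sl, d, sub_r, p, rng)
                mt_total += t
                ppix_total += tp
                n_px_total += n
            if n_px_total == 0:
                continue
            truth.objects.append(ObjectTruth(
                centroid_x=cx, centroid_y=cy, radius_px=r, kind="clump",
                subpop=None,
                mt_mean=mt_total / n_px_total, mt_total=mt_total,
                ppix_mean=ppix_total / max(n_px_total, 1), ppix_total=ppix_total,
                n_px=n_px_total,
                touches_border=_is_border(cx, cy, fp, size),
            ))
        else:  # debris: small dark fragment, no fluorescence signal
            patch = _disk_patch(scene, cx, cy, r)
            if patch is None:
                continue
            sl, d = patch
            _paint_trans(trans, sl, d, r)
            truth.objects.append(ObjectTruth(
                centroid_x=cx, centroid_y=cy, radius_px=r, kind="debris",
                subpop=None, mt_mean=0.0, mt_total=0.0,
                ppix_mean=0.0, ppix_total=0.0,
                n_px=int(np.count_nonzero(np.clip(r + 0.5 - d, 0, 1) >= 0.5)),
                touches_border=_is_border(cx, cy, r, size),
            ))

    mt += MT_OFFSET
    ppix += PPIX_OFFSET

    tile = Tile(
        mt=_apply_noise(mt, scene, rng, baseline=MT_OFFSET),
        ppix=_apply_noise(ppix, scene, rng, baseline=PPIX_OFFSET),
        trans=_apply_noise(trans, scene, rng),
        subject_id=subject.subject_id,
        tile_index=tile_index,
        um_per_px=scene.um_per_px,
    )
    return tile, truth


def _is_border(cx: float, cy: float, r: float, size: int) -> bool:
    m = r + _BORDER_GUARD_PX
    return cx < m or cy < m or cx > size - 1 - m or cy > size - 1 - m


def render_subject(scene: SceneSpec,
                   subject: SubjectSpec) -> list[tuple[Tile, GroundTruth]]:
    """Render a subject's full tile set on disjoint RNG substreams."""
    return [render_tile(scene, subject, t) for t in range(subject.n_tiles)]


def generate_cohort(cohort: CohortSpec) -> tuple[list[SubjectSpec], pd.DataFrame]:
    """Draw per-subject specs and the covariate table for a planted cohort.

    TNF_LPS = intercept + beta_tnf * pi_low + noise (floored above 0);
    basal TNF is independent of pi_low; the plaque score is elevated for
    subjects drawn from the high-pi_low mixture component.
    """
    weights = np.array([c[0] for c in cohort.pi_mix])
    if len(cohort.pi_mix) >= 2:
        a = cohort.pi_mix[0][1:]
        b = cohort.pi_mix[1][1:]
        if np.allclose(a, b):
            warnings.warn("degenerate pi_low mixture: components identical",
                          stacklevel=2)

    rng = np.random.default_rng(np.random.SeedSequence((cohort.seed, 0xC0)))
    groups = ([0] * cohort.n_young + [1] * cohort.n_old_healthy
              + [2] * cohort.n_athero)
    imt_mu = {0: 0.61, 1: 0.71, 2: 0.84}
    imt_sd = {0: 0.04, 1: 0.05, 2: 0.06}
    plaque_base = {0: 0.0, 1: 0.6, 2: 2.0}

    subjects: list[SubjectSpec] = []
    rows = []
    for i, g in enumerate(groups):
        comp = int(rng.choice(len(weights), p=weights))
        _, alpha, beta = cohort.pi_mix[comp]
        pi_low = float(rng.beta(alpha, beta))
        high_comp = comp == int(np.argmax([c[1] / (c[1] + c[2])
                                           for c in cohort.pi_mix]))
        imt = max(0.4, float(rng.normal(imt_mu[g], imt_sd[g])))
        plaque_mu = plaque_base[g] + (cohort.plaque_effect if high_comp else 0.0)
        plaque = int(np.clip(round(rng.normal(plaque_mu, 0.6)), 0, 3))
        tnf_basal = max(cohort.tnf_floor,
                        float(rng.normal(cohort.tnf_basal_mean, cohort.tnf_basal_sd)))
        tnf_lps = max(cohort.tnf_floor,
                      cohort.tnf_lps_intercept + cohort.beta_tnf * pi_low
                      + float(rng.normal(0.0, cohort.tnf_noise_sd)))
        subjects.append(SubjectSpec(subject_id=i + 1, group=g, pi_low=pi_low))
        rows.append({
            "patient_id": i + 1, "group": g, "imt": imt,
            "plaque_score": plaque, "tnf_basal": tnf_basal,
            "tnf_lps": tnf_lps, "pi_low_true": pi_low,
            "mix_component": comp,
        })
    return subjects, pd.DataFrame(rows)


def default_subject(subject_id: int = 1, **kwargs) -> SubjectSpec:
    """A subject at documented defaults (27 tiles, pi_low 0.2)."""
    return SubjectSpec(subject_id=subject_id, **kwargs)


def scale_down(subject: SubjectSpec, n_tiles: int) -> SubjectSpec:
    """Copy of ``subject`` with a reduced tile count (desk-scale runs)."""
    return replace(subject, n_tiles=n_tiles)
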