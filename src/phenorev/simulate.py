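"""Synthetic data generators with recorded ground truth.

Three generators emulate the inputs of the downstream analysis stages:

* per-gene differential-expression summary tables for a disease contrast
  and one or more treatment scenarios, where each treatment effect is a
  known multiple alpha of the true disease effect,
* behavioral feature matrices as multivariate-normal group clouds, and
* two-channel fluorescence images with known nuclei and spot truth.

Treatment contrast semantics: the simulated treatment effect is the
lowered-group-versus-disease-group contrast, so alpha = -1 means an
exact return to control expression.  This convention is recorded in the
truth table metadata.
"""
from __future__ import annotations

import dataclasses
from typing import Callable, Dict, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from numpy.random import default_rng
from scipy import ndimage as ndi
from scipy.stats import norm

__all__ = [
    "DESimConfig",
    "BehaviorSimConfig",
    "ImageSimConfig",
    "ImageSim",
    "simulate_de_tables",
    "simulate_behavior",
    "simulate_images",
]

AlphaSpec = Union[float, Callable[[np.random.Generator, int], np.ndarray]]


@dataclasses.dataclass(frozen=True)
class DESimConfig:
    """Configuration of the differential-expression table generator.

    ``alpha_by_scenario`` maps each treatment scenario name to a true
    reversal multiplier: either a single float applied to every
    dysregulated gene or a callable ``(rng, size) -> array`` drawing
    per-gene multipliers.
    """

    n_genes: int
    frac_dysregulated: float
    alpha_by_scenario: Mapping[str, AlphaSpec]
    effect_mean: float = 1.0
    effect_sd: float = 0.5
    se_low: float = 0.05
    se_high: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 <= self.frac_dysregulated <= 1.0:
            raise ValueError("frac_dysregulated must lie in [0, 1]")
        if not self.se_low > 0:
            raise ValueError("se_low must be > 0")
        if self.se_high < self.se_low:
            raise ValueError("se_high must be >= se_low")
        if not self.alpha_by_scenario:
            raise ValueError("alpha_by_scenario must name at least one scenario")


def _observe(rng: np.random.Generator, true_effect: np.ndarray, se: np.ndarray) -> pd.DataFrame:
    est = true_effect + rng.normal(0.0, se)
    pval = 2.0 * norm.sf(np.abs(est / se))
    return est, pval


def simulate_de_tables(cfg: DESimConfig):
    """Generate (disease table, {scenario: treatment table}, truth table).

    Tables carry columns gene_id, log2fc, lfc_se, pvalue.  The truth
    table records the per-gene true disease effect, the dysregulation
    flag, and per scenario the true multiplier and treatment effect
    (multiplier is NaN for non-dysregulated genes, whose true effects
    are zero in every contrast).
    """
    rng = default_rng(cfg.seed)
    n = cfg.n_genes
    gene_ids = np.array([f"g{i:06d}" for i in range(1, n + 1)])
    n_dys = int(round(cfg.frac_dysregulated * n))
    dys_idx = rng.permutation(n)[:n_dys]
    dysregulated = np.zeros(n, dtype=bool)
    dysregulated[dys_idx] = True

    delta = np.zeros(n)
    delta[dys_idx] = rng.normal(cfg.effect_mean, cfg.effect_sd, size=n_dys)

    se_d = rng.uniform(cfg.se_low, cfg.se_high, size=n)
    est_d, p_d = _observe(rng, delta, se_d)
    disease = pd.DataFrame(
        {"gene_id": gene_ids, "log2fc": est_d, "lfc_se": se_d, "pvalue": p_d}
    )

    truth = pd.DataFrame(
        {"gene_id": gene_ids, "dysregulated": dysregulated, "true_log2fc": delta}
    )
    treatment: Dict[str, pd.DataFrame] = {}
    for scenario, alpha_spec in cfg.alpha_by_scenario.items():
        if callable(alpha_spec):
            alpha_dys = np.asarray(alpha_spec(rng, n_dys), dtype=float)
            if alpha_dys.shape != (n_dys,):
                raise ValueError("alpha callable must return one value per dysregulated gene")
        else:
            alpha_dys = np.full(n_dys, float(alpha_spec))
        alpha = np.full(n, np.nan)
        alpha[dys_idx] = alpha_dys
        true_t = np.zeros(n)
        true_t[dys_idx] = alpha_dys * delta[dys_idx]
        se_t = rng.uniform(cfg.se_low, cfg.se_high, size=n)
        est_t, p_t = _observe(rng, true_t, se_t)
        treatment[scenario] = pd.DataFrame(
            {"gene_id": gene_ids, "log2fc": est_t, "lfc_se": se_t, "pvalue": p_t}
        )
        truth[f"alpha_{scenario}"] = alpha
        truth[f"true_log2fc_{scenario}"] = true_t
    truth.attrs["treatment_contrast"] = (
        "lowered-vs-disease; alpha = -1 means exact return to control"
    )
    return disease, treatment, truth


@dataclasses.dataclass(frozen=True)
class BehaviorSimConfig:
    """Gaussian group clouds with an equicorrelated feature covariance.

    ``mean_shift`` maps each group label to either a scalar offset
    applied to every feature or a length-``n_features`` vector, in
    standardized (unit-variance) units.
    """

    groups: Sequence[Tuple[str, int]]
    n_features: int
    mean_shift: Mapping[str, Union[float, Sequence[float]]]
    feature_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        for label, n in self.groups:
            if n < 3:
                raise ValueError(f"group {label!r} needs >= 3 subjects")
        if not 0.0 <= self.feature_correlation < 1.0:
            raise ValueError(
                "feature_correlation must lie in [0, 1) for a positive definite covariance"
            )


def simulate_behavior(cfg: BehaviorSimConfig) -> pd.DataFrame:
    """Subjects x features DataFrame with a leading ``group`` column."""
    rng = default_rng(cfg.seed)
    p = cfg.n_features
    rho = cfg.feature_correlation
    cov = np.full((p, p), rho) + (1.0 - rho) * np.eye(p)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by config
        raise ValueError("feature covariance is not positive definite") from exc
    frames = []
    for label, n in cfg.groups:
        shift = np.asarray(cfg.mean_shift.get(label, 0.0), dtype=float)
        shift = np.broadcast_to(shift, (p,))
        Z = rng.standard_normal((n, p)) @ L.T + shift
        df = pd.DataFrame(Z, columns=[f"f{j + 1}" for j in range(p)])
        df.insert(0, "group", label)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@dataclasses.dataclass(frozen=True)
class ImageSimConfig:
    """Two-channel image generator with nuclei and spot ground truth.

    ``nuclear_spot_rate`` is the expected number of spots per nucleus;
    ``extranuclear_spot_rate`` is the expected number of spots per mm^2
    of non-nuclear area.
    """

    image_shape: Tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.32
    n_nuclei: int = 10
    nuclear_spot_rate: float = 1.0
    extranuclear_spot_rate: float = 0.0
    spot_sigma_px: float = 2.0
    min_spot_separation_px: float = 12.0
    background_level: float = 0.05
    noise_sd: float = 0.01
    nucleus_radius_px: float = 12.0
    nucleus_radius_jitter: float = 0.15
    nucleus_amplitude: float = 0.5
    spot_amplitude: float = 0.6
    photon_scale: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.nuclear_spot_rate < 0 or self.extranuclear_spot_rate < 0:
            raise ValueError("spot rates must be >= 0")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if not self.spot_sigma_px > 0:
            raise ValueError("spot_sigma_px must be > 0")


@dataclasses.dataclass(frozen=True)
class ImageSim:
    dapi: np.ndarray
    spot_channel: np.ndarray
    nuclei_mask: np.ndarray
    spot_truth: pd.DataFrame
    pixel_size_um: float


def _place_nuclei(rng, shape, n, radius, jitter, max_tries=2000):
    h, w = shape
    centers = []
    radii = []
    tries = 0
    margin = radius * (1 + jitter) + 2
    while len(centers) < n:
        tries += 1
        if tries > max_tries * max(n, 1):
            raise ValueError(
                f"could not place {n} non-overlapping nuclei in a {h}x{w} image"
            )
        r = radius * (1.0 + jitter * rng.uniform(-1.0, 1.0))
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        ok = all(
            (cy - oy) ** 2 + (cx - ox) ** 2 > (r + orad + 2) ** 2
            for (oy, ox), orad in zip(centers, radii)
        )
        if ok:
            centers.append((cy, cx))
            radii.append(r)
    return centers, radii


def _render_gaussian(img, cy, cx, amplitude, sigma):
    h, w = img.shape
    half = int(np.ceil(4 * sigma))
    r0, r1 = max(int(cy) - half, 0), min(int(cy) + half + 1, h)
    c0, c1 = max(int(cx) - half, 0), min(int(cx) + half + 1, w)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    img[r0:r1, c0:c1] += amplitude * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)
    )


def simulate_images(cfg: ImageSimConfig) -> ImageSim:
    """Render nuclei (nuclear channel) and aggregate spots (spot channel)
    with Poisson-Gaussian noise; returns float images in [0, ~1], the
    true nuclei label mask, and the spot truth table (row, col,
    is_nuclear)."""
    rng = default_rng(cfg.seed)
    h, w = cfg.image_shape
    centers, radii = _place_nuclei(
        rng, (h, w), cfg.n_nuclei, cfg.nucleus_radius_px, cfg.nucleus_radius_jitter
    )
    yy, xx = np.mgrid[0:h, 0:w]
    nuclei_mask = np.zeros((h, w), dtype=np.int32)
    dapi = np.full((h, w), cfg.background_level)
    for i, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        nuclei_mask[inside] = i
        dapi[inside] += cfg.nucleus_amplitude
    dapi = ndi.gaussian_filter(dapi, sigma=1.0)

    spot_channel = np.full((h, w), cfg.background_level)
    truth_rows = []

    def far_enough(sy, sx):
        return all(
            (sy - oy) ** 2 + (sx - ox) ** 2 >= cfg.min_spot_separation_px**2
            for oy, ox in truth_rows
        )

    for (cy, cx), r in zip(centers, radii):
        for _ in range(rng.poisson(cfg.nuclear_spot_rate)):
            # spots that cannot be placed with the required separation
            # are dropped, keeping the recorded truth unambiguous
            for _ in range(50):
                rad = max(r - 2.0 * cfg.spot_sigma_px, 0.0) * np.sqrt(rng.uniform())
                theta = rng.uniform(0, 2 * np.pi)
                sy, sx = cy + rad * np.sin(theta), cx + rad * np.cos(theta)
                if far_enough(sy, sx):
                    truth_rows.append((sy, sx))
                    break
    outside_px = int((nuclei_mask == 0).sum())
    area_mm2 = outside_px * (cfg.pixel_size_um * 1e-3) ** 2
    n_ext = rng.poisson(cfg.extranuclear_spot_rate * area_mm2)
    if n_ext > 0:
        free = np.argwhere(nuclei_mask == 0)
        for _ in range(n_ext):
            for _ in range(50):
                sy, sx = free[rng.integers(0, free.shape[0])] + rng.uniform(-0.5, 0.5, 2)
                if far_enough(sy, sx):
                    truth_rows.append((float(sy), float(sx)))
                    break
    for sy, sx in truth_rows:
        _render_gaussian(spot_channel, sy, sx, cfg.spot_amplitude, cfg.spot_sigma_px)

    def add_noise(img):
        noisy = rng.poisson(np.clip(img, 0, None) * cfg.photon_scale) / cfg.photon_scale
        noisy = noisy + rng.normal(0.0, cfg.noise_sd, size=img.shape)
        return np.clip(noisy, 0.0, None)

    dapi = add_noise(dapi)
    spot_channel = add_noise(spot_channel)

    is_nuclear = [
        bool(
            nuclei_mask[
                int(np.clip(round(sy), 0, h - 1)), int(np.clip(round(sx), 0, w - 1))
            ]
            > 0
        )
        for sy, sx in truth_rows
    ]
    spot_truth = pd.DataFrame(
        {
            "row": [sy for sy, _ in truth_rows],
            "col": [sx for _, sx in truth_rows],
            "is_nuclear": is_nuclear,
        }
    )
    return ImageSim(
        dapi=dapi,
        spot_channel=spot_channel,
        nuclei_mask=nuclei_mask,
        spot_truth=spot_truth,
        pixel_size_um=cfg.pixel_size_um,
    )
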