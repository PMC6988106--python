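"""Synthetic LGE-MRI phantoms of the left atrium.

Each phantom is a closed LA-like cavity (a sphere with a smooth low-order
spherical-harmonic radial deformation), a thin enhancing wall carrying one or
more bright scar patches, nearby enhanced confounding structures (an
aorta-like tube and an RA-wall-like shell segment), a smooth intensity bias
field, optional acquisition blur, and Gaussian or Rician noise.  Alongside
the ground-truth label volumes, an imperfect "automatic" LA segmentation is
produced by displacing the cavity boundary with a smooth random field — the
stand-in for the few-mm errors of a real whole-heart segmentation pipeline.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.special import sph_harm_y

from .volume import ImageVolume, save_mask

__all__ = [
    "Confounder",
    "PhantomConfig",
    "PhantomTruth",
    "make_phantom",
    "perturb_segmentation",
    "default_confounders",
]


@dataclass
class Confounder:
    """A bright structure near the LA wall that mimics aorta / RA wall.

    ``kind`` is ``"tube"`` (infinite cylinder, aorta analogue) or ``"shell"``
    (partial spherical shell, right-atrial-wall analogue).  ``direction`` is
    the placement direction from the cavity centre; ``gap_mm`` the clearance
    between the epicardial surface and the structure.
    """

    kind: str = "tube"
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    gap_mm: float = 2.0
    radius_mm: float = 4.0
    thickness_mm: float = 2.0  # shells only
    intensity: float | None = None  # None -> scar mean


def default_confounders() -> list[Confounder]:
    return [
        Confounder(kind="tube", direction=(1.0, 0.0, 0.0), gap_mm=0.5, radius_mm=4.0),
        Confounder(kind="shell", direction=(0.0, -1.0, 0.0), gap_mm=0.5,
                   radius_mm=20.0, thickness_mm=2.0),
    ]


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    cavity_radius_mm: float = 18.0
    cavity_irregularity: float = 0.08
    wall_thickness_mm: float = 2.0
    n_scar_patches: int = 3
    scar_area_fraction: float = 0.25
    # (blood pool, normal wall, scar, confounder) mean intensities
    intensity_means: tuple[float, float, float, float] = (100.0, 60.0, 160.0, 160.0)
    intensity_background: float = 10.0
    # SD of per-patch scar enhancement around the scar mean; real scar
    # enhancement is heterogeneous, which is what defeats global thresholds
    scar_heterogeneity: float = 25.0
    noise_sigma: float = 5.0
    noise_model: str = "gaussian"  # or "rician"
    bias_amplitude: float = 0.0    # additive bias, fraction of the wall mean
    psf_fwhm_mm: float = 0.0       # acquisition blur; 0 disables
    confounders: list[Confounder] = field(default_factory=default_confounders)
    seg_error_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wall_thickness_mm <= 0:
            raise ValueError("wall_thickness_mm must be positive")
        if not (0 <= self.scar_area_fraction < 1):
            raise ValueError("scar_area_fraction must be in [0, 1)")
        if self.seg_error_mm < 0:
            raise ValueError("seg_error_mm must be non-negative")
        if self.intensity_means[2] <= self.intensity_means[1]:
            raise ValueError("scar mean must exceed wall mean (scars are enhanced)")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass
class PhantomTruth:
    """A phantom image with its ground-truth and perturbed segmentations."""

    image: ImageVolume
    la_seg: np.ndarray
    wall_seg: np.ndarray
    scar_seg: np.ndarray
    la_seg_auto: np.ndarray
    config: PhantomConfig

    def save(self, out_dir: str, case: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.image.save(os.path.join(out_dir, f"{case}_image.nii.gz"))
        for name, mask in [("la", self.la_seg), ("wall", self.wall_seg),
                           ("scar", self.scar_seg), ("la_auto", self.la_seg_auto)]:
            save_mask(mask, self.image, os.path.join(out_dir, f"{case}_{name}.nii.gz"))


def _real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real spherical harmonic (theta = polar angle, phi = azimuth)."""
    y = sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return np.sqrt(2.0) * (-1) ** m * y.real
    if m < 0:
        return np.sqrt(2.0) * (-1) ** m * y.imag
    return y.real


def _smooth_direction_field(theta, phi, rng, max_band: int = 4) -> np.ndarray:
    """Band-limited random function of direction, normalized to max |f| = 1."""
    f = np.zeros_like(theta)
    for l in range(1, max_band + 1):
        for m in range(-l, l + 1):
            f += rng.normal(0.0, 1.0 / (2 * l + 1)) * _real_sph_harm(l, m, theta, phi)
    peak = np.max(np.abs(f))
    return f / peak if peak > 0 else f


def _world_grids(cfg: PhantomConfig):
    shape = cfg.grid_shape
    sp = np.asarray(cfg.spacing_mm, dtype=float)
    center = (np.asarray(shape) - 1) / 2.0 * sp
    ax = [(np.arange(shape[i]) * sp[i] - center[i]) for i in range(3)]
    x = ax[0][:, None, None]
    y = ax[1][None, :, None]
    z = ax[2][None, None, :]
    return x, y, z, center


def _confounder_mask(conf: Confounder, cfg: PhantomConfig, x, y, z) -> np.ndarray:
    u = np.asarray(conf.direction, dtype=float)
    u = u / np.linalg.norm(u)
    reach = cfg.cavity_radius_mm * (1 + cfg.cavity_irregularity) + cfg.wall_thickness_mm
    if conf.kind == "tube":
        p = u * (reach + conf.gap_mm + conf.radius_mm)
        # axis direction: any vector orthogonal to the placement direction
        a = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(a) < 1e-6:
            a = np.cross(u, [0.0, 1.0, 0.0])
        a = a / np.linalg.norm(a)
        dx, dy, dz = x - p[0], y - p[1], z - p[2]
        along = dx * a[0] + dy * a[1] + dz * a[2]
        d2 = dx**2 + dy**2 + dz**2 - along**2
        return d2 < conf.radius_mm**2
    if conf.kind == "shell":
        c2 = u * (reach + conf.gap_mm + conf.radius_mm)
        dx, dy, dz = x - c2[0], y - c2[1], z - c2[2]
        r = np.sqrt(dx**2 + dy**2 + dz**2)
        on_shell = np.abs(r - conf.radius_mm) < conf.thickness_mm / 2.0
        # keep only the cap of the shell facing the LA
        with np.errstate(invalid="ignore", divide="ignore"):
            facing = -(dx * u[0] + dy * u[1] + dz * u[2]) / np.maximum(r, 1e-9) > 0.5
        return on_shell & facing
    raise ValueError(f"unknown confounder kind {conf.kind!r}")


def make_phantom(config: PhantomConfig) -> PhantomTruth:
    """Generate one phantom; deterministic for a given ``config.seed``."""
    cfg = config
    shape = tuple(cfg.grid_shape)
    sp = np.asarray(cfg.spacing_mm, dtype=float)
    rng = np.random.default_rng(cfg.seed)

    half_extent = (np.asarray(shape) - 1) / 2.0 * sp
    reach = cfg.cavity_radius_mm * (1 + cfg.cavity_irregularity) + cfg.wall_thickness_mm
    if np.any(reach + 2 * sp > half_extent):
        raise ValueError(
            f"cavity (max extent {reach:.1f} mm + margin) does not fit in the "
            f"grid (half extents {half_extent} mm)")

    x, y, z, _ = _world_grids(cfg)
    rho = np.sqrt(x**2 + y**2 + z**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(rho > 0, z / np.maximum(rho, 1e-12), 1.0), -1, 1))
        phi = np.arctan2(y, x) * np.ones_like(rho)

    if cfg.cavity_irregularity > 0:
        s_field = _smooth_direction_field(theta, phi, rng)
    else:
        _ = rng.normal(size=24)  # keep the RNG stream layout stable
        s_field = np.zeros_like(rho)
    r_dir = cfg.cavity_radius_mm * (1.0 + cfg.cavity_irregularity * s_field)

    la_seg = rho < r_dir
    wall_seg = (rho >= r_dir) & (rho < r_dir + cfg.wall_thickness_mm)

    # scar patches: angular caps around random seed directions, with the cap
    # radius chosen by quantile so the realized wall fraction hits the target
    scar_seg = np.zeros(shape, dtype=bool)
    scar_patch_id = np.zeros(shape, dtype=np.int32)  # 0 = no scar, else patch index
    if cfg.n_scar_patches > 0 and cfg.scar_area_fraction > 0:
        seeds = rng.normal(size=(cfg.n_scar_patches, 3))
        seeds /= np.linalg.norm(seeds, axis=1, keepdims=True)
        wall_idx = np.nonzero(wall_seg)
        ux = x[:, 0, 0][wall_idx[0]]
        uy = y[0, :, 0][wall_idx[1]]
        uz = z[0, 0, :][wall_idx[2]]
        norms = np.sqrt(ux**2 + uy**2 + uz**2)
        dirs = np.stack([ux, uy, uz], axis=1) / norms[:, None]
        all_ang = np.arccos(np.clip(dirs @ seeds.T, -1, 1))
        ang = all_ang.min(axis=1)
        alpha = np.quantile(ang, cfg.scar_area_fraction)
        sel = ang <= alpha
        scar_seg[wall_idx[0][sel], wall_idx[1][sel], wall_idx[2][sel]] = True
        scar_patch_id[wall_idx[0][sel], wall_idx[1][sel], wall_idx[2][sel]] = \
            1 + all_ang.argmin(axis=1)[sel]

    blood_mu, wall_mu, scar_mu, conf_mu = cfg.intensity_means
    image = np.full(shape, float(cfg.intensity_background))
    image[la_seg] = blood_mu
    image[wall_seg] = wall_mu
    # heterogeneous enhancement: each scar patch has its own mean, never
    # dimmer than a third of the nominal scar-wall contrast above the wall
    patch_mu = scar_mu + cfg.scar_heterogeneity * rng.normal(size=max(cfg.n_scar_patches, 1))
    patch_mu = np.maximum(patch_mu, wall_mu + 0.3 * (scar_mu - wall_mu))
    for k in range(cfg.n_scar_patches):
        image[scar_patch_id == k + 1] = patch_mu[k]
    interior = la_seg | wall_seg
    for conf in cfg.confounders:
        mask = _confounder_mask(conf, cfg, x, y, z) & ~interior
        image[mask] = conf_mu if conf.intensity is None else conf.intensity

    if cfg.bias_amplitude > 0:
        g = rng.normal(size=shape)
        g = ndimage.gaussian_filter(g, sigma=np.asarray(shape) / 6.0)
        g -= g.mean()
        peak = np.max(np.abs(g))
        if peak > 0:
            image = image + cfg.bias_amplitude * wall_mu * g / peak
    else:
        _ = rng.normal()  # keep stream layout stable

    if cfg.psf_fwhm_mm > 0:
        sigma_vox = (cfg.psf_fwhm_mm / 2.355) / sp
        image = ndimage.gaussian_filter(image, sigma=sigma_vox)

    if cfg.noise_sigma > 0:
        if cfg.noise_model == "gaussian":
            image = image + rng.normal(0.0, cfg.noise_sigma, size=shape)
        else:  # Rician: magnitude of a complex signal with Gaussian noise
            n1 = rng.normal(0.0, cfg.noise_sigma, size=shape)
            n2 = rng.normal(0.0, cfg.noise_sigma, size=shape)
            image = np.sqrt((image + n1) ** 2 + n2**2)

    auto_seed = int(rng.integers(0, 2**31 - 1))
    la_seg_auto = perturb_segmentation(la_seg, sp, cfg.seg_error_mm, seed=auto_seed)

    assert not np.any(scar_seg & ~wall_seg), "scar must be a subset of the wall"
    assert not np.any(la_seg & wall_seg), "cavity and wall must be disjoint"
    vol = ImageVolume(image, sp, np.zeros(3))
    return PhantomTruth(vol, la_seg, wall_seg, scar_seg, la_seg_auto, replace(cfg))


def perturb_segmentation(seg: np.ndarray, spacing_mm, seg_error_mm: float,
                         seed: int = 0, smooth_mm: float = 8.0) -> np.ndarray:
    """Displace a binary segmentation's boundary by a smooth random field.

    The signed distance of ``seg`` is thresholded at a Gaussian-filtered
    white-noise field scaled so its maximum magnitude equals ``seg_error_mm``;
    since the signed distance has unit gradient, the boundary moves by at most
    ``seg_error_mm`` along its normal.  The output is kept a single connected
    component with no interior holes.
    """
    seg = np.asarray(seg).astype(bool)
    if not seg.any():
        raise ValueError("cannot perturb an empty segmentation")
    n_comp = ndimage.label(seg)[1]
    if n_comp != 1:
        raise ValueError(f"segmentation must be a single connected component, got {n_comp}")
    if seg_error_mm == 0:
        return seg.copy()
    sp = np.asarray(spacing_mm, dtype=float)
    d_out = ndimage.distance_transform_edt(~seg, sampling=sp)
    d_in = ndimage.distance_transform_edt(seg, sampling=sp)
    sdf = d_out - d_in  # positive outside, negative inside, never exactly 0
    # half-voxel correction: the implied surface sits between voxel centers
    sdf -= 0.5 * sp.min() * np.sign(sdf)

    rng = np.random.default_rng(seed)
    noise = rng.normal(size=seg.shape)
    noise = ndimage.gaussian_filter(noise, sigma=smooth_mm / sp)
    scale = 2.0 * noise.std()  # ~2 sigma reaches the cap; clip guarantees the bound
    if scale > 0:
        delta = np.clip(seg_error_mm * noise / scale, -seg_error_mm, seg_error_mm)
    else:
        delta = np.zeros_like(noise)

    out = sdf < delta
    labels, n = ndimage.label(out)
    if n == 0:
        raise ValueError("perturbation erased the segmentation; reduce seg_error_mm")
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        out = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(out)
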