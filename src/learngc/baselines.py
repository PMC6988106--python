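"""Classical scar-segmentation baselines on a dilation-derived wall mask.

All four methods operate on the voxels of a wall mask built by morphological
dilation of the LA cavity segmentation: fixed thresholding at n SD above the
wall mean, Otsu's automatic threshold, a two-class multi-component Gaussian
mixture (MGMM) fitted by EM, and MGMM followed by a voxel-grid graph-cuts
regularization whose boundary weights decay with the squared intensity
difference of 6-connected neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu as _skimage_otsu

from .graphcut import GraphModel, min_cut

__all__ = ["MGMMModel", "wall_from_la", "threshold_nsd", "threshold_otsu",
           "mgmm_fit", "mgmm_gc"]


def wall_from_la(la_seg: np.ndarray, dilation_mm: float, spacing_mm) -> np.ndarray:
    """Wall mask = dilate(LA, dilation_mm) minus LA."""
    la_seg = np.asarray(la_seg).astype(bool)
    if not la_seg.any():
        raise ValueError("empty LA segmentation")
    sp = np.asarray(spacing_mm, dtype=float)
    dist = ndimage.distance_transform_edt(~la_seg, sampling=sp)
    wall = (dist > 0) & (dist <= dilation_mm)
    if not wall.any():
        raise ValueError(f"dilation of {dilation_mm} mm produced an empty wall mask")
    return wall


def threshold_nsd(image: np.ndarray, wall_mask: np.ndarray, n_sd: float = 2.0
                  ) -> np.ndarray:
    """Scar = wall voxels strictly above mean + n_sd * SD of wall intensity.

    Population SD (divide by n); strict inequality, so a constant wall yields
    an empty scar mask.
    """
    wall_mask = np.asarray(wall_mask).astype(bool)
    vals = np.asarray(image, dtype=float)[wall_mask]
    if vals.size == 0:
        raise ValueError("empty wall mask")
    if vals.size < 2:
        raise ValueError("wall mask must contain at least two voxels")
    thr = vals.mean() + n_sd * vals.std()
    scar = np.zeros_like(wall_mask)
    scar[wall_mask] = np.asarray(image, dtype=float)[wall_mask] > thr
    return scar


def threshold_otsu(image: np.ndarray, wall_mask: np.ndarray) -> np.ndarray:
    """Scar = wall voxels above the Otsu threshold (256-bin histogram)."""
    wall_mask = np.asarray(wall_mask).astype(bool)
    vals = np.asarray(image, dtype=float)[wall_mask]
    if vals.size == 0:
        raise ValueError("empty wall mask")
    if np.unique(vals).size < 2:
        raise ValueError("wall intensities are constant; Otsu is undefined")
    thr = _skimage_otsu(vals, nbins=256)
    scar = np.zeros_like(wall_mask)
    scar[wall_mask] = np.asarray(image, dtype=float)[wall_mask] > thr
    return scar


@dataclass
class MGMMModel:
    """Two-class (normal wall / scar) mixture, several components per class."""

    means: np.ndarray        # (K,) component means, scar components last
    variances: np.ndarray    # (K,)
    weights: np.ndarray      # (K,) mixing weights, sum to 1
    k_normal: int
    k_scar: int
    log_likelihoods: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def scar_components(self) -> slice:
        return slice(self.k_normal, self.k_normal + self.k_scar)

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)[:, None]
        log_pdf = (-0.5 * np.log(2 * np.pi * self.variances)
                   - (x - self.means) ** 2 / (2 * self.variances))
        log_w = np.log(self.weights) + log_pdf
        log_w -= log_w.max(axis=1, keepdims=True)
        r = np.exp(log_w)
        return r / r.sum(axis=1, keepdims=True)

    def scar_posterior(self, x: np.ndarray) -> np.ndarray:
        """P(scar | intensity): summed responsibility of the scar components."""
        return self.responsibilities(x)[:, self.scar_components].sum(axis=1)


def _log_likelihood(x, means, variances, weights) -> float:
    log_pdf = (-0.5 * np.log(2 * np.pi * variances)
               - (x[:, None] - means) ** 2 / (2 * variances))
    a = np.log(weights) + log_pdf
    amax = a.max(axis=1, keepdims=True)
    return float((amax[:, 0] + np.log(np.exp(a - amax).sum(axis=1))).sum())


def mgmm_fit(intensities: np.ndarray, k_scar: int = 2, k_normal: int = 3,
             tol: float = 1e-6, max_iter: int = 500, seed: int = 0) -> MGMMModel:
    """EM fit of the two-class multi-component mixture to 1D intensities.

    Components are initialized from intensity quantiles — normal-wall
    components on the lower range, scar components on the enhanced upper
    range (scar is bright in LGE).  Log-likelihood is recorded per iteration
    and is non-decreasing; if the gain stays above ``tol`` after ``max_iter``
    iterations the best fit is returned with ``converged = False``.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    k = k_scar + k_normal
    if x.size <= k:
        raise ValueError("need more samples than mixture components")
    rng = np.random.default_rng(seed)
    q_normal = np.linspace(0.1, 0.6, k_normal)
    q_scar = np.linspace(0.85, 0.98, k_scar)
    means = np.quantile(x, np.r_[q_normal, q_scar])
    means = means + rng.normal(0, 1e-3 * (x.std() + 1e-12), size=k)  # break ties
    variances = np.full(k, x.var() / k + 1e-12)
    weights = np.full(k, 1.0 / k)
    var_floor = max(1e-10, 1e-6 * x.var())

    lls: list[float] = []
    converged = False
    for _ in range(max_iter):
        lls.append(_log_likelihood(x, means, variances, weights))
        log_pdf = (-0.5 * np.log(2 * np.pi * variances)
                   - (x[:, None] - means) ** 2 / (2 * variances))
        a = np.log(weights) + log_pdf
        a -= a.max(axis=1, keepdims=True)
        r = np.exp(a)
        r /= r.sum(axis=1, keepdims=True)
        nk = r.sum(axis=0) + 1e-12
        means = (r * x[:, None]).sum(axis=0) / nk
        variances = (r * (x[:, None] - means) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, var_floor)
        weights = nk / x.size
        if len(lls) > 1 and lls[-1] - lls[-2] < tol:
            converged = True
            break
    if not converged:
        import warnings
        warnings.warn("MGMM EM did not converge; returning the best fit so far")
    return MGMMModel(means, variances, weights, k_normal, k_scar, lls, converged)


def _wall_voxel_edges(wall_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Node ids and 6-connected edge list over the wall voxels."""
    ids = -np.ones(wall_mask.shape, dtype=int)
    coords = np.argwhere(wall_mask)
    ids[tuple(coords.T)] = np.arange(len(coords))
    edges = []
    for ax in range(3):
        a = ids[tuple(slice(0, -1) if d == ax else slice(None) for d in range(3))]
        b = ids[tuple(slice(1, None) if d == ax else slice(None) for d in range(3))]
        ok = (a >= 0) & (b >= 0)
        edges.append(np.stack([a[ok], b[ok]], axis=1))
    return coords, np.concatenate(edges) if edges else np.zeros((0, 2), int)


def mgmm_gc(image: np.ndarray, wall_mask: np.ndarray, model: MGMMModel,
            lam: float = 0.5, sigma_intensity: float | None = None) -> np.ndarray:
    """Graph-cuts regularization of the MGMM posterior on the wall voxels.

    t-links come from the class posteriors (assigning scar costs the normal
    posterior and vice versa); n-links on the 6-connected voxel grid are
    ``exp(-(I_i - I_j)^2 / (2 sigma^2))`` with ``sigma`` defaulting to the SD
    of the wall intensities.  The cut is exact, and ``lam`` = 0 reduces to
    posterior argmax.
    """
    wall_mask = np.asarray(wall_mask).astype(bool)
    img = np.asarray(image, dtype=float)
    vals = img[wall_mask]
    if vals.size == 0:
        raise ValueError("empty wall mask")
    if sigma_intensity is None:
        sigma_intensity = float(vals.std()) or 1.0
    p_scar = np.clip(model.scar_posterior(vals), 0.0, 1.0)
    coords, edges = _wall_voxel_edges(wall_mask)
    ivals = img[tuple(coords.T)]
    if len(edges):
        di = ivals[edges[:, 0]] - ivals[edges[:, 1]]
        w = np.exp(-di**2 / (2 * sigma_intensity**2))
    else:
        w = np.zeros(0)
    graph = GraphModel(len(coords), edges, cost_normal=p_scar,
                       cost_scar=1.0 - p_scar, edge_weights=w, lam=lam)
    if lam == 0:
        labeling = (p_scar > 0.5).astype(int)
    else:
        labeling = min_cut(graph)
    scar = np.zeros_like(wall_mask)
    scar[tuple(coords[labeling == 1].T)] = True
    return scar
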