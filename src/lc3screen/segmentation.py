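"""Nuclei tracing and subcellular object detection.

Nuclei are traced by mixture-of-Gaussians (MoG) thresholding: a
two-component Gaussian mixture is fitted to the log-transformed pixel
intensities by EM with a deterministic percentile initialization, and the
foreground threshold is the intensity where the posterior responsibility of
the brighter component reaches one half.  The cytoplasmic compartment is a
ring obtained by dilating each nuclear mask by a set radius; nuclear holes
are connected regions of low DNA intensity fully interior to a nucleus; LC3
puncta are white-top-hat maxima thresholded per cell.

All operations are deterministic functions of their inputs: the EM
initialization is fixed (percentile split), connected components use
8-connectivity, and labels follow raster-scan order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .errors import DegenerateInputError, DesignError

logger = logging.getLogger(__name__)

_LOG_EPS = 1.0  # offset before log-transform so zero-valued pixels are usable


@dataclass(frozen=True)
class SegmentationParams:
    """Segmentation thresholds and radii (pixels / fractions).

    ``ring_radius`` is the set dilation radius defining the cytoplasmic
    compartment; ``hole_intensity_fraction`` is the fraction of a nucleus's
    median DNA intensity below which pixels count as hole candidates;
    ``puncta_k_sigma`` is the per-cell mean + k*SD threshold on the white
    top-hat response.  ``exclude_border_nuclei`` optionally removes nuclei
    touching the field edge (kept by default).
    """

    min_nucleus_area: int = 50
    max_nucleus_area: int = 5000
    ring_radius: int = 10
    hole_intensity_fraction: float = 0.5
    hole_min_area: int = 10
    puncta_tophat_radius: int = 3
    puncta_k_sigma: float = 3.0
    puncta_min_area: int = 2
    smoothing_sigma: float = 1.0
    exclude_border_nuclei: bool = False

    def __post_init__(self) -> None:
        if not self.min_nucleus_area < self.max_nucleus_area:
            raise DesignError("min_nucleus_area must be < max_nucleus_area")
        if self.ring_radius < 0:
            raise DesignError("ring_radius must be >= 0")
        if not 0.0 < self.hole_intensity_fraction < 1.0:
            raise DesignError("hole_intensity_fraction must be in (0, 1)")
        for name in ("min_nucleus_area", "hole_min_area", "puncta_min_area"):
            if getattr(self, name) < 1:
                raise DesignError(f"{name} must be >= 1")


@dataclass
class Punctum:
    """One detected LC3 spot, assigned to a cell and a compartment."""

    center: tuple[int, int]
    area: int
    integrated_intensity: float
    compartment: str  # "nuclear" | "cytoplasmic"
    owner_cell: int


@dataclass
class MogFit:
    """Diagnostics of the two-component mixture threshold."""

    threshold: float
    means: tuple[float, float]  # log-space, (dim, bright)
    sigmas: tuple[float, float]
    weights: tuple[float, float]
    n_iter: int
    converged: bool
    used_fallback: bool


# ---------------------------------------------------------------------------
# Mixture-of-Gaussians threshold
# ---------------------------------------------------------------------------

def _otsu_threshold(x: np.ndarray) -> float:
    """Between-class-variance-maximizing threshold (EM fallback)."""
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(x))


def mog_threshold(
    sample: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-6,
    return_fit: bool = False,
    init_percentiles: tuple[float, float] = (25.0, 90.0),
) -> float | MogFit:
    """Foreground/background threshold from a two-component Gaussian mixture.

    The mixture is fitted to log-transformed intensities by EM with a shared
    (tied) variance.  Means are initialized at the sample's 25th and 90th
    log-percentiles, the variance at the sample variance and the weights at
    0.5 each, making the fit a deterministic function of the sample.  Tying
    the variances keeps the fit well-posed on near-noiseless images, where a
    free-variance component collapses onto the constant background and drags
    the threshold to the background mode; with tied variances the
    posterior-0.5 crossing always lies between the two component means and
    has the closed form (m0+m1)/2 + v*ln(w0/w1)/(m1-m0).  The returned
    threshold is the intensity at which the posterior responsibility of the
    brighter component reaches 0.5.  If EM fails to converge within
    ``max_iter`` iterations the between-class variance criterion (Otsu) is
    used instead and the fallback is flagged.
    """
    sample = np.asarray(sample, dtype=float).ravel()
    if sample.size < 2 or np.unique(sample).size < 2:
        raise DegenerateInputError(
            "intensity sample is constant; no foreground/background structure to fit"
        )
    x = np.log(sample + _LOG_EPS)

    lo, hi = np.percentile(x, init_percentiles)
    if hi - lo < 1e-12:
        # distinct values but percentile collapse: spread the inits
        lo, hi = float(x.min()), float(x.max())
    mu = np.array([lo, hi])
    var = max(float(x.var()), 1e-8)
    w = np.array([0.5, 0.5])

    prev_ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step in log-space (shared variance)
        log_pdf = (
            -0.5 * math.log(2.0 * math.pi * var)
            - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var
            + np.log(w)[None, :]
        )
        m = log_pdf.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_pdf - m).sum(axis=1))
        resp = np.exp(log_pdf - lse[:, None])
        ll = float(lse.sum())
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / x.size
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = float((resp * (x[:, None] - mu[None, :]) ** 2).sum() / x.size)
        var = max(var, 1e-8)
        if abs(ll - prev_ll) < tol * max(1.0, abs(prev_ll)):
            converged = True
            break
        prev_ll = ll

    used_fallback = False
    order = np.argsort(mu)
    mu, w = mu[order], w[order]
    if not converged or abs(mu[1] - mu[0]) < 1e-9:
        used_fallback = True
        thr = _otsu_threshold(sample)
        logger.warning(
            "MoG EM did not converge after %d iterations; using between-class "
            "variance fallback threshold %.3f",
            max_iter,
            thr,
        )
    else:
        log_thr = 0.5 * (mu[0] + mu[1]) + var * math.log(w[0] / w[1]) / (mu[1] - mu[0])
        log_thr = float(np.clip(log_thr, mu[0], mu[1]))
        thr = float(np.exp(log_thr) - _LOG_EPS)

    sigma = float(np.sqrt(var))
    fit = MogFit(
        threshold=thr,
        means=(float(mu[0]), float(mu[1])),
        sigmas=(sigma, sigma),
        weights=(float(w[0]), float(w[1])),
        n_iter=n_iter,
        converged=converged,
        used_fallback=used_fallback,
    )
    return fit if return_fit else fit.threshold


# ---------------------------------------------------------------------------
# Nuclei
# ---------------------------------------------------------------------------

def _raster_scan_relabel(labels: np.ndarray) -> np.ndarray:
    """Relabel components 1..N in order of first pixel in raster scan."""
    out = np.zeros_like(labels)
    next_id = 1
    seen: dict[int, int] = {}
    flat = labels.ravel()
    order_ids = flat[np.flatnonzero(flat)]
    for lab in order_ids:
        if lab not in seen:
            seen[lab] = next_id
            next_id += 1
    for old, new in seen.items():
        out[labels == old] = new
    return out


def segment_nuclei(
    dna: np.ndarray,
    params: Optional[SegmentationParams] = None,
    sample_stride: int = 1,
) -> np.ndarray:
    """Trace nuclei on the DNA channel; returns a label raster (0 = background).

    The raster is lightly smoothed (Gaussian, sigma from ``params``), the
    MoG threshold is computed on its intensities (optionally subsampled with
    ``sample_stride`` for speed; the threshold remains deterministic),
    foreground components are labeled with 8-connectivity, interior holes are
    filled (nuclear holes are low-DNA regions *within* a nucleus and must
    stay part of its mask), and components outside the
    [min_nucleus_area, max_nucleus_area] band are removed.  A degenerate
    (constant) field yields an empty labeling with a logged warning — a blank
    field is a legitimate outcome.
    """
    p = params or SegmentationParams()
    dna = np.asarray(dna, dtype=float)
    if dna.ndim != 2:
        raise DesignError("dna raster must be 2-D")
    smooth = ndimage.gaussian_filter(dna, sigma=p.smoothing_sigma, mode="nearest")
    sample = smooth[::sample_stride, ::sample_stride].ravel()
    try:
        thr = mog_threshold(sample)
    except DegenerateInputError:
        logger.warning("constant DNA raster; returning empty labeling")
        return np.zeros(dna.shape, dtype=np.int32)
    fg = smooth > thr
    fg = ndimage.binary_fill_holes(fg)
    labels, _ = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if labels.max() == 0:
        return labels.astype(np.int32)
    areas = np.bincount(labels.ravel())
    bad = np.flatnonzero((areas < p.min_nucleus_area) | (areas > p.max_nucleus_area))
    kill = np.isin(labels, bad[bad > 0])
    labels[kill] = 0
    if p.exclude_border_nuclei:
        edge_labels = np.unique(
            np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
        )
        labels[np.isin(labels, edge_labels[edge_labels > 0])] = 0
    return _raster_scan_relabel(labels).astype(np.int32)


# ---------------------------------------------------------------------------
# Cytoplasm rings
# ---------------------------------------------------------------------------

def cytoplasm_rings(nuclei_labels: np.ndarray, ring_radius: int) -> np.ndarray:
    """Cytoplasmic ring masks by dilating each nuclear mask.

    A cell's ring is the disk-dilation of its nucleus by ``ring_radius``
    minus all nuclear pixels; contested pixels go to the nucleus with the
    smallest Euclidean distance, ties to the lower label.  Rings are mutually
    disjoint and disjoint from every nucleus.
    """
    if ring_radius < 0:
        raise DesignError(f"ring_radius must be >= 0, got {ring_radius}")
    nuclei_labels = np.asarray(nuclei_labels)
    rings = np.zeros_like(nuclei_labels, dtype=np.int32)
    if ring_radius == 0 or nuclei_labels.max() == 0:
        return rings
    nuc_any = nuclei_labels > 0
    # distance to nearest nucleus pixel and its label, with exact
    # ties-to-lower-label semantics via per-label distance stack
    ids = np.unique(nuclei_labels)
    ids = ids[ids > 0]
    best_dist = np.full(nuclei_labels.shape, np.inf)
    best_label = np.zeros(nuclei_labels.shape, dtype=np.int32)
    for lab in ids:  # ascending: strict '<' keeps the lower label on ties
        d = ndimage.distance_transform_edt(nuclei_labels != lab)
        closer = d < best_dist
        best_dist[closer] = d[closer]
        best_label[closer] = lab
    in_ring = (~nuc_any) & (best_dist <= ring_radius)
    rings[in_ring] = best_label[in_ring]
    return rings


# ---------------------------------------------------------------------------
# Nuclear holes
# ---------------------------------------------------------------------------

def detect_nuclear_holes(
    dna: np.ndarray,
    nuclei_labels: np.ndarray,
    params: Optional[SegmentationParams] = None,
) -> dict[int, list[dict]]:
    """Detect low-DNA holes inside each nucleus.

    Within a nucleus, a hole is an 8-connected region of pixels whose
    smoothed DNA intensity is below ``hole_intensity_fraction`` times that
    nucleus's median DNA intensity, with area >= ``hole_min_area`` and fully
    interior (no pixel adjacent to the nuclear boundary — boundary-touching
    low regions are indentations, not holes).  Returns
    ``{label: [{"area":..., "mean_intensity":..., "center":...}, ...]}`` with
    an entry for every nucleus label (possibly empty).
    """
    p = params or SegmentationParams()
    dna = np.asarray(dna, dtype=float)
    nuclei_labels = np.asarray(nuclei_labels)
    if dna.shape != nuclei_labels.shape:
        raise DesignError("dna raster and label raster shapes differ")
    smooth = ndimage.gaussian_filter(dna, sigma=p.smoothing_sigma, mode="nearest")
    out: dict[int, list[dict]] = {}
    s8 = np.ones((3, 3), dtype=int)
    for region in measure.regionprops(nuclei_labels):
        lab = region.label
        out[lab] = []
        mask = nuclei_labels == lab
        median = float(np.median(smooth[mask]))
        low = mask & (smooth < p.hole_intensity_fraction * median)
        if not low.any():
            continue
        interior = ndimage.binary_erosion(mask, structure=s8, border_value=0)
        comp, n = ndimage.label(low, structure=s8)
        for ci in range(1, n + 1):
            cmask = comp == ci
            if cmask.sum() < p.hole_min_area:
                continue
            if not np.all(interior[cmask]):
                continue  # touches the nuclear boundary
            ys, xs = np.nonzero(cmask)
            out[lab].append(
                {
                    "area": int(cmask.sum()),
                    "mean_intensity": float(dna[cmask].mean()),
                    "center": (float(ys.mean()), float(xs.mean())),
                }
            )
    return out


# ---------------------------------------------------------------------------
# LC3 puncta
# ---------------------------------------------------------------------------

def detect_puncta(
    lc3: np.ndarray,
    nuclei_labels: np.ndarray,
    ring_labels: np.ndarray,
    params: Optional[SegmentationParams] = None,
) -> list[Punctum]:
    """Detect LC3 puncta per cell and assign compartments.

    The white top-hat (disk radius ``puncta_tophat_radius``) isolates
    structures smaller than the disk.  For each cell, candidate pixels are
    those whose response exceeds mean + k*SD of the response over the cell's
    combined nucleus-plus-ring region; 8-connected candidate components with
    area >= ``puncta_min_area`` become puncta.  A punctum's compartment is
    decided by its center pixel, nuclear mask taking priority over ring;
    components outside any cell region are discarded.
    """
    p = params or SegmentationParams()
    lc3 = np.asarray(lc3, dtype=float)
    nuclei_labels = np.asarray(nuclei_labels)
    ring_labels = np.asarray(ring_labels)
    if not (lc3.shape == nuclei_labels.shape == ring_labels.shape):
        raise DesignError("lc3 raster and mask shapes differ")
    response = morphology.white_tophat(lc3, footprint=morphology.disk(p.puncta_tophat_radius))
    s8 = np.ones((3, 3), dtype=int)
    puncta: list[Punctum] = []
    ids = np.unique(nuclei_labels)
    for lab in ids[ids > 0]:
        cell = (nuclei_labels == lab) | (ring_labels == lab)
        vals = response[cell]
        thr = float(vals.mean() + p.puncta_k_sigma * vals.std())
        cand = cell & (response > thr)
        if not cand.any():
            continue
        comp, n = ndimage.label(cand, structure=s8)
        for ci in range(1, n + 1):
            cmask = comp == ci
            area = int(cmask.sum())
            if area < p.puncta_min_area:
                continue
            ys, xs = np.nonzero(cmask)
            cy, cx = int(round(ys.mean())), int(round(xs.mean()))
            if nuclei_labels[cy, cx] == lab:
                compartment = "nuclear"
            elif ring_labels[cy, cx] == lab:
                compartment = "cytoplasmic"
            else:
                continue  # center outside this cell's compartments
            puncta.append(
                Punctum(
                    center=(cy, cx),
                    area=area,
                    integrated_intensity=float(lc3[cmask].sum()),
                    compartment=compartment,
                    owner_cell=int(lab),
                )
            )
    return puncta
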