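"""Vascular metrics from en face OCT angiograms.

Implements the quantification recipe used in OCTA case-control studies of the
retinal microvasculature:

* **VD** (vessel density): percent of ROI pixels classified as vessel after
  binarization — Phansalkar local thresholding (15×15 px window) on disc
  scans, a noise threshold derived from the foveal avascular zone (FAZ)
  background on macular scans.
* **Microcapillary VD**: VD after removing the large arterioles/venules via a
  mask built from a contrast-stretched, Shanbhag-thresholded image with small
  connected components removed.
* **VLD** (vessel length density): percent of ROI pixels on the 1-pixel-wide
  vessel skeleton; calibre-independent.
* **AFI** (adjusted flow index): mean decorrelation value of supra-threshold
  (vessel) pixels in the ROI — a surrogate of flow velocity.
* **FAZ area** in mm².

All thresholds are strict (``value > t`` is foreground; ties go to
background).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

from .io_roi import AnnularROI, EnFaceAngiogram, ScaleInfo, make_annulus

logger = logging.getLogger(__name__)

#: parafoveal ring diameters (mm) centred on the fovea
PARAFOVEA_MM = (1.0, 3.0)
#: peripapillary "donut" diameters (mm) centred on the optic nerve head
PERIPAPILLARY_MM = (2.0, 4.0)

#: device image-quality gates: minimum SQ, and minimum SSI per scan type
MIN_SQ = 6
MIN_SSI = {"macula": 50, "disc": 45}


@dataclass
class BinaryVesselMap:
    """Binary perfusion map: True = vessel (above threshold)."""

    mask: np.ndarray
    provenance: str  # {phansalkar, shanbhag, faz_background}
    threshold_params: dict = field(default_factory=dict)


@dataclass
class LargeVesselMask:
    """Mask of the major vasculature (small components removed)."""

    mask: np.ndarray
    min_component_px: int
    min_component_area_um2: float


@dataclass
class SkeletonMap:
    """1-pixel-wide, 8-connected vessel centrelines."""

    mask: np.ndarray


@dataclass
class FazRegion:
    """Delineated foveal avascular zone and the noise threshold it defines."""

    mask: np.ndarray
    area_mm2: float
    threshold: float
    seed_px: tuple[int, int]


@dataclass
class MetricResult:
    """One metric value for one (layer, ROI) combination."""

    layer: str
    roi: str
    metric: str
    value: float

    def __post_init__(self) -> None:
        if self.metric in ("vd", "vld", "microcap_vd") and np.isfinite(self.value):
            if not 0.0 <= self.value <= 100.0:
                raise ValueError(f"{self.metric} must be in [0, 100], got {self.value}")
        if self.metric == "afi" and np.isfinite(self.value):
            if not 0.0 <= self.value <= 1.0:
                raise ValueError(f"afi must be in [0, 1], got {self.value}")


def _pixels(image: EnFaceAngiogram | np.ndarray) -> np.ndarray:
    if isinstance(image, EnFaceAngiogram):
        return image.pixels
    return np.asarray(image, dtype=float)


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------


def phansalkar_binarize(
    image: EnFaceAngiogram | np.ndarray,
    window_px: int = 15,
    p: float = 2.0,
    q: float = 10.0,
    k: float = 0.25,
    r: float = 0.5,
) -> BinaryVesselMap:
    """Phansalkar local thresholding for low-contrast images on [0, 1].

    The per-pixel threshold is

    .. math:: t = m \\cdot (1 + p e^{-qm} + k(s/r - 1))

    with *m* and *s* the mean and standard deviation over a ``window_px``
    square window (mirror padding at the edges).  A pixel is foreground iff
    its value is strictly above *t*.  Defaults are the canonical constants of
    the ImageJ auto-local-threshold family with the study's 15×15 window.
    """
    img = _pixels(image)
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError(f"window_px must be an odd integer >= 3, got {window_px}")
    m = ndimage.uniform_filter(img, size=window_px, mode="mirror")
    m2 = ndimage.uniform_filter(img * img, size=window_px, mode="mirror")
    s = np.sqrt(np.maximum(m2 - m * m, 0.0))
    t = m * (1.0 + p * np.exp(-q * m) + k * (s / r - 1.0))
    return BinaryVesselMap(
        mask=img > t,
        provenance="phansalkar",
        threshold_params={"window_px": window_px, "p": p, "q": q, "k": k, "r": r},
    )


def shanbhag_threshold_bin(hist: np.ndarray) -> int | None:
    """Shanbhag (1994) fuzzy-entropy threshold bin for a histogram.

    Returns the bin index minimising the absolute difference of the fuzzy
    information measures of the two classes, or None when fewer than two bins
    are occupied (no threshold exists).  Pixels in bins ``<= t`` are
    background.
    """
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    occupied = np.nonzero(hist)[0]
    if occupied.size < 2:
        return None
    norm = hist / total
    p1 = np.cumsum(norm)  # P(<= bin)
    p2 = 1.0 - p1  # P(> bin)
    first, last = occupied[0], occupied[-1]

    best_bin, best_val = None, np.inf
    # valid thresholds leave mass on both sides
    for it in range(first, last):
        # fuzzy entropy of the background class
        term = 0.5 / p1[it]
        ent_back = 0.0
        for ih in range(1, it + 1):
            if norm[ih] > 0:
                ent_back -= norm[ih] * np.log(1.0 - term * p1[ih - 1])
        ent_back *= term
        # fuzzy entropy of the foreground class
        term = 0.5 / p2[it]
        ent_obj = 0.0
        for ih in range(it + 1, len(hist)):
            if norm[ih] > 0:
                ent_obj -= norm[ih] * np.log(1.0 - term * p2[ih])
        ent_obj *= term
        val = abs(ent_back - ent_obj)
        if val < best_val:
            best_val, best_bin = val, it
    return best_bin


def shanbhag_binarize(
    image: EnFaceAngiogram | np.ndarray, n_bins: int = 256
) -> BinaryVesselMap:
    """Global Shanbhag fuzzy-entropy threshold on the ``n_bins`` histogram.

    Foreground is strictly above the threshold bin's upper edge value.  A
    constant image (single occupied bin) has no threshold: everything is
    background and a warning is logged.
    """
    img = _pixels(image)
    hist, edges = np.histogram(img, bins=n_bins, range=(0.0, 1.0))
    t_bin = shanbhag_threshold_bin(hist)
    if t_bin is None:
        logger.warning("shanbhag_binarize: constant image, no threshold; all background")
        warnings.warn("constant image: Shanbhag threshold undefined, all background")
        return BinaryVesselMap(
            mask=np.zeros_like(img, dtype=bool),
            provenance="shanbhag",
            threshold_params={"n_bins": n_bins, "threshold_bin": None},
        )
    threshold = edges[t_bin + 1]  # upper edge of the threshold bin
    return BinaryVesselMap(
        mask=img > threshold,
        provenance="shanbhag",
        threshold_params={
            "n_bins": n_bins,
            "threshold_bin": int(t_bin),
            "threshold": float(threshold),
        },
    )


def contrast_stretch(
    image: EnFaceAngiogram,
    low_percentile: float = 0.5,
    high_percentile: float = 99.5,
) -> EnFaceAngiogram:
    """Linear percentile stretch to the full [0, 1] range, clipping the tails."""
    img = image.pixels
    lo, hi = np.percentile(img, [low_percentile, high_percentile])
    if hi <= lo:
        warnings.warn("contrast_stretch: degenerate percentile range, image unchanged")
        return image.replace(pixels=img.copy())
    out = np.clip((img - lo) / (hi - lo), 0.0, 1.0)
    return image.replace(pixels=out)


def faz_background_binarize(
    image: EnFaceAngiogram,
    faz_seed_px: tuple[int, int] | None = None,
    sd_multiplier: float = 2.0,
    seed_disc_diameter_mm: float = 0.3,
    max_zone_diameter_mm: float = 1.0,
) -> tuple[BinaryVesselMap, FazRegion]:
    """Binarize a macular scan using the FAZ background signal as threshold.

    The avascular zone is delineated by growing, from ``faz_seed_px`` (default:
    image centre), the connected region of pixels at or below
    ``mean + sd_multiplier·SD`` of a small seed disc; growth is bounded to the
    central ``max_zone_diameter_mm`` zone (the fovea lies inside the 1.0 mm
    parafoveal inner ring) and isolated supra-threshold holes are filled.  The
    global noise threshold is then ``mean + sd_multiplier·SD`` of the pixels in
    the delineated FAZ; foreground = strictly above it.
    """
    if image.scan_type != "macula":
        raise ValueError("FAZ-background thresholding applies to macular scans")
    img = image.pixels
    h, w = img.shape
    if faz_seed_px is None:
        faz_seed_px = image.center_px
    sr, sc = faz_seed_px
    if not (0 <= sr < h and 0 <= sc < w):
        raise ValueError(f"faz_seed_px {faz_seed_px} outside image")
    try:
        otsu = filters.threshold_otsu(img)
    except ValueError:  # constant image: no vessel/background split to guard
        otsu = np.inf
    if img[sr, sc] > otsu:
        raise ValueError(
            "faz_seed_px lies on a high-signal (vessel) pixel; move the seed "
            "into the avascular zone or pass the image centre"
        )
    rows = np.arange(h)[:, None] - sr
    cols = np.arange(w)[None, :] - sc
    d_mm = np.hypot(rows, cols) * image.mm_per_px
    seed_disc = d_mm <= seed_disc_diameter_mm / 2.0
    mu, sd = img[seed_disc].mean(), img[seed_disc].std()
    grow_t = mu + sd_multiplier * sd

    # bound growth to the central zone, measured from the image centre
    crows = np.arange(h)[:, None] - image.center_px[0]
    ccols = np.arange(w)[None, :] - image.center_px[1]
    central = np.hypot(crows, ccols) * image.mm_per_px <= max_zone_diameter_mm / 2.0
    candidate = (img <= grow_t) & central
    candidate[sr, sc] = True  # the seed may itself be an isolated noise speck
    labels, _ = ndimage.label(candidate)  # 4-connectivity: a closed 1-px vessel
    region = labels == labels[sr, sc]  # ring blocks the flood
    region = ndimage.binary_fill_holes(region)

    faz_mu, faz_sd = img[region].mean(), img[region].std()
    threshold = faz_mu + sd_multiplier * faz_sd
    area_mm2 = float(region.sum()) * image.scale.px_area_um2 / 1e6
    faz = FazRegion(
        mask=region, area_mm2=area_mm2, threshold=float(threshold), seed_px=(sr, sc)
    )
    binary = BinaryVesselMap(
        mask=img > threshold,
        provenance="faz_background",
        threshold_params={
            "threshold": float(threshold),
            "sd_multiplier": sd_multiplier,
            "faz_mean": float(faz_mu),
            "faz_sd": float(faz_sd),
        },
    )
    return binary, faz


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def vessel_density(binary: BinaryVesselMap, roi: AnnularROI) -> float:
    """Percent of ROI pixels occupied by vessels: 100·|fg ∧ roi| / |roi|."""
    mask, roi_mask = binary.mask, roi.pixel_mask
    if mask.shape != roi_mask.shape:
        raise ValueError("binary map and ROI shapes differ")
    n_roi = roi_mask.sum()
    if n_roi == 0:
        raise ValueError("empty ROI")
    return 100.0 * float((mask & roi_mask).sum()) / float(n_roi)


def large_vessel_mask(
    image_disc: EnFaceAngiogram,
    scale: ScaleInfo | None = None,
    min_component_px: int = 25,
    min_component_area_um2: float | None = None,
) -> LargeVesselMask:
    """Major-vasculature mask of a disc scan.

    Pipeline: contrast stretch → Shanbhag global threshold → removal of small
    8-connected components.  By default components smaller than
    ``min_component_px`` pixels are removed (the perfused-capillary removal
    criterion of the original ImageJ workflow, applied in pixel units);
    alternatively a physical criterion in µm² may be given, with a floor of
    one pixel.  The surviving components are the large arterioles/venules.
    """
    if scale is None:
        scale = image_disc.scale
    stretched = contrast_stretch(image_disc)
    binary = shanbhag_binarize(stretched)
    if min_component_area_um2 is not None:
        thr_px = max(min_component_area_um2 / scale.px_area_um2, 1.0)
        area_um2 = float(min_component_area_um2)
    else:
        thr_px = float(min_component_px)
        area_um2 = min_component_px * scale.px_area_um2
    labels, n = ndimage.label(binary.mask, structure=np.ones((3, 3), dtype=int))
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = sizes >= thr_px
        mask = keep[labels]
    else:
        mask = np.zeros_like(binary.mask)
    return LargeVesselMask(
        mask=mask,
        min_component_px=int(np.ceil(thr_px)),
        min_component_area_um2=area_um2,
    )


def microcapillary_density(
    binary_rpc: BinaryVesselMap, large: LargeVesselMask, roi: AnnularROI
) -> float:
    """VD of the small capillaries after removing the large-vessel pixels.

    Large-vessel pixels are excluded from both numerator and denominator:
    ``100·|fg ∧ roi ∧ ¬large| / |roi ∧ ¬large|``.
    """
    if binary_rpc.mask.shape != roi.pixel_mask.shape:
        raise ValueError("binary map and ROI shapes differ")
    denom_mask = roi.pixel_mask & ~large.mask
    denom = denom_mask.sum()
    if denom == 0:
        raise ValueError("ROI entirely covered by the large-vessel mask")
    return 100.0 * float((binary_rpc.mask & denom_mask).sum()) / float(denom)


def skeletonize(binary: BinaryVesselMap | np.ndarray) -> SkeletonMap:
    """Thin a binary vessel map to 1-pixel-wide, 8-connected centrelines.

    Topology-preserving iterative thinning (scikit-image); the skeleton is a
    subset of the input mask and thinning is idempotent.
    """
    mask = binary.mask if isinstance(binary, BinaryVesselMap) else np.asarray(binary, bool)
    return SkeletonMap(mask=morphology.skeletonize(mask))


def vessel_length_density(skeleton: SkeletonMap, roi: AnnularROI) -> float:
    """Percent of ROI pixels on the skeleton (length in pixel units)."""
    if skeleton.mask.shape != roi.pixel_mask.shape:
        raise ValueError("skeleton and ROI shapes differ")
    n_roi = roi.pixel_mask.sum()
    if n_roi == 0:
        raise ValueError("empty ROI")
    return 100.0 * float((skeleton.mask & roi.pixel_mask).sum()) / float(n_roi)


def adjusted_flow_index(
    image: EnFaceAngiogram, binary: BinaryVesselMap, roi: AnnularROI
) -> float:
    """Mean decorrelation value over vessel pixels inside the ROI.

    Returns NaN (with a warning) when the ROI contains no supra-threshold
    pixel.
    """
    img = _pixels(image)
    sel = binary.mask & roi.pixel_mask
    if img.shape != sel.shape:
        raise ValueError("image, binary map and ROI shapes differ")
    if not sel.any():
        warnings.warn("adjusted_flow_index: no vessel pixels in ROI; returning NaN")
        return float("nan")
    return float(img[sel].mean())


# ---------------------------------------------------------------------------
# Per-eye orchestration
# ---------------------------------------------------------------------------


@dataclass
class QuantifyConfig:
    """Parameters of the per-eye quantification run."""

    eye: str = "OD"
    phansalkar_window_px: int = 15
    faz_sd_multiplier: float = 2.0
    min_component_px: int = 25
    enforce_quality: bool = True
    min_sq: int = MIN_SQ
    min_ssi: dict = field(default_factory=lambda: dict(MIN_SSI))


def _quality_ok(image: EnFaceAngiogram, config: QuantifyConfig) -> bool:
    if not config.enforce_quality or image.quality is None:
        return True
    sq, ssi = image.quality
    return sq >= config.min_sq and ssi >= config.min_ssi[image.scan_type]


def quantify_eye(
    images: Sequence[EnFaceAngiogram], config: QuantifyConfig | None = None
) -> list[MetricResult]:
    """Compute every (layer, ROI, metric) row available from the given scans.

    Expected scans (any subset; missing layers are simply skipped with a log
    entry, as are quality-failing scans):

    * macula / SCP → parafoveal VD, VLD, AFI (FAZ-background threshold) and
      FAZ area,
    * macula / whole_retina → parafoveal VD and FAZ area (preferred source),
    * macula / DCP → parafoveal VD,
    * disc / RPC → peripapillary VD (global + superior quadrant), VLD, and
      microcapillary VD (large-vessel mask removed),
    * disc / SVC → peripapillary VD and VLD.

    Deterministic given images + config.
    """
    if config is None:
        config = QuantifyConfig()
    by_layer: dict[str, EnFaceAngiogram] = {}
    for img in images:
        if img.layer is None:
            raise ValueError("every input scan needs a layer label")
        if not _quality_ok(img, config):
            logger.info(
                "quantify_eye: %s scan (%s) fails quality gate SQ>=%d/SSI>=%d; skipped",
                img.scan_type,
                img.layer,
                config.min_sq,
                config.min_ssi[img.scan_type],
            )
            continue
        by_layer[img.layer] = img

    results: list[MetricResult] = []

    def add(layer: str, roi: str, metric: str, value: float) -> None:
        results.append(MetricResult(layer=layer, roi=roi, metric=metric, value=value))

    # --- macular layers -----------------------------------------------------
    scp = by_layer.get("SCP")
    if scp is not None:
        roi = make_annulus(scp, *PARAFOVEA_MM, eye=config.eye)
        binary, faz = faz_background_binarize(scp, sd_multiplier=config.faz_sd_multiplier)
        add("SCP", "parafovea", "vd", vessel_density(binary, roi))
        add("SCP", "parafovea", "vld", vessel_length_density(skeletonize(binary), roi))
        add("SCP", "parafovea", "afi", adjusted_flow_index(scp, binary, roi))
        if "whole_retina" not in by_layer:
            add("SCP", "fovea", "faz_area_mm2", faz.area_mm2)
    for layer in ("whole_retina", "DCP"):
        img = by_layer.get(layer)
        if img is None:
            continue
        roi = make_annulus(img, *PARAFOVEA_MM, eye=config.eye)
        binary, faz = faz_background_binarize(img, sd_multiplier=config.faz_sd_multiplier)
        add(layer, "parafovea", "vd", vessel_density(binary, roi))
        if layer == "whole_retina":
            add(layer, "fovea", "faz_area_mm2", faz.area_mm2)

    # --- disc layers --------------------------------------------------------
    rpc = by_layer.get("RPC")
    if rpc is not None:
        roi = make_annulus(rpc, *PERIPAPILLARY_MM, eye=config.eye)
        roi_sup = make_annulus(rpc, *PERIPAPILLARY_MM, quadrant="superior", eye=config.eye)
        binary = phansalkar_binarize(rpc, window_px=config.phansalkar_window_px)
        add("RPC", "peripapillary", "vd", vessel_density(binary, roi))
        add("RPC", "peripapillary_superior", "vd", vessel_density(binary, roi_sup))
        add("RPC", "peripapillary", "vld", vessel_length_density(skeletonize(binary), roi))
        large = large_vessel_mask(rpc, min_component_px=config.min_component_px)
        add(
            "RPC",
            "peripapillary",
            "microcap_vd",
            microcapillary_density(binary, large, roi),
        )
    svc = by_layer.get("SVC")
    if svc is not None:
        roi = make_annulus(svc, *PERIPAPILLARY_MM, eye=config.eye)
        binary = phansalkar_binarize(svc, window_px=config.phansalkar_window_px)
        add("SVC", "peripapillary", "vd", vessel_density(binary, roi))
        add("SVC", "peripapillary", "vld", vessel_length_density(skeletonize(binary), roi))

    return results
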