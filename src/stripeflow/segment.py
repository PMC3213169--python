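"""Midsagittal-plane nuclei segmentation with oversegmentation fusion.

The nuclear-marker channel of a laterally imaged blastoderm embryo shows a
cortical monolayer of nuclei around a bright autofluorescent yolk, all
enclosed by the brighter vitelline membrane.  Segmentation proceeds as:

1. gray-scale top-hat transform followed by Otsu thresholding, which
   removes the broad yolk autofluorescence;
2. binary erosions followed by morphological reconstruction, which delete
   the thin vitelline-membrane ring while restoring the nuclei;
3. Gaussian smoothing and marker-based watershed to separate touching
   nuclei inside the cortical band.

During mid cycle 14 the invaginating cell membrane draws dark lines across
nuclei and splits their watershed basins.  A pair of watershed regions is
fused into one nucleus when (1) their shared watershed line is longer than
one pixel and (2) one region touches the yolk but not the outside while the
other touches the outside but not the yolk — i.e. the two fragments sit on
the inner and outer faces of the cortical layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, morphology, segmentation
from skimage.feature import peak_local_max
from skimage.measure import regionprops

__all__ = [
    "SegmentationConfig",
    "LabelImage",
    "cortical_mask",
    "segment_nuclei",
    "fuse_oversegmented",
    "quantify_nuclei",
    "match_centroids",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters; defaults are tied to the expected nucleus size."""

    nucleus_radius: float = 4.0
    tophat_radius: float | None = None   # default: 2x nucleus radius
    erosion_radius: int = 2
    smooth_sigma: float | None = None    # default: 0.4x nucleus radius
    closing_radius: float | None = None  # band closure; default: 1.5x radius
    marker_h: float = 0.04  # marker prominence, fraction of band dynamic range

    def resolved(self) -> "SegmentationConfig":
        r = self.nucleus_radius
        return SegmentationConfig(
            nucleus_radius=r,
            tophat_radius=self.tophat_radius or 2.0 * r,
            erosion_radius=self.erosion_radius,
            smooth_sigma=self.smooth_sigma or 0.4 * r,
            closing_radius=self.closing_radius or 1.5 * r,
            marker_h=self.marker_h,
        )


@dataclass
class LabelImage:
    """Watershed labeling of the cortical band.

    ``labels`` partitions the cortical mask (``band``); 0 is background.
    The band's complement splits into the interior yolk cavity and the
    exterior; these define the topology flags used by the fusion rule.
    ``cores`` marks the bright nuclear pixels within the band: each basin's
    core is the nucleus mask used for quantification.  ``adjacency`` maps
    unordered label pairs to watershed-line lengths in pixels.
    """

    labels: np.ndarray
    band: np.ndarray
    cores: np.ndarray
    yolk: np.ndarray
    outside: np.ndarray
    adjacency: dict[tuple[int, int], int] = field(default_factory=dict)
    touches_yolk: dict[int, bool] = field(default_factory=dict)
    touches_outside: dict[int, bool] = field(default_factory=dict)
    frame_id: str = ""

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids != 0]


def cortical_mask(nuclear_frame: np.ndarray,
                  config: SegmentationConfig = SegmentationConfig()) -> np.ndarray:
    """Solid cortical-band mask excluding yolk and the vitelline ring.

    Top-hat + Otsu keeps only small-scale bright structures (nuclei and the
    thin ring); erosion followed by morphological reconstruction removes
    the ring, which erodes away completely, while nuclei regrow from their
    cores.  A morphological closing then joins the nuclei into the solid
    band.  An all-zero frame yields an empty mask.
    """
    cfg = config.resolved()
    img = np.asarray(nuclear_frame, dtype=float)
    if img.max() <= 0:
        return np.zeros(img.shape, dtype=bool)
    th = morphology.white_tophat(img, morphology.disk(int(round(cfg.tophat_radius))))
    fg = th > filters.threshold_otsu(th)
    eroded = morphology.erosion(fg, morphology.disk(cfg.erosion_radius))
    recon = morphology.reconstruction(eroded.astype(np.uint8), fg.astype(np.uint8),
                                      method="dilation").astype(bool)
    band = morphology.closing(recon, morphology.disk(int(round(cfg.closing_radius))))
    return band


def _foreground_in_band(nuclear_frame: np.ndarray, band: np.ndarray,
                        cfg: SegmentationConfig) -> np.ndarray:
    """Bright nuclear foreground within the band (second Otsu pass).

    The cortical band mixes nuclei with dimmer cortical cytoplasm; an Otsu
    threshold restricted to band pixels separates the two.
    """
    img = np.asarray(nuclear_frame, dtype=float)
    vals = img[band]
    if vals.size == 0 or vals.max() <= vals.min():
        return np.zeros(band.shape, dtype=bool)
    return band & (img > filters.threshold_otsu(vals))


def _complement_regions(band: np.ndarray):
    """Split the band complement into the exterior and the yolk cavity."""
    comp, n = ndi.label(~band)
    if n == 0:
        empty = np.zeros(band.shape, dtype=bool)
        return empty, empty
    border_labels = set(np.unique(np.concatenate([
        comp[0, :], comp[-1, :], comp[:, 0], comp[:, -1]])))
    border_labels.discard(0)
    outside = np.isin(comp, list(border_labels))
    interior_ids = [i for i in range(1, n + 1) if i not in border_labels]
    if interior_ids:
        sizes = ndi.sum(np.ones_like(comp), comp, interior_ids)
        yolk = comp == interior_ids[int(np.argmax(sizes))]
    else:
        yolk = np.zeros(band.shape, dtype=bool)
    return yolk, outside


_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _adjacency(labels: np.ndarray) -> dict[tuple[int, int], int]:
    """Watershed-line length per adjacent label pair.

    Length is the larger of the two one-sided counts of pixels in one
    region having an 8-neighbor in the other; a single diagonal contact
    therefore scores 1 ("not greater than one pixel").
    """
    pairs: dict[tuple[int, int], tuple[set, set]] = {}
    h, w = labels.shape
    for dy, dx in _N8:
        a = labels[max(dy, 0):h + min(dy, 0), max(dx, 0):w + min(dx, 0)]
        b = labels[max(-dy, 0):h + min(-dy, 0), max(-dx, 0):w + min(-dx, 0)]
        m = (a != b) & (a > 0) & (b > 0)
        ys, xs = np.nonzero(m)
        la = a[ys, xs]
        lb = b[ys, xs]
        # pixel coordinates of the a-side pixel in the original image
        ay = ys + max(dy, 0)
        ax = xs + max(dx, 0)
        for y, x, i, j in zip(ay, ax, la, lb):
            key = (int(min(i, j)), int(max(i, j)))
            sa, sb = pairs.setdefault(key, (set(), set()))
            if i < j:
                sa.add((int(y), int(x)))
            else:
                sb.add((int(y), int(x)))
    return {k: max(len(sa), len(sb)) for k, (sa, sb) in pairs.items()}


def _touch_flags(labels: np.ndarray, yolk: np.ndarray, outside: np.ndarray):
    """4-connectivity adjacency of each label to the yolk / exterior."""
    grown_y = morphology.dilation(yolk, morphology.disk(1))
    grown_o = morphology.dilation(outside, morphology.disk(1))
    ty: dict[int, bool] = {}
    to: dict[int, bool] = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        m = labels == lab
        ty[int(lab)] = bool(np.any(m & grown_y))
        to[int(lab)] = bool(np.any(m & grown_o))
    return ty, to


def segment_nuclei(nuclear_frame: np.ndarray, mask: np.ndarray,
                   config: SegmentationConfig = SegmentationConfig(),
                   frame_id: str = "") -> LabelImage:
    """Watershed separation of nuclei within the cortical band.

    Markers are the h-maxima of the Gaussian-smoothed frame inside the
    band (peaks whose prominence exceeds ``marker_h`` of the band's dynamic
    range): one marker per bright nucleus or membrane-split fragment, none
    in the dimmer cortical cytoplasm.  The watershed floods the negated
    smoothed image over the whole band, so the basins partition the
    cortical mask and each basin genuinely borders the yolk cavity and/or
    the exterior.  An empty mask yields an empty labeling.
    """
    cfg = config.resolved()
    band = np.asarray(mask, dtype=bool)
    img = np.asarray(nuclear_frame, dtype=float)
    if not band.any():
        empty = np.zeros(band.shape, dtype=bool)
        return LabelImage(labels=np.zeros(band.shape, dtype=np.int32),
                          band=band, cores=empty, yolk=empty, outside=~band,
                          frame_id=frame_id)
    cores = _foreground_in_band(img, band, cfg)
    smoothed = ndi.gaussian_filter(img, cfg.smooth_sigma)
    vals = smoothed[band]
    h = cfg.marker_h * float(np.percentile(vals, 99.5) - np.percentile(vals, 1.0))
    peaks = morphology.h_maxima(smoothed, max(h, 1e-12)) & band
    markers, _ = ndi.label(peaks)
    labels = segmentation.watershed(-smoothed, markers=markers, mask=band)
    labels, _, _ = segmentation.relabel_sequential(labels)
    labels = labels.astype(np.int32)
    yolk, outside = _complement_regions(band)
    adj = _adjacency(labels)
    ty, to = _touch_flags(labels, yolk, outside)
    return LabelImage(labels=labels, band=band, cores=cores, yolk=yolk,
                      outside=outside, adjacency=adj, touches_yolk=ty,
                      touches_outside=to, frame_id=frame_id)


def _qualifying_pairs(li: LabelImage) -> list[tuple[int, int]]:
    out = []
    for (i, j), length in li.adjacency.items():
        if length < 2:
            continue
        fi = (li.touches_yolk.get(i, False), li.touches_outside.get(i, False))
        fj = (li.touches_yolk.get(j, False), li.touches_outside.get(j, False))
        if (fi == (True, False) and fj == (False, True)) or (
                fi == (False, True) and fj == (True, False)):
            out.append((i, j))
    return out


def fuse_oversegmented(li: LabelImage) -> LabelImage:
    """Fuse membrane-split watershed pairs; idempotent coarsening.

    All qualifying pairs (line length >= 2 px; one fragment yolk-only, the
    other outside-only) are merged by union-find, flags and adjacency are
    recomputed, and the pass repeats until no qualifying pair remains.  A
    merged nucleus spans the band, touches both faces, and can no longer
    qualify, so the procedure reaches a fixpoint.
    """
    current = li
    while True:
        pairs = _qualifying_pairs(current)
        if not pairs:
            return current
        parent: dict[int, int] = {}

        def find(x: int) -> int:
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in pairs:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
        mapping = np.arange(current.labels.max() + 1)
        for lab in np.unique(current.labels):
            if lab != 0:
                mapping[lab] = find(int(lab))
        labels = mapping[current.labels]
        labels, _, _ = segmentation.relabel_sequential(labels)
        labels = labels.astype(np.int32)
        adj = _adjacency(labels)
        ty, to = _touch_flags(labels, current.yolk, current.outside)
        current = LabelImage(labels=labels, band=current.band, cores=current.cores,
                             yolk=current.yolk, outside=current.outside,
                             adjacency=adj, touches_yolk=ty, touches_outside=to,
                             frame_id=current.frame_id)


def quantify_nuclei(li: LabelImage, reporter_frame: np.ndarray,
                    embryo_id: str = "", t_min: float = np.nan) -> pd.DataFrame:
    """Per-nucleus mean reporter fluorescence and centroid.

    The mask corresponding to each nucleus is its basin's bright core
    (basin intersected with the nuclear foreground), which excludes the
    surrounding cortical cytoplasm from the mean.  Returns one record per
    label with columns ``embryo_id``, ``t_min``, ``label``, ``x_px``,
    ``y_px``, ``mean_fluo``, ``n_pixels``.  Pixel indexing is 0-based,
    row-major; the centroid is the unweighted pixel centroid of the core.
    Basins without a bright core (rare spurious markers) are omitted.
    """
    rep = np.asarray(reporter_frame, dtype=float)
    if rep.shape != li.labels.shape:
        raise ValueError("reporter frame shape does not match label image")
    core_labels = np.where(li.cores, li.labels, 0)
    rows = []
    for p in regionprops(core_labels, intensity_image=rep):
        cy, cx = p.centroid
        rows.append({
            "embryo_id": embryo_id, "t_min": t_min, "label": int(p.label),
            "x_px": float(cx), "y_px": float(cy),
            "mean_fluo": float(p.intensity_mean),
            "n_pixels": int(p.area),
        })
    return pd.DataFrame(rows, columns=["embryo_id", "t_min", "label", "x_px",
                                       "y_px", "mean_fluo", "n_pixels"])


def match_centroids(found: pd.DataFrame, truth: pd.DataFrame,
                    max_dist: float) -> pd.DataFrame:
    """Greedy one-to-one nearest matching of detected to true centroids.

    Both frames need ``x_px``/``y_px`` columns.  Returns matched index
    pairs with distances; unmatched entries are omitted.
    """
    from scipy.spatial import cKDTree
    fa = found[["x_px", "y_px"]].to_numpy(dtype=float)
    tb = truth[["x_px", "y_px"]].to_numpy(dtype=float)
    if len(fa) == 0 or len(tb) == 0:
        return pd.DataFrame(columns=["found_idx", "truth_idx", "distance"])
    tree = cKDTree(tb)
    dists, idxs = tree.query(fa, k=1, distance_upper_bound=max_dist)
    order = np.argsort(dists)
    used_t: set[int] = set()
    rows = []
    for fi in order:
        ti = idxs[fi]
        if not np.isfinite(dists[fi]) or ti in used_t:
            continue
        used_t.add(int(ti))
        rows.append({"found_idx": int(found.index[fi]), "truth_idx": int(truth.index[ti]),
                     "distance": float(dists[fi])})
    return pd.DataFrame(rows)
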