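"""Baseline correction and inverse-watershed peak picking on the 2-D
total-ion image.

Peaks in the total-ion-current (TIC) image are treated as catchment basins of
the *inverted* image: watershed flooding from the local minima of the
inverted (smoothed) TIC segments the above-noise region into one footprint
per peak. The noise floor is robust (median + ``min_snr`` × 1.4826·MAD of the
smoothed TIC), basins smaller than ``min_area`` cells are discarded, the apex
is the maximum-TIC cell of a footprint, and the apex spectrum is the m/z
slice at that single cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .io_core import Chromatogram2D, MassSpectrum

__all__ = ["PeakBlob", "correct_baseline", "detect_peaks"]


@dataclass
class PeakBlob:
    """One detected peak region of the TIC image."""

    apex: tuple[int, int]                 # (mod_idx, scan_idx)
    rt1: float                            # min
    rt2: float                            # s
    footprint: set[tuple[int, int]] = field(default_factory=set)
    volume: float = 0.0                   # summed TIC over the footprint
    apex_spectrum: MassSpectrum | None = None

    def __post_init__(self):
        if self.footprint and self.apex not in self.footprint:
            raise ValueError("apex must lie inside the footprint")
        if self.footprint and self.volume <= 0:
            raise ValueError("blob volume must be positive")


def correct_baseline(chrom: Chromatogram2D, window_mod: int = 21,
                     window_scan: int = 151, smooth: int = 5) -> Chromatogram2D:
    """Rolling-minimum baseline subtraction per m/z channel.

    For every m/z channel the baseline is the rolling minimum over a
    (``window_mod`` × ``window_scan``) neighbourhood of the retention plane,
    lightly smoothed with a uniform filter, and subtracted; the result is
    clipped at zero. Windows default to several peak widths so that an
    isolated Gaussian on a flat baseline *b* keeps its shape with the apex
    lowered by exactly *b*.
    """
    data = np.asarray(chrom.data, dtype=np.float32)
    size = (min(window_mod, data.shape[0]), min(window_scan, data.shape[1]), 1)
    baseline = ndi.minimum_filter(data, size=size, mode="nearest")
    if smooth > 1:
        baseline = ndi.uniform_filter(
            baseline, size=(min(smooth, data.shape[0]), min(smooth, data.shape[1]), 1),
            mode="nearest",
        )
    corrected = np.clip(data - baseline, 0.0, None)
    return Chromatogram2D(
        corrected, chrom.modulation_period, chrom.scan_rate,
        chrom.mz_start, chrom.mz_end, chrom.acquisition_start,
    )


def _merge_wraparound(blobs: list[PeakBlob], n_scans: int, tic: np.ndarray,
                      chrom: Chromatogram2D) -> list[PeakBlob]:
    """Merge blob pairs split across the modulation boundary.

    A pair is merged when one footprint touches the last scan, the other
    touches scan 0, and their modulation-index ranges overlap.
    """
    top = [b for b in blobs if any(s == n_scans - 1 for _, s in b.footprint)]
    bottom = [b for b in blobs if any(s == 0 for _, s in b.footprint)]
    merged: set[int] = set()
    out = []
    for t in top:
        t_mods = {m for m, _ in t.footprint}
        for b in bottom:
            if id(b) == id(t) or id(b) in merged or id(t) in merged:
                continue
            if t_mods & {m for m, _ in b.footprint}:
                foot = t.footprint | b.footprint
                apex = max(foot, key=lambda c: tic[c])
                out.append(PeakBlob(
                    apex=apex,
                    rt1=float(chrom.rt1_of(apex[0])),
                    rt2=float(chrom.rt2_of(apex[1])),
                    footprint=foot,
                    volume=t.volume + b.volume,
                    apex_spectrum=chrom.spectrum_at(*apex),
                ))
                merged.update((id(t), id(b)))
                break
    out.extend(b for b in blobs if id(b) not in merged)
    return out


def _merge_shallow_saddles(labels: np.ndarray, smoothed: np.ndarray,
                           rel: float) -> np.ndarray:
    """Merge adjacent watershed basins separated by a shallow saddle.

    Two basins are one peak when the saddle between them rises above ``rel``
    × the lower of the two basin apexes (over-segmentation from noise ripples
    on a peak's flank); merging repeats until stable.
    """
    while True:
        apex = ndi.maximum(smoothed, labels=labels,
                           index=np.arange(1, labels.max() + 1))
        saddle: dict[tuple[int, int], float] = {}
        for axis in (0, 1):
            a = labels if axis == 0 else labels.T
            s = smoothed if axis == 0 else smoothed.T
            l1, l2 = a[:-1, :], a[1:, :]
            both = (l1 > 0) & (l2 > 0) & (l1 != l2)
            h = np.minimum(s[:-1, :][both], s[1:, :][both])
            for x, y, hh in zip(l1[both], l2[both], h):
                key = (min(x, y), max(x, y))
                saddle[key] = max(saddle.get(key, -np.inf), float(hh))
        parent = list(range(labels.max() + 1))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        merged_any = False
        for (x, y), h in saddle.items():
            if h >= rel * min(apex[x - 1], apex[y - 1]):
                rx, ry = find(x), find(y)
                if rx != ry:
                    parent[max(rx, ry)] = min(rx, ry)
                    merged_any = True
        if not merged_any:
            return labels
        remap = np.array([find(i) for i in range(labels.max() + 1)])
        labels = remap[labels]


def detect_peaks(chrom: Chromatogram2D, min_snr: float = 5.0,
                 min_area: int = 5, smooth_sigma: float = 1.0,
                 merge_wrap: bool = True,
                 merge_saddle_rel: float = 0.9) -> list[PeakBlob]:
    """Inverse-watershed blob detection on the TIC image.

    Returns one :class:`PeakBlob` per catchment basin of the inverted,
    Gaussian-smoothed TIC image whose basin lies above the robust noise floor
    and covers at least ``min_area`` cells. Adjacent basins whose separating
    saddle exceeds ``merge_saddle_rel`` of the lower apex are merged (noise
    ripples on one peak's flank are not two peaks). Footprints partition the
    above-noise region (no cell belongs to two blobs). An all-zero image
    yields an empty list.
    """
    if min_snr <= 0:
        raise ValueError("min_snr must be > 0")
    if min_area < 1:
        raise ValueError("min_area must be >= 1 cell")
    tic = chrom.tic_image().astype(float)
    if not np.any(tic):
        return []
    smoothed = ndi.gaussian_filter(tic, smooth_sigma)
    med = float(np.median(smoothed))
    mad = float(np.median(np.abs(smoothed - med)))
    # the relative term keeps numerically-tiny smoothing tails out of the
    # mask when the image is noise-free (MAD = 0)
    floor = max(med + min_snr * 1.4826 * mad, 1e-4 * float(smoothed.max()))
    mask = smoothed > floor
    if not mask.any():
        return []
    coords = peak_local_max(
        smoothed, min_distance=1, threshold_abs=floor, exclude_border=False,
    )
    if coords.size == 0:
        return []
    markers = np.zeros_like(tic, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    labels = watershed(-smoothed, markers=markers, mask=mask, connectivity=1)
    if merge_saddle_rel is not None and 0 < merge_saddle_rel < 1:
        labels = _merge_shallow_saddles(labels, smoothed, merge_saddle_rel)

    blobs: list[PeakBlob] = []
    for lab in range(1, int(labels.max()) + 1):
        cells = np.argwhere(labels == lab)
        if cells.shape[0] < min_area:
            continue
        foot = {(int(r), int(c)) for r, c in cells}
        apex = max(foot, key=lambda cell: tic[cell])
        volume = float(sum(tic[cell] for cell in foot))
        if volume <= 0:
            continue
        blobs.append(PeakBlob(
            apex=apex,
            rt1=float(chrom.rt1_of(apex[0])),
            rt2=float(chrom.rt2_of(apex[1])),
            footprint=foot,
            volume=volume,
            apex_spectrum=chrom.spectrum_at(*apex),
        ))
    if merge_wrap and chrom.n_scans > 2:
        blobs = _merge_wraparound(blobs, chrom.n_scans, tic, chrom)
    return blobs
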