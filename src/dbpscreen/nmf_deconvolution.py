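"""NNSVD-seeded Frobenius NMF deconvolution of peak regions into layers.

Each peak region is cast as a non-negative matrix ``V`` (rows: nominal m/z
bins, columns: the region's retention-plane cells ordered by time) and
factored as ``V ≈ W H`` with ``W ≥ 0`` the component spectra and ``H ≥ 0``
their elution profiles. Seeding uses non-negative double singular value
decomposition (NNSVD, Boutsidis & Gallopoulos), which is deterministic, and
the factorisation is refined with Lee–Seung multiplicative updates for the
Frobenius objective; the loss trace is monotonically non-increasing.

At most four overlapping compounds are assumed per region (``k_max=4``);
components are ranked by their total contribution and components below 1% of
the total are pruned. The i-th ranked component of every region populates
layer *i* of the layered chromatogram, so layer 1 holds the cleanest
(dominant) spectrum of each peak and deeper layers the residual co-eluters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import Chromatogram2D, MassSpectrum, PeakRecord
from .peak_detection import PeakBlob

__all__ = [
    "RegionMatrix",
    "NMFResult",
    "LayerSet",
    "nnsvd_seed",
    "nmf_frobenius",
    "deconvolve_peak",
    "build_layers",
]


@dataclass
class RegionMatrix:
    """Non-negative m/z × scan matrix extracted from one blob footprint."""

    V: np.ndarray
    mz_axis: np.ndarray
    cells: list[tuple[int, int]]   # footprint cells, time-ordered (column order)

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=float)
        if np.any(self.V < 0):
            raise ValueError("region matrix must be non-negative")


@dataclass
class NMFResult:
    """Factorisation outcome: spectra ``W`` (m/z × k), profiles ``H``
    (k × scans), and the Frobenius objective trace."""

    W: np.ndarray
    H: np.ndarray
    k: int
    objective_trace: list[float] = field(default_factory=list)


@dataclass
class LayerSet:
    """Layered peak records: layer index (1–4) -> records."""

    layers: dict[int, list[PeakRecord]] = field(default_factory=dict)

    def records(self, layer: int) -> list[PeakRecord]:
        return self.layers.get(layer, [])

    def all_records(self) -> list[PeakRecord]:
        out = []
        for i in sorted(self.layers):
            out.extend(self.layers[i])
        return out


def nnsvd_seed(V: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative double SVD seeding (Boutsidis–Gallopoulos).

    For each leading singular triplet the dominant non-negative section of
    the singular vectors is kept; exact zeros are replaced by a small epsilon
    (1e-9 × mean of V) so multiplicative updates can move every entry.
    """
    V = np.asarray(V, dtype=float)
    if not np.any(V):
        raise ValueError("empty region")
    if k > min(V.shape):
        raise ValueError(f"k={k} exceeds min(V.shape)={min(V.shape)}")
    U, S, Vt = np.linalg.svd(V, full_matrices=False)
    m, n = V.shape
    W = np.zeros((m, k))
    H = np.zeros((k, n))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, k):
        u, v = U[:, j], Vt[j, :]
        up, un = np.clip(u, 0, None), np.clip(-u, 0, None)
        vp, vn = np.clip(v, 0, None), np.clip(-v, 0, None)
        nup, nun = np.linalg.norm(up), np.linalg.norm(un)
        nvp, nvn = np.linalg.norm(vp), np.linalg.norm(vn)
        if nup * nvp >= nun * nvn:
            sigma, wj, hj = nup * nvp, up / nup if nup else up, vp / nvp if nvp else vp
        else:
            sigma, wj, hj = nun * nvn, un / nun if nun else un, vn / nvn if nvn else vn
        W[:, j] = np.sqrt(S[j] * sigma) * wj
        H[j, :] = np.sqrt(S[j] * sigma) * hj
    eps = 1e-9 * V.mean()
    W[W <= 0] = eps
    H[H <= 0] = eps
    return W, H


def nmf_frobenius(V: np.ndarray, k: int, W0: np.ndarray | None = None,
                  H0: np.ndarray | None = None, tol: float = 1e-4,
                  max_iter: int = 200) -> NMFResult:
    """Lee–Seung multiplicative updates minimising ``||V - WH||_F``.

    Stops when the relative loss decrease drops below ``tol`` or after
    ``max_iter`` iterations. The objective trace is non-increasing (within
    floating-point guard epsilons); a NaN in the updates raises with the
    iteration index.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    V = np.asarray(V, dtype=float)
    if W0 is None or H0 is None:
        W0, H0 = nnsvd_seed(V, k)
    W = np.array(W0, dtype=float, copy=True)
    H = np.array(H0, dtype=float, copy=True)
    if np.any(W < 0) or np.any(H < 0):
        raise ValueError("seeds must be non-negative")
    guard = 1e-12 * (V.max() if V.size else 1.0) + 1e-300
    norm_v = np.linalg.norm(V)
    loss = float(np.linalg.norm(V - W @ H))
    trace = [loss]
    for it in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + guard)
        W *= (V @ H.T) / (W @ H @ H.T + guard)
        if np.any(np.isnan(W)) or np.any(np.isnan(H)):
            raise FloatingPointError(f"NaN in NMF updates at iteration {it + 1}")
        new_loss = float(np.linalg.norm(V - W @ H))
        trace.append(new_loss)
        rel = (loss - new_loss) / max(loss, 1e-30)
        loss = new_loss
        if rel < tol:
            break
    return NMFResult(W=W, H=H, k=k, objective_trace=trace)


def region_matrix(blob: PeakBlob, chrom: Chromatogram2D,
                  noise_floor: float = 0.0) -> RegionMatrix:
    """Build the nominal-m/z region matrix for a blob footprint.

    Entries below ``noise_floor`` are zeroed so that broadband residual
    noise does not masquerade as a low-rank component.
    """
    cells = sorted(
        blob.footprint,
        key=lambda c: c[0] * chrom.modulation_period + c[1] / chrom.scan_rate,
    )
    cols = [chrom.data[m, s].astype(float) for m, s in cells]
    V = np.stack(cols, axis=1)
    if noise_floor > 0:
        V = np.where(V >= noise_floor, V, 0.0)
    return RegionMatrix(V=V, mz_axis=chrom.mz_axis, cells=cells)


def _column_spectrum(w: np.ndarray, mz_axis: np.ndarray) -> MassSpectrum:
    keep = w > 1e-6 * w.max() if w.max() > 0 else np.zeros_like(w, bool)
    if not keep.any():
        return MassSpectrum(np.array([]), np.array([]), allow_empty=True)
    return MassSpectrum(mz_axis[keep].astype(float), w[keep])


def _plain_cosine(w1: np.ndarray, w2: np.ndarray) -> float:
    n1, n2 = np.linalg.norm(w1), np.linalg.norm(w2)
    return float(w1 @ w2 / (n1 * n2)) if n1 > 0 and n2 > 0 else 0.0


def deconvolve_peak(blob: PeakBlob, chrom: Chromatogram2D, k_max: int = 4,
                    prune_fraction: float = 0.01, tol: float = 1e-4,
                    max_iter: int = 200, noise_floor: float = 0.0,
                    prune_edge: bool = True, merge_cosine: float = 0.95):
    """Deconvolve one blob into up to ``k_max`` components.

    Returns a list of ``(spectrum, elution_profile, contribution)`` sorted by
    contribution (Σ of the W column × Σ of the H row) in descending order;
    components contributing less than ``prune_fraction`` of the total are
    pruned. With ``prune_edge`` (default), components whose elution profile
    peaks on the footprint *boundary* are also pruned: a compound eluting
    inside the region has its profile maximum in the interior, whereas the
    tail of a neighbouring peak leaking across the watershed line rises
    monotonically toward the edge. Because ``k`` is fixed rather than
    model-selected, a real component can be split across two factors; factors
    whose spectra agree at plain cosine ≥ ``merge_cosine`` are therefore
    re-merged (profiles and contributions summed). A single-scan footprint
    degenerates to the apex spectrum.
    """
    region = region_matrix(blob, chrom, noise_floor=noise_floor)
    V = region.V
    if V.shape[1] < 2:
        spec = blob.apex_spectrum or _column_spectrum(V[:, 0], region.mz_axis)
        return [(spec, np.array([1.0]), float(V.sum()))]
    k = int(min(k_max, V.shape[0], V.shape[1]))
    if not np.any(V):
        return []
    result = nmf_frobenius(V, k, tol=tol, max_iter=max_iter)
    contrib = result.W.sum(axis=0) * result.H.sum(axis=1)
    total = float(contrib.sum())
    order = np.argsort(contrib)[::-1]

    interior = None
    if prune_edge:
        foot = blob.footprint
        interior = [
            all(n in foot for n in ((m - 1, s), (m + 1, s), (m, s - 1), (m, s + 1)))
            for m, s in region.cells
        ]
    kept: list[int] = []
    merged_w = {}
    merged_h = {}
    merged_c = {}
    for idx in order:
        if total > 0 and contrib[idx] < prune_fraction * total:
            continue
        if interior is not None:
            j = int(np.argmax(result.H[idx, :]))
            if not interior[j]:
                continue
        w = result.W[:, idx].copy()
        host = next((k for k in kept
                     if _plain_cosine(merged_w[k], w) >= merge_cosine), None)
        if host is not None:
            merged_w[host] += w
            merged_h[host] += result.H[idx, :]
            merged_c[host] += float(contrib[idx])
            continue
        kept.append(idx)
        merged_w[idx] = w
        merged_h[idx] = result.H[idx, :].copy()
        merged_c[idx] = float(contrib[idx])
    out = []
    for idx in sorted(kept, key=lambda k: -merged_c[k]):
        spec = _column_spectrum(merged_w[idx], region.mz_axis)
        if len(spec):
            out.append((spec, merged_h[idx], merged_c[idx]))
    if not out:  # degenerate fallback: keep the dominant component
        idx = int(order[0])
        spec = _column_spectrum(result.W[:, idx], region.mz_axis)
        if len(spec):
            out.append((spec, result.H[idx, :].copy(), float(contrib[idx])))
    return out


def build_layers(blobs, chrom: Chromatogram2D, sample_id: str = "",
                 k_max: int = 4, **kwargs) -> LayerSet:
    """Deconvolve every blob and organise components into layers.

    The i-th ranked component of each blob becomes a :class:`PeakRecord` in
    layer *i* at the blob's retention coordinates; blobs with fewer surviving
    components leave the deeper layers empty.
    """
    layers: dict[int, list[PeakRecord]] = {}
    for bi, blob in enumerate(blobs):
        comps = deconvolve_peak(blob, chrom, k_max=k_max, **kwargs)
        for i, (spec, _profile, _contrib) in enumerate(comps, start=1):
            if i > 4:
                break
            layers.setdefault(i, []).append(PeakRecord(
                sample_id=sample_id,
                layer=i,
                rt1=blob.rt1,
                rt2=blob.rt2,
                apex_spectrum=spec,
                record_id=f"{sample_id}/blob{bi}/layer{i}",
                source_id=f"{sample_id}/blob{bi}",
            ))
    return LayerSet(layers=layers)
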