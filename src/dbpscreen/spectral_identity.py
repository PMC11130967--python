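"""Spectral identity metrics: library match factors, theoretical isotopologue
patterns, isotopic-pattern cosine similarity, and ppm mass accuracy.

The match factor is the 0–999 weighted-cosine score used throughout GC-MS
library searching: intensities are weighted as ``(m/z)^3 * I^0.6``
(Stein–Scott identity weighting) after nominal binning, and the reverse mode
restricts the comparison to m/z bins present in the library spectrum so that
extraneous query peaks (e.g. from co-elution) are ignored.

Isotope patterns are generated by per-element convolution of single-atom
isotope distributions with relative-abundance pruning — the standard
tree-pruned traversal for generating only the relevant isotopologues — and
centroids closer than a merge width (default 0.0005 Da) are combined by
abundance-weighted averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._data import load_isotopes
from .io_core import Formula, MassSpectrum

__all__ = [
    "IsotopePattern",
    "IsotopeFit",
    "match_factor",
    "monoisotopic_mass",
    "isotope_pattern",
    "cosine_isotope_similarity",
    "mass_error_ppm",
]

_MERGE_WIDTH_DA = 0.0005


@dataclass
class IsotopePattern:
    """Theoretical isotopologue masses and abundances for a formula.

    Abundances are percentages of the base (most abundant) isotopologue, so
    the maximum is exactly 100; masses are strictly increasing; every retained
    peak exceeds ``threshold`` (relative to the base peak).
    """

    masses: np.ndarray
    abundances: np.ndarray
    threshold: float = 1e-4

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.masses.size == 0:
            raise ValueError("empty isotope pattern")
        if np.any(np.diff(self.masses) <= 0):
            raise ValueError("isotopologue masses must be strictly increasing")
        if abs(self.abundances.max() - 100.0) > 1e-9:
            raise ValueError("base-peak abundance must be exactly 100")

    def __len__(self) -> int:
        return self.masses.size

    @property
    def monoisotopic(self) -> float:
        return float(self.masses[0])

    def indices(self) -> np.ndarray:
        """Isotopologue index M+k of each peak, k = round(mass - monoisotopic)."""
        return np.round(self.masses - self.monoisotopic).astype(int)


@dataclass
class IsotopeFit:
    """Outcome of comparing a theoretical pattern with observed data.

    ``molecular_ion_status`` is ``appeared``/``faint``/``absent``; cosine and
    ppm error are only defined when the molecular ion was found.
    """

    molecular_ion_status: str
    theoretical_mass: float
    measured_mass: float | None = None
    cosine: float | None = None
    mass_error_ppm: float | None = None

    def __post_init__(self):
        if self.molecular_ion_status not in ("appeared", "faint", "absent"):
            raise ValueError(f"bad status {self.molecular_ion_status!r}")
        if self.cosine is not None and not 0.0 <= self.cosine <= 1.0 + 1e-12:
            raise ValueError("cosine outside [0, 1]")


def _weighted_vector(spec: MassSpectrum, bins: np.ndarray) -> np.ndarray:
    nominal = spec.nominal()
    v = np.zeros(bins.size)
    for i, b in enumerate(bins):
        inten = nominal.get(int(b), 0.0)
        if inten > 0:
            v[i] = (float(b) ** 3) * (inten ** 0.6)
    return v


def match_factor(query: MassSpectrum, library: MassSpectrum,
                 mode: str = "forward") -> int:
    """Weighted-cosine library match factor on the 0–999 scale.

    ``forward`` compares over the union of nominal m/z bins; ``reverse``
    restricts both spectra to the bins present in the library spectrum.
    Identical spectra score 999; disjoint spectra score 0.
    """
    if len(query) == 0 or len(library) == 0:
        raise ValueError("match_factor requires non-empty spectra")
    if mode not in ("forward", "reverse"):
        raise ValueError(f"unknown mode {mode!r}")
    q_bins = set(query.nominal())
    l_bins = set(library.nominal())
    bins = np.array(sorted(l_bins if mode == "reverse" else q_bins | l_bins))
    q = _weighted_vector(query, bins)
    l = _weighted_vector(library, bins)
    nq, nl = np.linalg.norm(q), np.linalg.norm(l)
    if nq == 0 or nl == 0:
        return 0
    cos = float(np.dot(q, l) / (nq * nl))
    return int(round(999 * min(max(cos, 0.0), 1.0)))


def monoisotopic_mass(formula: Formula | str) -> float:
    """Exact mass of the isotopologue built from each element's most
    abundant isotope, from the bundled IUPAC isotope table."""
    if isinstance(formula, str):
        formula = Formula.parse(formula)
    iso = load_isotopes()
    total = 0.0
    for el, n in formula.counts.items():
        masses = iso[el]
        mass, _ = max(masses, key=lambda t: t[1])
        total += n * mass
    return total


def _merge_centroids(masses: np.ndarray, probs: np.ndarray,
                     width: float) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(masses)
    masses, probs = masses[order], probs[order]
    out_m, out_p = [], []
    cur_m, cur_p = masses[0], probs[0]
    for m, p in zip(masses[1:], probs[1:]):
        if m - cur_m <= width:
            tot = cur_p + p
            cur_m = (cur_m * cur_p + m * p) / tot
            cur_p = tot
        else:
            out_m.append(cur_m)
            out_p.append(cur_p)
            cur_m, cur_p = m, p
    out_m.append(cur_m)
    out_p.append(cur_p)
    return np.array(out_m), np.array(out_p)


def isotope_pattern(formula: Formula | str, threshold: float = 1e-4,
                    merge_width: float = _MERGE_WIDTH_DA) -> IsotopePattern:
    """Theoretical isotopologue pattern of ``formula``.

    Convolves single-atom isotope distributions atom by atom, pruning
    isotopologues below ``threshold`` × the current maximum after each step,
    merging centroids within ``merge_width`` Da, and normalising the base
    peak to 100. For a single poly-isotopic element the result equals the
    multinomial closed form.
    """
    if isinstance(formula, str):
        formula = Formula.parse(formula)
    iso = load_isotopes()
    masses = np.array([0.0])
    probs = np.array([1.0])
    # canonical element order so the result is independent of how the
    # formula's element map was built (progressive pruning is order-aware)
    for el in sorted(formula.counts):
        n = formula.counts[el]
        el_m = np.array([m for m, _ in iso[el]])
        el_p = np.array([p for _, p in iso[el]])
        for _ in range(n):
            masses = (masses[:, None] + el_m[None, :]).ravel()
            probs = (probs[:, None] * el_p[None, :]).ravel()
            masses, probs = _merge_centroids(masses, probs, merge_width)
            keep = probs >= threshold * probs.max()
            masses, probs = masses[keep], probs[keep]
    abund = 100.0 * probs / probs.max()
    keep = abund > 100.0 * threshold
    return IsotopePattern(masses[keep], abund[keep], threshold=threshold)


def cosine_isotope_similarity(theoretical: IsotopePattern,
                              observed: IsotopePattern) -> float:
    """Cosine similarity of two isotope patterns aligned on isotopologue
    index M+k, with k = round(mass − theoretical monoisotopic mass) for both
    patterns; indices present in only one pattern contribute zeros, so an
    observed cluster in a different mass region scores 0."""
    anchor = theoretical.monoisotopic
    ti = np.round(theoretical.masses - anchor).astype(int)
    oi = np.round(observed.masses - anchor).astype(int)
    all_idx = sorted(set(ti) | set(oi))
    t = np.zeros(len(all_idx))
    o = np.zeros(len(all_idx))
    pos = {k: i for i, k in enumerate(all_idx)}
    for k, a in zip(ti, theoretical.abundances):
        t[pos[k]] += a
    for k, a in zip(oi, observed.abundances):
        o[pos[k]] += a
    denom = np.linalg.norm(t) * np.linalg.norm(o)
    if denom == 0:
        return 0.0
    return float(np.clip(np.dot(t, o) / denom, 0.0, 1.0))


def mass_error_ppm(theoretical: float, measured: float) -> float:
    """Signed mass error ``(theoretical - measured) / theoretical * 1e6``."""
    if theoretical <= 0 or measured <= 0:
        raise ValueError("masses must be positive")
    return (theoretical - measured) / theoretical * 1e6
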