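"""Domain types and text-format I/O for the GC×GC-TOFMS screening pipeline.

The pipeline exchanges four kinds of on-disk artifacts, all plain text:

* NIST-style MSP spectral libraries (``read_msp`` / ``write_msp``),
* CSV peak tables, the exchange format between screening stages
  (``read_peak_table`` / ``write_peak_table``),
* chromatogram containers, either a sparse long-format CSV or an ``.npz``
  dense array for larger cubes (``load_chromatogram`` / ``save_chromatogram``),
* Abraham-LFER configuration tables holding solute descriptors and phase
  system coefficients (``read_lser_table``).

Conventions: first-dimension retention ``rt1`` is in minutes, second-dimension
retention ``rt2`` in seconds (within the modulation period); the m/z axis of a
:class:`Chromatogram2D` is nominal (1 Da integer bins).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUPPORTED_ELEMENTS = ("C", "H", "N", "O", "S", "P", "Si", "F", "Cl", "Br", "I")

_CAS_RE = re.compile(r"^\d{2,7}-\d{2}-\d$")
_FORMULA_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class MSPParseError(ValueError):
    """Raised when an MSP library entry violates the dialect contract."""


class PeakTableError(ValueError):
    """Raised when a peak-table CSV fails validation."""


# ---------------------------------------------------------------------------
# Mass spectra and molecular formulas
# ---------------------------------------------------------------------------


class MassSpectrum:
    """A centroided mass spectrum: (m/z, intensity) pairs sorted by m/z.

    Invariants: m/z strictly increasing, intensities non-negative, non-empty
    unless constructed with ``allow_empty=True``. Duplicate m/z values are
    merged by summing intensities.
    """

    __slots__ = ("mz", "intensity")

    def __init__(self, mz, intensity, *, allow_empty: bool = False):
        mz = np.asarray(mz, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        if mz.shape != intensity.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size == 0 and not allow_empty:
            raise ValueError("empty spectrum (pass allow_empty=True to permit)")
        if np.any(intensity < 0):
            raise ValueError("negative intensity in spectrum")
        if mz.size:
            order = np.argsort(mz, kind="stable")
            mz, intensity = mz[order], intensity[order]
            if np.any(np.diff(mz) == 0):  # merge duplicate m/z
                uniq, inv = np.unique(mz, return_inverse=True)
                summed = np.zeros_like(uniq)
                np.add.at(summed, inv, intensity)
                mz, intensity = uniq, summed
        self.mz = mz
        self.intensity = intensity

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, float]], **kw) -> "MassSpectrum":
        pairs = list(pairs)
        if pairs:
            mz, inten = zip(*pairs)
        else:
            mz, inten = (), ()
        return cls(np.array(mz, float), np.array(inten, float), **kw)

    def __len__(self) -> int:
        return self.mz.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, MassSpectrum):
            return NotImplemented
        return np.array_equal(self.mz, other.mz) and np.array_equal(
            self.intensity, other.intensity
        )

    def __repr__(self) -> str:
        return f"MassSpectrum(n={len(self)})"

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self) else 0.0

    def nominal(self) -> dict[int, float]:
        """Bin to nominal (integer) m/z, summing intensities per bin."""
        bins: dict[int, float] = {}
        for m, i in zip(self.mz, self.intensity):
            b = int(round(m))
            bins[b] = bins.get(b, 0.0) + float(i)
        return bins


@dataclass(frozen=True)
class Formula:
    """A molecular formula over the supported element set."""

    counts: Mapping[str, int]

    def __post_init__(self):
        counts = dict(self.counts)
        for el, n in counts.items():
            if el not in SUPPORTED_ELEMENTS:
                raise ValueError(f"unsupported element {el!r}")
            if not isinstance(n, (int, np.integer)) or n <= 0:
                raise ValueError(f"element count must be a positive integer: {el}={n}")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a Hill-style formula string such as ``'C2HBr3O'``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN_RE.finditer(text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            pos = m.end()
            el, num = m.group(1), m.group(2)
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        if pos != len(text) or not counts:
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical
        keys = sorted(
            self.counts, key=lambda e: (e != "C", e != "H", e)
        )
        return "".join(
            f"{el}{self.counts[el] if self.counts[el] > 1 else ''}" for el in keys
        )


# ---------------------------------------------------------------------------
# Chromatograms
# ---------------------------------------------------------------------------


@dataclass
class Chromatogram2D:
    """A GC×GC-TOFMS data cube indexed ``[modulation][scan][mz_bin]``.

    ``modulation_period`` is in seconds, ``scan_rate`` in Hz, the m/z axis is
    nominal with contiguous integer bins from ``mz_start`` to ``mz_end``
    inclusive, and ``acquisition_start`` (minutes) offsets the rt1 axis.
    """

    data: np.ndarray
    modulation_period: float
    scan_rate: float
    mz_start: int
    mz_end: int
    acquisition_start: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("chromatogram cube must be 3-D with all dims >= 1")
        expected_scans = int(round(self.modulation_period * self.scan_rate))
        if self.data.shape[1] != expected_scans:
            raise ValueError(
                f"intra-modulation scan count {self.data.shape[1]} != "
                f"round(modulation_period x scan_rate) = {expected_scans}"
            )
        n_mz = self.mz_end - self.mz_start + 1
        if self.data.shape[2] != n_mz:
            raise ValueError(
                f"m/z bin count {self.data.shape[2]} != {n_mz} implied by "
                f"[{self.mz_start}, {self.mz_end}]"
            )

    @property
    def n_modulations(self) -> int:
        return self.data.shape[0]

    @property
    def n_scans(self) -> int:
        return self.data.shape[1]

    @property
    def mz_axis(self) -> np.ndarray:
        return np.arange(self.mz_start, self.mz_end + 1)

    def rt1_of(self, mod_idx) -> np.ndarray | float:
        """First-dimension retention (minutes) of a modulation index."""
        return self.acquisition_start + np.asarray(mod_idx) * self.modulation_period / 60.0

    def rt2_of(self, scan_idx) -> np.ndarray | float:
        """Second-dimension retention (seconds) of an intra-modulation scan."""
        return np.asarray(scan_idx) / self.scan_rate

    def tic_image(self) -> np.ndarray:
        """Total-ion-current image (modulation × scan)."""
        return self.data.sum(axis=2)

    def spectrum_at(self, mod_idx: int, scan_idx: int) -> MassSpectrum:
        """Nominal-m/z spectrum at one cell, zero bins dropped."""
        slice_ = np.asarray(self.data[mod_idx, scan_idx], dtype=float)
        keep = slice_ > 0
        if not keep.any():
            return MassSpectrum(np.array([]), np.array([]), allow_empty=True)
        return MassSpectrum(self.mz_axis[keep].astype(float), slice_[keep])


def save_chromatogram(chrom: Chromatogram2D, path: str | Path) -> None:
    """Write a chromatogram container.

    ``.csv`` → sparse long format (zero cells omitted) with a commented
    metadata header; anything else → NumPy ``.npz`` with a metadata record.
    """
    path = Path(path)
    meta = dict(
        modulation_period_s=chrom.modulation_period,
        scan_rate_hz=chrom.scan_rate,
        mz_start=chrom.mz_start,
        mz_end=chrom.mz_end,
        acquisition_start_min=chrom.acquisition_start,
        n_modulations=chrom.n_modulations,
    )
    if path.suffix.lower() == ".csv":
        idx = np.nonzero(chrom.data)
        with open(path, "w", encoding="utf-8") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
            fh.write("mod_idx,scan_idx,mz_bin,intensity\n")
            mz_axis = chrom.mz_axis
            vals = chrom.data[idx]
            for i, j, k, v in zip(*idx, vals):
                fh.write(f"{i},{j},{mz_axis[k]},{float(v)!r}\n")
    else:
        np.savez_compressed(
            path,
            data=chrom.data,
            meta=np.array([list(meta.values())], dtype=float),
        )


def load_chromatogram(path: str | Path) -> Chromatogram2D:
    """Read a chromatogram container written by :func:`save_chromatogram`.

    Negative intensities load successfully (they are flagged for baseline
    correction downstream); a metadata/shape mismatch is an error.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        meta: dict[str, float] = {}
        with open(path, encoding="utf-8") as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = float(val)
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            table = pd.read_csv(fh)
        required = {"modulation_period_s", "scan_rate_hz", "mz_start", "mz_end", "n_modulations"}
        if not required <= meta.keys():
            raise ValueError(f"missing chromatogram metadata: {sorted(required - meta.keys())}")
        n_mod = int(meta["n_modulations"])
        n_scan = int(round(meta["modulation_period_s"] * meta["scan_rate_hz"]))
        mz_start, mz_end = int(meta["mz_start"]), int(meta["mz_end"])
        cube = np.zeros((n_mod, n_scan, mz_end - mz_start + 1), dtype=np.float32)
        mod = table["mod_idx"].to_numpy(int)
        scan = table["scan_idx"].to_numpy(int)
        mzb = table["mz_bin"].to_numpy(int)
        if len(table) and (
            mod.max() >= n_mod or scan.max() >= n_scan
            or mzb.min() < mz_start or mzb.max() > mz_end
        ):
            raise ValueError("chromatogram CSV indices inconsistent with metadata")
        cube[mod, scan, mzb - mz_start] = table["intensity"].to_numpy(np.float32)
        return Chromatogram2D(
            cube,
            meta["modulation_period_s"],
            meta["scan_rate_hz"],
            mz_start,
            mz_end,
            meta.get("acquisition_start_min", 0.0),
        )
    with np.load(path) as npz:
        data = npz["data"]
        period, rate, mz_start, mz_end, acq, n_mod = npz["meta"][0]
    if data.shape[0] != int(n_mod):
        raise ValueError("chromatogram npz shape inconsistent with metadata")
    return Chromatogram2D(data, float(period), float(rate), int(mz_start), int(mz_end), float(acq))


# ---------------------------------------------------------------------------
# Peak records and tables
# ---------------------------------------------------------------------------


@dataclass
class PeakRecord:
    """One detected (or deconvolved) peak.

    ``layer`` 0 denotes the raw chromatogram; 1–4 are NMF layers. Retention
    coordinates are rt1 in minutes and rt2 in seconds. ``flags`` carries
    free-form markers such as ``layer_only`` (peak absent from the raw
    chromatogram) or ``extrapolated``.
    """

    sample_id: str = ""
    layer: int = 0
    rt1: float = 0.0
    rt2: float = 0.0
    apex_spectrum: MassSpectrum | None = None
    hit_name: str | None = None
    hit_cas: str | None = None
    match_factor: int | None = None
    reverse_match_factor: int | None = None
    flags: set[str] = field(default_factory=set)
    record_id: str | None = None
    source_id: str | None = None  # provenance: id of the originating raw record

    def __post_init__(self):
        if not 0 <= self.layer <= 4:
            raise ValueError(f"layer must be in 0..4, got {self.layer}")
        for name, v in (("match_factor", self.match_factor),
                        ("reverse_match_factor", self.reverse_match_factor)):
            if v is not None and not 0 <= v <= 999:
                raise PeakTableError(f"{name} outside 0-999: {v}")
        if self.hit_cas is not None and self.hit_cas and not _CAS_RE.match(self.hit_cas):
            logger.debug("CAS %r does not match NN..-NN-N pattern", self.hit_cas)
        self.flags = set(self.flags)


PEAK_TABLE_COLUMNS = ["id", "sample_id", "rt1_min", "rt2_s", "name", "cas",
                      "mf", "rmf", "layer", "flags"]


def read_peak_table(path: str | Path) -> list[PeakRecord]:
    """Read a peak-table CSV into :class:`PeakRecord` rows.

    Blank optional fields become ``None``; a match factor outside 0–999 raises
    :class:`PeakTableError`.
    """
    df = pd.read_csv(path, dtype={"flags": str, "name": str, "cas": str, "sample_id": str})
    records = []
    for _, row in df.iterrows():
        def _opt(key):
            v = row.get(key)
            if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
                return None
            return v

        mf, rmf = _opt("mf"), _opt("rmf")
        flags = _opt("flags")
        records.append(
            PeakRecord(
                sample_id=str(_opt("sample_id") or ""),
                layer=int(row.get("layer", 0) if not pd.isna(row.get("layer", 0)) else 0),
                rt1=float(row["rt1_min"]),
                rt2=float(row["rt2_s"]),
                hit_name=_opt("name"),
                hit_cas=_opt("cas"),
                match_factor=int(mf) if mf is not None else None,
                reverse_match_factor=int(rmf) if rmf is not None else None,
                flags=set(str(flags).split(";")) if flags else set(),
                record_id=str(_opt("id")) if _opt("id") is not None else None,
            )
        )
    return records


def write_peak_table(records: Iterable[PeakRecord], path: str | Path) -> None:
    rows = []
    for i, r in enumerate(records, start=1):
        rows.append(
            dict(
                id=r.record_id if r.record_id is not None else i,
                sample_id=r.sample_id,
                rt1_min=r.rt1,
                rt2_s=r.rt2,
                name=r.hit_name,
                cas=r.hit_cas,
                mf=r.match_factor,
                rmf=r.reverse_match_factor,
                layer=r.layer,
                flags=";".join(sorted(r.flags)) if r.flags else None,
            )
        )
    pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# MSP spectral libraries
# ---------------------------------------------------------------------------


@dataclass
class LibraryEntry:
    """One reference spectrum of an MSP library."""

    name: str
    spectrum: MassSpectrum
    cas: str | None = None
    formula: Formula | None = None
    comments: list[str] = field(default_factory=list)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LibraryEntry):
            return NotImplemented
        return (
            self.name == other.name
            and self.cas == other.cas
            and self.spectrum == other.spectrum
        )


def read_msp(path: str | Path) -> list[LibraryEntry]:
    """Parse a NIST-dialect MSP library.

    Honoured keys: ``Name:``, ``CAS#:``, ``Formula:``, ``Num Peaks:``; any
    other ``Key: value`` line is preserved verbatim in ``entry.comments`` so a
    write/read round trip is the identity. After ``Num Peaks: n`` exactly *n*
    m/z–intensity pairs must follow (whitespace- or semicolon-separated);
    a count mismatch raises :class:`MSPParseError` naming the entry.
    """
    entries: list[LibraryEntry] = []
    name = cas = formula = None
    comments: list[str] = []
    pairs: list[tuple[float, float]] = []
    declared: int | None = None

    def _flush(line_no: int):
        nonlocal name, cas, formula, comments, pairs, declared
        if name is None and declared is None:
            return
        label = name or f"<entry #{len(entries) + 1}>"
        if declared is None:
            raise MSPParseError(f"entry {label!r}: missing 'Num Peaks:'")
        if len(pairs) != declared:
            raise MSPParseError(
                f"entry {label!r}: declared Num Peaks: {declared} but found {len(pairs)} pairs"
            )
        entries.append(
            LibraryEntry(
                name=label,
                cas=cas,
                formula=Formula.parse(formula) if formula else None,
                spectrum=MassSpectrum.from_pairs(pairs),
                comments=list(comments),
            )
        )
        name = cas = formula = None
        comments, pairs, declared = [], [], None

    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                _flush(line_no)
                continue
            lower = line.lower()
            if lower.startswith("name:"):
                if name is not None or declared is not None:
                    _flush(line_no)
                name = line[5:].strip()
            elif lower.startswith("cas#:"):
                cas = line[5:].strip() or None
            elif lower.startswith("formula:"):
                formula = line[8:].strip() or None
            elif lower.startswith("num peaks:"):
                try:
                    declared = int(line[10:].strip())
                except ValueError as exc:
                    raise MSPParseError(
                        f"entry {name!r}: malformed Num Peaks line {line!r}"
                    ) from exc
            elif declared is not None:
                tokens = line.replace(";", " ").split()
                if len(tokens) % 2:
                    raise MSPParseError(
                        f"entry {name!r}: odd token count in peak line {line!r}"
                    )
                for mz_s, int_s in zip(tokens[::2], tokens[1::2]):
                    pairs.append((float(mz_s), float(int_s)))
            else:
                comments.append(line)
        _flush(-1)
    return entries


def write_msp(entries: Iterable[LibraryEntry], path: str | Path) -> None:
    """Write entries in the MSP dialect read by :func:`read_msp`.

    Intensities are written with full ``repr`` precision so the round trip is
    exact; unknown-key comment lines are replayed verbatim.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for e in entries:
            fh.write(f"Name: {e.name}\n")
            if e.cas:
                fh.write(f"CAS#: {e.cas}\n")
            if e.formula is not None:
                fh.write(f"Formula: {e.formula}\n")
            for c in e.comments:
                fh.write(c.rstrip("\n") + "\n")
            fh.write(f"Num Peaks: {len(e.spectrum)}\n")
            for m, i in zip(e.spectrum.mz, e.spectrum.intensity):
                fh.write(f"{float(m)!r} {float(i)!r}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Abraham LFER configuration tables
# ---------------------------------------------------------------------------


def read_lser_table(path: str | Path):
    """Read a combined Abraham-LFER configuration CSV.

    The file mixes solute rows (``kind=solute`` with columns E,S,A,B,L and an
    optional ``provenance``) and phase rows (``kind=phase`` with coefficients
    c,e,s,a,b,l). Lines starting with ``#`` are comments. Returns
    ``(solutes, phases)`` as name-keyed dicts of
    :class:`~dbpscreen.retention_modeling.AbrahamSolute` and
    :class:`~dbpscreen.retention_modeling.PhaseSystem`. A solute row missing a
    descriptor is skipped with a warning; duplicate names are an error.
    """
    from .retention_modeling import AbrahamSolute, PhaseSystem
    from ._data import load_alkane_l

    df = pd.read_csv(path, comment="#")
    solutes: dict[str, AbrahamSolute] = {}
    phases: dict[str, PhaseSystem] = {}
    alkanes = load_alkane_l()
    for _, row in df.iterrows():
        name = str(row["name"])
        kind = str(row["kind"]).strip().lower()
        if name in solutes or name in phases:
            raise ValueError(f"duplicate LSER entry name {name!r}")
        if kind == "solute":
            vals = [row.get(c) for c in ("E", "S", "A", "B", "L")]
            if any(v is None or pd.isna(v) for v in vals):
                logger.warning("solute %r skipped: incomplete descriptors", name)
                continue
            prov = row.get("provenance")
            solutes[name] = AbrahamSolute(
                *map(float, vals),
                provenance=str(prov) if prov is not None and not pd.isna(prov) else "estimated",
            )
        elif kind == "phase":
            vals = [row.get(c) for c in ("c", "e", "s", "a", "b", "l")]
            if any(v is None or pd.isna(v) for v in vals):
                logger.warning("phase %r skipped: incomplete coefficients", name)
                continue
            phases[name] = PhaseSystem(name, *map(float, vals), alkane_l=dict(alkanes))
        else:
            raise ValueError(f"unknown LSER row kind {kind!r} for {name!r}")
    return solutes, phases
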