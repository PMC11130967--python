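"""Ground-truthed synthetic GC×GC-TOFMS chromatograms and six-sampler
study designs.

The generator emulates the passive-sampler study layout the screening funnel
assumes: two field blanks, two pre-chlorination replicates and two
post-chlorination replicates, with spiked disinfection byproducts (DBPs)
present only post-chlorination, background compounds present pre and post,
and a configurable subset of background compounds also present in the blanks.
Each compound is placed as a separable two-dimensional Gaussian in
(rt1, rt2), multiplied across m/z by its fragment spectrum; a flat baseline
plus zero-truncated Gaussian noise is added. Replicates share compound truth
but draw independent noise.

Instrument defaults mirror a typical modulated TOF acquisition: 6.5 s
modulation period, 50 Hz scan rate, nominal m/z 33–800, at a desk-scale run
length of 12 min.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_core import Chromatogram2D, Formula, LibraryEntry, MassSpectrum
from .spectral_identity import isotope_pattern, monoisotopic_mass

__all__ = [
    "TruthCompound",
    "StudyDesign",
    "generate_spectrum",
    "generate_chromatogram",
    "generate_study",
    "truth_library",
]

SAMPLER_ROLES = ("blank", "pre", "post")

# name -> formula palettes for spiked DBPs and for the sampler background
DBP_PALETTE = [
    ("tribromoacetaldehyde", "C2HBr3O"),
    ("chlorodibromoacetaldehyde", "C2HBr2ClO"),
    ("bromodichloroacetaldehyde", "C2HBrCl2O"),
    ("1,1,3-trichloroacetone", "C3H3Cl3O"),
    ("dibromoacetonitrile", "C2HBr2N"),
    ("2,4-dichlorophenol", "C6H4Cl2O"),
    ("tribromomethane", "CHBr3"),
    ("dichloroacetonitrile", "C2HCl2N"),
    ("4-chlorophenol", "C6H5ClO"),
    ("2,4,6-tribromophenol", "C6H3Br3O"),
]
BACKGROUND_PALETTE = [
    ("n-undecane", "C11H24"),
    ("toluene", "C7H8"),
    ("naphthalene", "C10H8"),
    ("methyl decanoate", "C11H22O2"),
    ("phenol", "C6H6O"),
    ("benzaldehyde", "C7H6O"),
    ("limonene", "C10H16"),
    ("nonanal", "C9H18O"),
    ("n-tridecane", "C13H28"),
    ("diethyl phthalate", "C12H14O4"),
    ("n-pentadecane", "C15H32"),
    ("acetophenone", "C8H8O"),
    ("styrene", "C8H8"),
    ("decamethylcyclopentasiloxane", "C10H30O5Si5"),
    ("n-heptadecane", "C17H36"),
    ("indole", "C8H7N"),
    ("benzothiazole", "C7H5NS"),
    ("2-ethylhexanol", "C8H18O"),
    ("n-nonadecane", "C19H40"),
    ("dibutyl phthalate", "C16H22O4"),
]


@dataclass
class TruthCompound:
    """Ground-truth placement of one compound in the study."""

    name: str
    formula: Formula
    rt1: float          # min
    rt2: float          # s
    spectrum: MassSpectrum
    amplitude: float    # apex intensity of the base-peak channel, a.u.
    sigma1: float       # min
    sigma2: float       # s
    membership: frozenset[str] = frozenset({"post"})

    def __post_init__(self):
        if self.sigma1 <= 0 or self.sigma2 <= 0 or self.amplitude <= 0:
            raise ValueError("sigma1, sigma2 and amplitude must be positive")
        if not set(self.membership) <= set(SAMPLER_ROLES):
            raise ValueError(f"membership outside {SAMPLER_ROLES}")


@dataclass
class StudyDesign:
    """Compound list plus instrument and noise settings for one study."""

    compounds: list[TruthCompound]
    seed: int = 0
    noise_sd: float = 3.0
    baseline_level: float = 20.0
    modulation_period: float = 6.5   # s
    scan_rate: float = 50.0          # Hz
    mz_start: int = 33
    mz_end: int = 800
    run_minutes: float = 12.0
    acquisition_start: float = 0.0

    @property
    def n_modulations(self) -> int:
        return int(round(self.run_minutes * 60.0 / self.modulation_period))

    def validate(self):
        for c in self.compounds:
            if not (self.acquisition_start <= c.rt1
                    <= self.acquisition_start + self.run_minutes):
                raise ValueError(f"{c.name}: rt1 outside acquisition window")
            if not 0 <= c.rt2 < self.modulation_period:
                raise ValueError(f"{c.name}: rt2 outside modulation period")


def generate_spectrum(formula: Formula | str, n_fragments: int = 8,
                      seed: int = 0, mz_min: int = 33) -> MassSpectrum:
    """A plausible EI fragment spectrum for ``formula``.

    ``n_fragments`` fragment ions are drawn at integer m/z below the
    monoisotopic mass with random intensities (base peak 100); the
    molecular-ion cluster is appended at the exact isotopologue masses of the
    formula's theoretical pattern, scaled to a random 10–60 relative height.
    Deterministic under a fixed seed.
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    if isinstance(formula, str):
        formula = Formula.parse(formula)
    mono = monoisotopic_mass(formula)
    if mono < mz_min + 1:
        raise ValueError("formula mass below the lowest m/z bin")
    rng = np.random.default_rng(seed)
    lo, hi = mz_min, int(mono) - 1
    n_avail = hi - lo + 1
    k = min(n_fragments, n_avail)
    frag_mz = rng.choice(np.arange(lo, hi + 1), size=k, replace=False).astype(float)
    frag_int = rng.uniform(5.0, 100.0, size=k)
    frag_int[rng.integers(k)] = 100.0  # force a base fragment
    pattern = isotope_pattern(formula, threshold=1e-3)
    mol_scale = rng.uniform(10.0, 60.0) / 100.0
    mz = np.concatenate([frag_mz, pattern.masses])
    inten = np.concatenate([frag_int, pattern.abundances * mol_scale])
    return MassSpectrum(mz, inten)


def truth_library(compounds) -> list[LibraryEntry]:
    """Reference library built from the clean truth spectra."""
    seen = {}
    for c in compounds:
        seen.setdefault(c.name, LibraryEntry(name=c.name, spectrum=c.spectrum,
                                             formula=c.formula))
    return list(seen.values())


def generate_chromatogram(design: StudyDesign, sampler_role: str,
                          noise_seed: int | None = None
                          ) -> tuple[Chromatogram2D, list[TruthCompound]]:
    """Render the cube for one sampler role.

    Only compounds whose membership includes ``sampler_role`` are placed.
    Returns the chromatogram and the list of placed compounds.
    """
    if sampler_role not in SAMPLER_ROLES:
        raise ValueError(f"sampler_role must be one of {SAMPLER_ROLES}")
    design.validate()
    n_mod = design.n_modulations
    n_scan = int(round(design.modulation_period * design.scan_rate))
    n_mz = design.mz_end - design.mz_start + 1
    cube = np.zeros((n_mod, n_scan, n_mz), dtype=np.float32)

    rt1_axis = design.acquisition_start + np.arange(n_mod) * design.modulation_period / 60.0
    rt2_axis = np.arange(n_scan) / design.scan_rate

    members = [c for c in design.compounds if sampler_role in c.membership]
    for c in members:
        g1 = np.exp(-0.5 * ((rt1_axis - c.rt1) / c.sigma1) ** 2)
        g2 = np.exp(-0.5 * ((rt2_axis - c.rt2) / c.sigma2) ** 2)
        i1 = np.nonzero(g1 > 1e-6)[0]
        i2 = np.nonzero(g2 > 1e-6)[0]
        if i1.size == 0 or i2.size == 0:
            continue
        # base peak channel reaches `amplitude` at the apex
        spec_rel = c.spectrum.intensity / c.spectrum.base_peak_intensity
        bins = np.round(c.spectrum.mz).astype(int) - design.mz_start
        ok = (bins >= 0) & (bins < n_mz)
        chan = np.zeros(n_mz)
        np.add.at(chan, bins[ok], c.amplitude * spec_rel[ok])
        patch = g1[i1][:, None, None] * g2[i2][None, :, None] * chan[None, None, :]
        cube[np.ix_(i1, i2)] += patch.astype(np.float32)

    if design.baseline_level > 0 or design.noise_sd > 0:
        rng = np.random.default_rng(design.seed if noise_seed is None else noise_seed)
        noise = rng.normal(design.baseline_level, design.noise_sd, size=cube.shape)
        cube += np.maximum(noise, 0.0).astype(np.float32)

    chrom = Chromatogram2D(
        cube,
        design.modulation_period,
        design.scan_rate,
        design.mz_start,
        design.mz_end,
        design.acquisition_start,
    )
    return chrom, members


def _place_compounds(rng, palette, n, run_minutes, period, start, used, sig1_rng,
                     sig2_rng, amp_rng, min_sep=4.0):
    """Draw non-colliding (rt1, rt2) placements; returns raw placement dicts."""
    placements = []
    lo1 = start + 0.8
    hi1 = start + run_minutes - 0.8
    lo2, hi2 = 0.4, period - 1.0
    for i in range(n):
        name, formula = palette[i % len(palette)]
        if i >= len(palette):
            name = f"{name} ({i // len(palette) + 1})"
        s1 = rng.uniform(*sig1_rng)
        s2 = rng.uniform(*sig2_rng)
        for _ in range(200):
            rt1 = rng.uniform(lo1, hi1)
            rt2 = rng.uniform(lo2, hi2)
            if all(
                abs(rt1 - u1) / max(s1, us1) > min_sep
                or abs(rt2 - u2) / max(s2, us2) > min_sep
                for (u1, u2, us1, us2) in used
            ):
                break
        used.append((rt1, rt2, s1, s2))
        placements.append(dict(name=name, formula=formula, rt1=rt1, rt2=rt2,
                               sigma1=s1, sigma2=s2,
                               amplitude=rng.uniform(*amp_rng)))
    return placements


def generate_study(
    n_dbps: int,
    n_background: int = 15,
    overlap_fraction: float = 0.0,
    seed: int = 0,
    blank_fraction: float = 0.3,
    noise_sd: float = 3.0,
    baseline_level: float = 20.0,
    **instrument,
):
    """Build the six-sampler study: two blanks, two pre- and two
    post-chlorination replicates.

    ``n_dbps`` spiked DBPs appear only in the post replicates;
    ``n_background`` compounds appear pre and post, with a ``blank_fraction``
    subset also present in the blanks; ``overlap_fraction`` of the DBPs is
    placed to co-elute with a background compound (|Δrt1| < σ1, |Δrt2| < σ2)
    to exercise spectral deconvolution.

    Returns ``(samplers, truth)`` where ``samplers`` is a list of six
    ``(sampler_id, Chromatogram2D)`` pairs (blank1, blank2, pre1, pre2,
    post1, post2) and ``truth`` the list of :class:`TruthCompound`.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    if n_dbps < 0 or n_background < 0:
        raise ValueError("compound counts must be non-negative")
    rng = np.random.default_rng(seed)
    design = StudyDesign(compounds=[], seed=seed, noise_sd=noise_sd,
                         baseline_level=baseline_level, **instrument)

    sig1_rng = (0.15, 0.25)   # min
    sig2_rng = (0.25, 0.45)   # s
    amp_rng = (400.0, 3000.0)
    used: list[tuple[float, float, float, float]] = []
    bg = _place_compounds(rng, BACKGROUND_PALETTE, n_background,
                          design.run_minutes, design.modulation_period,
                          design.acquisition_start, used, sig1_rng, sig2_rng, amp_rng)
    dbp = _place_compounds(rng, DBP_PALETTE, n_dbps,
                           design.run_minutes, design.modulation_period,
                           design.acquisition_start, used, sig1_rng, sig2_rng, amp_rng)

    n_overlap = int(round(overlap_fraction * n_dbps))
    if n_overlap > 0 and not bg:
        raise ValueError("overlap requested but no background compounds")
    partners = rng.choice(len(bg), size=n_overlap, replace=n_overlap > len(bg))
    for d, p in zip(dbp[:n_overlap], partners):
        host = bg[int(p)]
        d["rt1"] = host["rt1"] + 0.8 * min(d["sigma1"], host["sigma1"]) * rng.choice([-1, 1])
        d["rt2"] = host["rt2"] + 0.8 * min(d["sigma2"], host["sigma2"]) * rng.choice([-1, 1])
        d["rt1"] = float(np.clip(d["rt1"], design.acquisition_start + 0.3,
                                 design.acquisition_start + design.run_minutes - 0.3))
        d["rt2"] = float(np.clip(d["rt2"], 0.05, design.modulation_period - 0.05))

    n_blank = int(round(blank_fraction * n_background))
    blank_idx = set(rng.choice(n_background, size=n_blank, replace=False)) if n_blank else set()

    compounds: list[TruthCompound] = []
    for i, plc in enumerate(bg):
        member = {"pre", "post"} | ({"blank"} if i in blank_idx else set())
        spec = generate_spectrum(plc["formula"], n_fragments=8,
                                 seed=int(rng.integers(2**31)),
                                 mz_min=design.mz_start)
        compounds.append(TruthCompound(
            name=plc["name"], formula=Formula.parse(plc["formula"]),
            rt1=plc["rt1"], rt2=plc["rt2"], spectrum=spec,
            amplitude=plc["amplitude"], sigma1=plc["sigma1"], sigma2=plc["sigma2"],
            membership=frozenset(member)))
    for plc in dbp:
        spec = generate_spectrum(plc["formula"], n_fragments=8,
                                 seed=int(rng.integers(2**31)),
                                 mz_min=design.mz_start)
        compounds.append(TruthCompound(
            name=plc["name"], formula=Formula.parse(plc["formula"]),
            rt1=plc["rt1"], rt2=plc["rt2"], spectrum=spec,
            amplitude=plc["amplitude"], sigma1=plc["sigma1"], sigma2=plc["sigma2"],
            membership=frozenset({"post"})))

    design = replace(design, compounds=compounds)
    samplers = []
    for role in ("blank", "blank", "pre", "pre", "post", "post"):
        noise_seed = int(rng.integers(2**31))
        chrom, _ = generate_chromatogram(design, role, noise_seed=noise_seed)
        idx = sum(1 for sid, _ in samplers if sid.startswith(role)) + 1
        samplers.append((f"{role}{idx}", chrom))
    return samplers, compounds
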