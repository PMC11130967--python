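"""The eight-filter sequential screen over layered peak tables.

The funnel mirrors a suspect-screening workflow for disinfection byproducts:

1. **Blank correction** – remove peaks matching any field-blank peak.
2. **Replicate consistency** – keep peaks detected in both replicates.
3. **Chlorination differential** – remove peaks present pre-chlorination.
4. **Optimal peak selection** – of a peak found in several layers (or the
   raw chromatogram), keep only the record with the highest match factor.
5. **Spectral confirmation** – drop records with match factor < 800.
6. **Isotopologue fit** – annotate cosine similarity of theoretical vs
   observed isotope pattern and ppm mass error.
7. **Retention-index fit** – annotate dI = calculated − reference Kováts
   index on the first-dimension phase.
8. **Elution-space concordance** – Procrustes disparity and per-dimension
   correlations between predicted (I1, u2) and observed (rt1, rt2).

Filters 1–5 remove records; filters 6–8 default to annotation only
(confidence evidence), matching the use of the screen as a candidate
isolator followed by orthogonal confirmation. Every stage's in/out/removed
counts are recorded in a conservation-checked :class:`FunnelReport`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_core import (Chromatogram2D, Formula, LibraryEntry, MassSpectrum,
                      PeakRecord, write_msp, write_peak_table)
from .nmf_deconvolution import build_layers
from .peak_detection import correct_baseline, detect_peaks
from .retention_modeling import (AbrahamSolute, ConcordanceReport, ElutionPoint,
                                 PhaseSystem, RIComparison, kovats_index,
                                 predict_elution_point, procrustes_concordance)
from .spectral_identity import (IsotopeFit, IsotopePattern,
                                cosine_isotope_similarity, isotope_pattern,
                                mass_error_ppm, match_factor, monoisotopic_mass)

logger = logging.getLogger(__name__)

__all__ = [
    "MatchTolerance",
    "FunnelReport",
    "CandidateDBP",
    "WorkflowConfig",
    "WorkflowResult",
    "records_match",
    "set_filter",
    "select_best_layer",
    "filter_match_threshold",
    "annotate_isotope_fit",
    "annotate_ri_fit",
    "evaluate_elution_concordance",
    "identify_compounds",
    "run_workflow",
]


@dataclass
class MatchTolerance:
    """Cross-sample peak matching rule.

    Two records match when their retention differences are within tolerance
    and either their library hit names agree (when ``require_same_name`` and
    both are named) or their apex spectra score at least ``spectral_floor``.
    Records carrying the *same* library identity additionally match inside a
    window widened by ``name_window_scale``: a confident shared identity is
    stronger evidence than retention alone, and deconvolved components of a
    compound's tail can surface a few peak-widths from its apex.
    """

    rt1_tol: float = 0.25       # min
    rt2_tol: float = 0.15       # s
    require_same_name: bool = True
    spectral_floor: int = 700   # MF units
    name_window_scale: float = 4.0

    def __post_init__(self):
        if self.rt1_tol <= 0 or self.rt2_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.name_window_scale < 1:
            raise ValueError("name_window_scale must be >= 1")


@dataclass
class FunnelStage:
    name: str
    n_in: int
    n_out: int

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_out


@dataclass
class FunnelReport:
    """Ordered per-filter accounting; conservation is enforced on append."""

    stages: list[FunnelStage] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {name}: n_out {n_out} > n_in {n_in}")
        if self.stages and self.stages[-1].n_out != n_in:
            raise ValueError(
                f"stage {name}: n_in {n_in} != previous n_out {self.stages[-1].n_out}"
            )
        self.stages.append(FunnelStage(name, n_in, n_out))

    def to_dict(self) -> list[dict]:
        return [
            dict(filter=s.name, n_in=s.n_in, n_out=s.n_out, n_removed=s.n_removed)
            for s in self.stages
        ]


@dataclass
class CandidateDBP:
    """A screened candidate: the surviving peak record plus the orthogonal
    confidence evidence of filters 6–8 (tri-state flags: True/False/None)."""

    record: PeakRecord
    formula: Formula | None = None
    isotope_fit: IsotopeFit | None = None
    ri_comparison: RIComparison | None = None
    elution_point: ElutionPoint | None = None
    isotope_ok: bool | None = None
    ri_ok: bool | None = None
    elution_ok: bool | None = None


def records_match(a: PeakRecord, b: PeakRecord, tol: MatchTolerance) -> bool:
    """Cross-sample/cross-layer identity test for two peak records."""
    d1, d2 = abs(a.rt1 - b.rt1), abs(a.rt2 - b.rt2)
    if a.hit_name and b.hit_name and a.hit_name == b.hit_name:
        scale = tol.name_window_scale
        return d1 <= scale * tol.rt1_tol and d2 <= scale * tol.rt2_tol
    if d1 > tol.rt1_tol or d2 > tol.rt2_tol:
        return False
    if tol.require_same_name and a.hit_name and b.hit_name:
        return a.hit_name == b.hit_name
    if a.apex_spectrum is not None and b.apex_spectrum is not None \
            and len(a.apex_spectrum) and len(b.apex_spectrum):
        return match_factor(a.apex_spectrum, b.apex_spectrum) >= tol.spectral_floor
    if a.hit_name and b.hit_name:
        return a.hit_name == b.hit_name
    return True  # retention agreement is all the evidence available


def set_filter(primary: list[PeakRecord], reference: list[PeakRecord],
               mode: str, tol: MatchTolerance) -> list[PeakRecord]:
    """Subtract or intersect two peak tables.

    ``subtract`` keeps primary records with no match in ``reference``;
    ``intersect`` keeps primary records with at least one match. Record
    identity (objects) of the primary table is preserved.
    """
    if mode not in ("subtract", "intersect"):
        raise ValueError(f"mode must be subtract|intersect, got {mode!r}")
    out = []
    for rec in primary:
        hit = any(records_match(rec, ref, tol) for ref in reference)
        if (mode == "subtract") != hit:
            out.append(rec)
        else:
            logger.debug("set_filter(%s): removed %s", mode, rec.record_id)
    return out


def select_best_layer(records: list[PeakRecord], tol: MatchTolerance) -> list[PeakRecord]:
    """Collapse duplicate detections of one compound across the raw table
    and the deconvolution layers.

    Records are grouped by transitive :func:`records_match`; from each group
    the member with the highest match factor is kept (ties resolved toward
    the lowest layer index).
    """
    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if records_match(records[i], records[j], tol):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[PeakRecord]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(records[i])
    kept = []
    for members in groups.values():
        best = min(
            members,
            key=lambda r: (-(r.match_factor if r.match_factor is not None else -1), r.layer),
        )
        kept.append(best)
    kept.sort(key=lambda r: (r.rt1, r.rt2, r.layer))
    return kept


def filter_match_threshold(records: list[PeakRecord], threshold: int = 800
                           ) -> list[PeakRecord]:
    """Keep records whose match factor is at least ``threshold``."""
    return [r for r in records if r.match_factor is not None
            and r.match_factor >= threshold]


def _observed_pattern(spectrum: MassSpectrum, theoretical: IsotopePattern
                      ) -> tuple[IsotopePattern | None, float | None, float]:
    """Extract the observed isotopologue cluster around the molecular ion.

    Looks up, for every theoretical isotopologue mass, the closest spectrum
    peak within ±0.5 Da. Returns (pattern, measured monoisotopic mass,
    relative molecular-ion intensity vs the spectrum base peak).
    """
    base = spectrum.base_peak_intensity
    masses, abund = [], []
    measured = None
    for k, m in enumerate(theoretical.masses):
        d = np.abs(spectrum.mz - m)
        j = int(np.argmin(d))
        if d[j] <= 0.5:
            masses.append(float(spectrum.mz[j]))
            abund.append(float(spectrum.intensity[j]))
            if k == 0:
                measured = float(spectrum.mz[j])
    if measured is None or not masses or max(abund) <= 0:
        return None, None, 0.0
    rel_molecular = abund[0] / base if base > 0 else 0.0
    abund = 100.0 * np.asarray(abund) / max(abund)
    # de-duplicate masses that collapsed onto one spectrum peak
    uniq: dict[float, float] = {}
    for m, a in zip(masses, abund):
        uniq[m] = max(uniq.get(m, 0.0), a)
    ms = np.array(sorted(uniq))
    return IsotopePattern(ms, np.array([uniq[m] for m in ms])), measured, rel_molecular


def annotate_isotope_fit(records: list[PeakRecord],
                         formulas: dict[str, Formula | str],
                         tol_ppm: float = 100.0,
                         cosine_floor: float = 0.9,
                         appeared_rel: float = 0.05,
                         faint_rel: float = 0.005) -> list[CandidateDBP]:
    """Filter 6: isotopologue-pattern and mass-accuracy annotation.

    The molecular ion is searched in each record's apex spectrum within
    ±0.5 Da of the theoretical monoisotopic mass; its relative intensity
    classifies the status (``appeared`` ≥ ``appeared_rel`` of the base peak,
    ``faint`` ≥ ``faint_rel``, else ``absent``). When found, the cosine
    similarity between theoretical and observed patterns and the signed ppm
    error are computed and ``isotope_ok`` set; an absent molecular ion (or a
    missing formula) leaves the flag indeterminate and the record kept.
    """
    out = []
    for rec in records:
        cand = CandidateDBP(record=rec)
        out.append(cand)
        raw = formulas.get(rec.hit_name) if rec.hit_name else None
        if raw is None or rec.apex_spectrum is None or len(rec.apex_spectrum) == 0:
            continue
        formula = Formula.parse(raw) if isinstance(raw, str) else raw
        cand.formula = formula
        theo = isotope_pattern(formula)
        mono = monoisotopic_mass(formula)
        observed, measured, rel = _observed_pattern(rec.apex_spectrum, theo)
        if observed is None or rel < faint_rel:
            cand.isotope_fit = IsotopeFit("absent", theoretical_mass=mono)
            continue
        status = "appeared" if rel >= appeared_rel else "faint"
        cos = cosine_isotope_similarity(theo, observed)
        ppm = mass_error_ppm(mono, measured)
        cand.isotope_fit = IsotopeFit(status, theoretical_mass=mono,
                                      measured_mass=measured, cosine=cos,
                                      mass_error_ppm=ppm)
        cand.isotope_ok = bool(cos >= cosine_floor and abs(ppm) <= tol_ppm)
    return out


def annotate_ri_fit(candidates: list[CandidateDBP],
                    solutes: dict[str, AbrahamSolute],
                    phase: PhaseSystem,
                    reference_ri: dict[str, float],
                    dI_floor: float = 50.0) -> list[CandidateDBP]:
    """Filter 7: retention-index annotation.

    ``dI = calculated − reference``; ``ri_ok`` is ``|dI| <= dI_floor``;
    a missing descriptor set or reference index leaves the flag
    indeterminate (record kept).
    """
    for cand in candidates:
        name = cand.record.hit_name
        if not name or name not in solutes or name not in reference_ri:
            continue
        calc = kovats_index(solutes[name], phase)
        cand.ri_comparison = RIComparison(name, calculated=calc,
                                          reference=float(reference_ri[name]))
        cand.ri_ok = bool(abs(cand.ri_comparison.dI) <= dI_floor)
    return candidates


def evaluate_elution_concordance(candidates: list[CandidateDBP],
                                 points: dict[str, ElutionPoint],
                                 drop_threshold: float | None = None
                                 ) -> tuple[list[CandidateDBP], ConcordanceReport | None]:
    """Filter 8: Procrustes/correlation concordance of the elution spaces.

    Uses the candidates with a predicted :class:`ElutionPoint`; with fewer
    than three, no report is produced and the table is unchanged. When
    ``drop_threshold`` is set, each candidate's leave-one-out disparity
    contribution (full disparity − disparity without the candidate) drives
    ``elution_ok``; otherwise the report is annotation-only.
    """
    matched = [c for c in candidates
               if c.record.hit_name and c.record.hit_name in points]
    if len(matched) < 3:
        return candidates, None
    for c in matched:
        c.elution_point = points[c.record.hit_name]
    pred = [(c.elution_point.I1, c.elution_point.u2) for c in matched]
    obs = [(c.record.rt1, c.record.rt2) for c in matched]
    report = procrustes_concordance(pred, obs)
    if drop_threshold is not None and len(matched) > 3:
        full = report.procrustes_disparity
        for i, c in enumerate(matched):
            sub_pred = pred[:i] + pred[i + 1:]
            sub_obs = obs[:i] + obs[i + 1:]
            loo = procrustes_concordance(sub_pred, sub_obs).procrustes_disparity
            c.elution_ok = bool(full - loo <= drop_threshold)
    return candidates, report


# ---------------------------------------------------------------------------
# Workflow driver
# ---------------------------------------------------------------------------


@dataclass
class WorkflowConfig:
    """Settings for :func:`run_workflow`."""

    library: list[LibraryEntry] = field(default_factory=list)
    tolerance: MatchTolerance = field(default_factory=MatchTolerance)
    min_snr: float = 5.0
    min_area: int = 5
    k_max: int = 4
    mf_threshold: int = 800
    use_layers: bool = True
    hit_floor: int = 500          # best library hit below this stays unnamed
    spectrum_rel_floor: float = 0.01  # drop spectrum peaks below this x base
    formulas: dict[str, Formula | str] = field(default_factory=dict)
    solutes: dict[str, AbrahamSolute] = field(default_factory=dict)
    phase1: PhaseSystem | None = None
    phase2: PhaseSystem | None = None
    reference_ri: dict[str, float] = field(default_factory=dict)
    elution_base: float = 1.6
    delta_scale: float = 100.0
    output_dir: str | Path | None = None


@dataclass
class WorkflowResult:
    candidates: list[CandidateDBP]
    funnel: FunnelReport
    concordance: ConcordanceReport | None
    sampler_tables: dict[str, list[PeakRecord]]


def _annotate_library_hits(records: list[PeakRecord],
                           library: list[LibraryEntry],
                           hit_floor: int = 0) -> None:
    """Attach the top-scoring library hit (and its reverse MF) per record.

    A best hit below ``hit_floor`` is treated as "no identification": the
    record stays unnamed so that later name-based matching is not poisoned by
    spurious assignments of noise spectra.
    """
    for rec in records:
        if rec.apex_spectrum is None or len(rec.apex_spectrum) == 0 or not library:
            continue
        best, best_mf = None, -1
        for entry in library:
            mf = match_factor(rec.apex_spectrum, entry.spectrum)
            if mf > best_mf:
                best, best_mf = entry, mf
        if best_mf < hit_floor:
            continue
        rec.hit_name = best.name
        rec.hit_cas = best.cas
        rec.match_factor = best_mf
        rec.reverse_match_factor = match_factor(rec.apex_spectrum, best.spectrum,
                                                mode="reverse")


def _noise_floor(chrom: Chromatogram2D, n_sigma: float = 3.0) -> float:
    """Robust per-cell noise floor of a (baseline-corrected) cube."""
    sample = chrom.data[::5, ::5, :].ravel()
    med = float(np.median(sample))
    mad = float(np.median(np.abs(sample - med)))
    return med + n_sigma * 1.4826 * mad


def _clean_spectrum(spec: MassSpectrum | None, abs_floor: float,
                    rel_floor: float) -> MassSpectrum | None:
    if spec is None or len(spec) == 0:
        return spec
    floor = max(abs_floor, rel_floor * spec.base_peak_intensity)
    keep = spec.intensity >= floor
    if not keep.any():
        return MassSpectrum(np.array([]), np.array([]), allow_empty=True)
    return MassSpectrum(spec.mz[keep], spec.intensity[keep])


def _process_sampler(sample_id: str, chrom: Chromatogram2D,
                     cfg: WorkflowConfig) -> list[PeakRecord]:
    """Baseline → detect → (deconvolve) → library match for one sampler."""
    corrected = correct_baseline(chrom)
    noise_floor = _noise_floor(corrected)
    blobs = detect_peaks(corrected, min_snr=cfg.min_snr, min_area=cfg.min_area)
    records: list[PeakRecord] = []
    for bi, blob in enumerate(blobs):
        records.append(PeakRecord(
            sample_id=sample_id, layer=0, rt1=blob.rt1, rt2=blob.rt2,
            apex_spectrum=_clean_spectrum(blob.apex_spectrum, noise_floor,
                                          cfg.spectrum_rel_floor),
            record_id=f"{sample_id}/blob{bi}/raw",
            source_id=f"{sample_id}/blob{bi}",
        ))
    if cfg.use_layers:
        layer_set = build_layers(blobs, corrected, sample_id=sample_id,
                                 k_max=cfg.k_max, noise_floor=noise_floor)
        for rec in layer_set.all_records():
            rec.apex_spectrum = _clean_spectrum(rec.apex_spectrum, 0.0,
                                                cfg.spectrum_rel_floor)
            records.append(rec)
    _annotate_library_hits(records, cfg.library, hit_floor=cfg.hit_floor)
    return records


def identify_compounds(chrom: Chromatogram2D, library: list[LibraryEntry],
                       use_layers: bool = True, mf_threshold: int = 800,
                       min_snr: float = 5.0, min_area: int = 5) -> set[str]:
    """Names identified in one chromatogram at the match-factor threshold.

    With ``use_layers`` the deconvolution layers are searched in addition to
    the raw apex spectra, so the identified set can only grow.
    """
    cfg = WorkflowConfig(library=library, use_layers=use_layers,
                         mf_threshold=mf_threshold, min_snr=min_snr,
                         min_area=min_area)
    records = _process_sampler("sample", chrom, cfg)
    return {r.hit_name for r in records
            if r.match_factor is not None and r.match_factor >= mf_threshold}


def run_workflow(samplers: dict[str, list[Chromatogram2D]],
                 config: WorkflowConfig) -> WorkflowResult:
    """Run the full eight-filter screen over a six-sampler study.

    ``samplers`` maps the roles ``blank``, ``pre`` and ``post`` to their
    replicate chromatograms (two each in the reference design). The funnel
    is accounted over the post-chlorination tables; blank subtraction uses
    the union of all blank peaks, and the pre-chlorination reference for the
    differential filter is the pooled union of the (blank-corrected) pre
    tables.
    """
    for role in ("blank", "pre", "post"):
        if role not in samplers or not samplers[role]:
            raise ValueError(f"missing sampler role {role!r}")
    tables: dict[str, list[PeakRecord]] = {}
    for role in ("blank", "pre", "post"):
        for i, chrom in enumerate(samplers[role], start=1):
            sid = f"{role}{i}"
            tables[sid] = _process_sampler(sid, chrom, config)
            logger.info("%s: %d records (raw + layers)", sid, len(tables[sid]))

    tol = config.tolerance
    blank_union = [r for sid, recs in tables.items() if sid.startswith("blank")
                   for r in recs]
    posts = [tables[sid] for sid in tables if sid.startswith("post")]
    pres = [tables[sid] for sid in tables if sid.startswith("pre")]

    funnel = FunnelReport()

    # Filter 1: blank correction
    n_in = sum(len(t) for t in posts)
    posts = [set_filter(t, blank_union, "subtract", tol) for t in posts]
    pres = [set_filter(t, blank_union, "subtract", tol) for t in pres]
    funnel.add("blank_correction", n_in, sum(len(t) for t in posts))

    # Filter 2: replicate consistency (pairwise intersection of post tables)
    n_in = sum(len(t) for t in posts)
    if len(posts) > 1:
        current = posts[0]
        for other in posts[1:]:
            current = set_filter(current, other, "intersect", tol)
    else:
        current = posts[0]
    funnel.add("replicate_consistency", n_in, len(current))

    # Filter 3: chlorination differential (subtract pooled pre tables)
    pre_pool = [r for t in pres for r in t]
    n_in = len(current)
    current = set_filter(current, pre_pool, "subtract", tol)
    funnel.add("chlorination_differential", n_in, len(current))

    # Filter 4: optimal peak selection across layers
    n_in = len(current)
    current = select_best_layer(current, tol)
    funnel.add("optimal_peak_selection", n_in, len(current))

    # Filter 5: match-factor threshold
    n_in = len(current)
    current = filter_match_threshold(current, config.mf_threshold)
    funnel.add("match_factor_threshold", n_in, len(current))

    # Filters 6-8: annotation only (no removals by default)
    candidates = annotate_isotope_fit(current, config.formulas)
    funnel.add("isotope_fit_annotation", len(current), len(current))
    if config.solutes and config.phase1 is not None and config.reference_ri:
        candidates = annotate_ri_fit(candidates, config.solutes, config.phase1,
                                     config.reference_ri)
    funnel.add("retention_index_annotation", len(current), len(current))
    concordance = None
    if config.solutes and config.phase1 is not None and config.phase2 is not None:
        points = {}
        for name, solute in config.solutes.items():
            points[name] = predict_elution_point(
                solute, config.phase1, config.phase2,
                base=config.elution_base, delta_scale=config.delta_scale,
            )
        candidates, concordance = evaluate_elution_concordance(candidates, points)
    funnel.add("elution_concordance_annotation", len(current), len(current))

    result = WorkflowResult(candidates=candidates, funnel=funnel,
                            concordance=concordance, sampler_tables=tables)
    if config.output_dir is not None:
        _write_outputs(result, Path(config.output_dir))
    return result


def _write_outputs(result: WorkflowResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_peak_table([c.record for c in result.candidates],
                     out_dir / "candidates.csv")
    entries = [LibraryEntry(name=c.record.hit_name or f"candidate {i}",
                            cas=c.record.hit_cas,
                            spectrum=c.record.apex_spectrum)
               for i, c in enumerate(result.candidates, 1)
               if c.record.apex_spectrum is not None and len(c.record.apex_spectrum)]
    write_msp(entries, out_dir / "candidates.msp")
    with open(out_dir / "funnel.json", "w", encoding="utf-8") as fh:
        json.dump(result.funnel.to_dict(), fh, indent=2)
    if result.concordance is not None:
        with open(out_dir / "concordance.json", "w", encoding="utf-8") as fh:
            json.dump(
                dict(procrustes_disparity=result.concordance.procrustes_disparity,
                     r1=result.concordance.r1, r2=result.concordance.r2,
                     n=result.concordance.n),
                fh, indent=2,
            )
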