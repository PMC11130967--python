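"""Shared fixtures: desk-scale synthetic studies and simple cubes.

Study geometries are reduced (shorter run, narrower m/z span than the
full instrument defaults) so the suite stays fast; the m/z span always
covers the heaviest molecular-ion cluster of the compound palettes.
"""

import numpy as np
import pytest

from dbpscreen.io_core import Chromatogram2D
from dbpscreen.synthetic_data import (StudyDesign, TruthCompound,
                                      generate_chromatogram, generate_spectrum,
                                      generate_study, truth_library)


@pytest.fixture(scope="session")
def mini_study():
    """Six-sampler study: 3 spiked DBPs (one co-eluting), 6 background."""
    samplers, truth = generate_study(
        3, 6, overlap_fraction=0.34, seed=11,
        run_minutes=5.0, mz_start=33, mz_end=340,
    )
    return samplers, truth


@pytest.fixture(scope="session")
def mini_library(mini_study):
    _, truth = mini_study
    return truth_library(truth)


def make_design(compounds, noise_sd=0.0, baseline=0.0, seed=0, run_minutes=3.0,
                mz_start=33, mz_end=200):
    return StudyDesign(
        compounds=compounds, seed=seed, noise_sd=noise_sd,
        baseline_level=baseline, run_minutes=run_minutes,
        mz_start=mz_start, mz_end=mz_end,
    )


def make_compound(name="4-chlorophenol", formula="C6H5ClO", rt1=1.5, rt2=2.5,
                  amplitude=1000.0, sigma1=0.2, sigma2=0.35, seed=3,
                  membership=frozenset({"blank", "pre", "post"})):
    from dbpscreen.io_core import Formula

    spec = generate_spectrum(formula, n_fragments=6, seed=seed)
    return TruthCompound(
        name=name, formula=Formula.parse(formula), rt1=rt1, rt2=rt2,
        spectrum=spec, amplitude=amplitude, sigma1=sigma1, sigma2=sigma2,
        membership=membership,
    )


@pytest.fixture()
def single_peak_chromatogram():
    """One clean Gaussian peak, no noise, no baseline."""
    c = make_compound()
    design = make_design([c])
    chrom, members = generate_chromatogram(design, "post")
    return chrom, c


def gaussian_pair_cube(separation_cells, sigma_cells=5.0, n_scans=80,
                       n_mod=40, amp=1000.0):
    """Two equal Gaussians along the scan axis on a mostly-empty image."""
    period, rate = 2.0, n_scans / 2.0
    scans = np.arange(n_scans, dtype=float)
    c1 = n_scans / 2 - separation_cells / 2
    c2 = n_scans / 2 + separation_cells / 2
    profile = amp * (np.exp(-0.5 * ((scans - c1) / sigma_cells) ** 2)
                     + np.exp(-0.5 * ((scans - c2) / sigma_cells) ** 2))
    rows = np.exp(-0.5 * ((np.arange(n_mod) - n_mod / 2) / 2.0) ** 2)
    rows[rows < 1e-3] = 0.0
    cube = (rows[:, None] * profile[None, :]).astype(np.float32)[:, :, None]
    return Chromatogram2D(cube, period, rate, 50, 50)
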