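"""Loaders for the small data tables bundled with the package."""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import pandas as pd

_PKG = "dbpscreen.data"


def _path(name: str):
    return resources.files(_PKG).joinpath(name)


@lru_cache(maxsize=None)
def load_isotopes() -> dict[str, list[tuple[float, float]]]:
    """Element -> [(exact mass Da, natural abundance), ...] sorted by mass."""
    with _path("isotopes.json").open(encoding="utf-8") as fh:
        raw = json.load(fh)
    return {
        el: [(float(m), float(a)) for m, a in iso]
        for el, iso in raw.items()
        if not el.startswith("_")
    }


@lru_cache(maxsize=None)
def load_alkane_l() -> dict[int, float]:
    """n-alkane carbon number -> Abraham L descriptor (calibration ladder)."""
    df = pd.read_csv(_path("alkane_l.csv"))
    return dict(zip(df["n"].astype(int), df["L"].astype(float)))


def load_dbp_peak_table():
    """The bundled 22-candidate DBP peak table (transcribed reference data)."""
    from .io_core import read_peak_table

    return read_peak_table(_path("dbp_peak_table.csv"))


def load_dbp_identity_table() -> pd.DataFrame:
    """Isotope/mass-accuracy/retention reference data for the 22 DBPs."""
    return pd.read_csv(_path("dbp_identity_table.csv"))


def load_default_lser():
    """Example Abraham solute/phase configuration bundled with the package."""
    from .io_core import read_lser_table

    return read_lser_table(_path("default_lser.csv"))
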