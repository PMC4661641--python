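"""Published Ezhou City summary tables shipped as package data.

Three small CSVs record the study region's printed accounting: class areas
for 1991/2004/2013 and the two land-use transition matrices (1991-2004 and
2004-2013), all in hectares over the 161,430.57 ha landscape.  They let the
change-accounting and composition statistics run without the original
rasters, which were never deposited.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .change import TransitionMatrix
from .grid import EZHOU_SCHEME

__all__ = ["class_areas", "transition_1991_2004", "transition_2004_2013", "fixtures"]

_DATA = resources.files("landrisk") / "data"


def class_areas() -> pd.DataFrame:
    """Class areas (ha) by year, indexed by year, columns in scheme order."""
    with resources.as_file(_DATA / "class_areas_1991_2013.csv") as p:
        df = pd.read_csv(p, index_col="year")
    return df[list(EZHOU_SCHEME.names)]


def transition_1991_2004() -> TransitionMatrix:
    with resources.as_file(_DATA / "transition_1991_2004.csv") as p:
        return TransitionMatrix.from_csv(p, EZHOU_SCHEME, "1991", "2004")


def transition_2004_2013() -> TransitionMatrix:
    with resources.as_file(_DATA / "transition_2004_2013.csv") as p:
        return TransitionMatrix.from_csv(p, EZHOU_SCHEME, "2004", "2013")


class _Fixtures:
    """Convenience bundle over the three embedded tables."""

    @property
    def table1(self) -> pd.DataFrame:
        return class_areas()

    @property
    def table2(self) -> TransitionMatrix:
        return transition_1991_2004()

    @property
    def table3(self) -> TransitionMatrix:
        return transition_2004_2013()


def fixtures() -> _Fixtures:
    return _Fixtures()
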