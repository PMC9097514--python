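"""Packaged formulation-study fixtures and the published model term sets.

The 17-run training design and the 13-run test design for
propranolol-loaded chitosan/TPP nanogels ship as delimited text inside
the package so the whole pipeline runs offline.  %EE columns are stored
as percent, as assayed, and converted to the fraction scale on load
(all statistics on encapsulation efficiency in this package are on the
fraction scale; multiply by 100 for display).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .design_space import DesignTable, FactorSpec

__all__ = [
    "FACTORS",
    "RESPONSES",
    "REPORTED_TERM_SETS",
    "load_training_design",
    "load_test_design",
]

# design cube: chitosan concentration (% w/v), chitosan/TPP mass ratio,
# chitosan/propranolol mass ratio, each at three levels (face-centered)
FACTORS = (
    FactorSpec("CC", 0.1, 0.3, "% w/v"),
    FactorSpec("CT", 3.0, 7.0),
    FactorSpec("CP", 0.25, 0.5),
)

RESPONSES = ("size", "ZP", "PDI", "EE")

# term sets of the reported reduced response-surface models (the
# stepwise-selected models behind the study's ANOVA); used by the
# "fixed" fitting mode to reproduce them exactly
REPORTED_TERM_SETS = {
    "size": ("CC", "CT", "CC:CT", "CT^2"),
    "PDI": ("CC", "CT", "CC:CT"),
    "ZP": ("CC", "CT", "CP", "CC:CT", "CC:CP", "CC^2"),
    "EE": ("CC", "CT"),
}


def _load(name: str) -> DesignTable:
    with resources.as_file(resources.files("formurs.data") / name) as path:
        df = pd.read_csv(path, comment="#", index_col="run_id")
    df.index = df.index.astype(str)
    df["EE"] = df["EE"] / 100.0  # percent as printed -> fraction
    return DesignTable(list(FACTORS), df, list(RESPONSES))


def load_training_design() -> DesignTable:
    """The 17-run face-centered CCD training set with measured responses."""
    return _load("train_design.csv")


def load_test_design() -> DesignTable:
    """The 13-run independent test set with measured responses."""
    return _load("test_design.csv")
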