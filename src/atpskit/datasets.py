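"""Packaged reference dataset: PEG600 + KOH + water at 298.15 K.

The five experimental tie-lines and the ten drug-partitioning measurements
(ibuprofen and acetaminophen on the same overall compositions) of the
reference liquid-liquid-equilibrium study ship with the package, so the
whole pipeline can be exercised without any download.  The extra
``tll_printed`` / ``ee_printed`` columns carry the originally reported
derived quantities for cross-checking recomputation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_partition_csv, read_tielines_csv

__all__ = [
    "load_peg600_koh_tielines",
    "load_peg600_koh_partition",
    "peg600_koh_tieline_table",
    "peg600_koh_partition_table",
]


def _data_path(name: str):
    return resources.files("atpskit.data").joinpath(name)


def peg600_koh_tieline_table() -> pd.DataFrame:
    """Tie-line table as a DataFrame, including the printed TLL column."""
    with resources.as_file(_data_path("peg600_koh_tielines.csv")) as p:
        return pd.read_csv(p)


def peg600_koh_partition_table() -> pd.DataFrame:
    """Partitioning table as a DataFrame, including the printed EE% column."""
    with resources.as_file(_data_path("peg600_koh_partition.csv")) as p:
        return pd.read_csv(p)


def load_peg600_koh_tielines():
    """The five reference tie-lines as :class:`~atpskit.core.TieLine` objects."""
    with resources.as_file(_data_path("peg600_koh_tielines.csv")) as p:
        return read_tielines_csv(p)


def load_peg600_koh_partition():
    """The ten reference partition records (K given, phase fractions not)."""
    with resources.as_file(_data_path("peg600_koh_partition.csv")) as p:
        return read_partition_csv(p)
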