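"""In-situ species diversity from tree inventory tables.

Field crews record every stem with DBH >= 5 cm together with its crown class
(dominant, co-dominant, intermediate, suppressed). Because optical sensors
see only the upper canopy, diversity is computed on the dominant and
co-dominant trees. Three indices are used per plot:

* Richness S — number of distinct species,
* Shannon–Wiener H = −Σ p_i ln p_i (natural log),
* Simpson D = 1 − Σ p_i², in [0, 1 − 1/S].

Proportions p_i are computed after the upper-canopy filter; each record
counts as one individual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

CROWN_CLASSES = ("dominant", "co-dominant", "intermediate", "suppressed")
UPPER_CANOPY_CLASSES = frozenset({"dominant", "co-dominant"})
MIN_DBH_CM = 5.0

INVENTORY_COLUMNS = [
    "plot_id", "species", "dbh_cm", "height_m", "crown_class", "crown_ew_m", "crown_ns_m",
]

__all__ = [
    "AbundanceVector",
    "DiversityRecord",
    "validate_inventory",
    "filter_upper_canopy",
    "abundance",
    "richness",
    "shannon",
    "simpson",
    "plot_diversity",
    "read_inventory_csv",
]


@dataclass
class AbundanceVector:
    """Species counts and proportional abundances for one plot."""

    plot_id: str
    counts: pd.Series  # index = species, values = n_i >= 1

    def __post_init__(self) -> None:
        self.counts = self.counts[self.counts > 0]

    @property
    def proportions(self) -> np.ndarray:
        n = self.counts.to_numpy(dtype=float)
        return n / n.sum()

    @property
    def n_individuals(self) -> int:
        return int(self.counts.sum())


@dataclass
class DiversityRecord:
    plot_id: str
    S: int
    H: float
    D: float
    n_trees: int


def validate_inventory(records: pd.DataFrame) -> pd.DataFrame:
    """Check the TreeRecord contract: positive DBH, known crown class,
    nonempty species names."""
    missing = [c for c in ("plot_id", "species", "dbh_cm", "crown_class") if c not in records]
    if missing:
        raise ValueError(f"inventory missing required columns: {missing}")
    if (records["dbh_cm"] <= 0).any():
        raise ValueError("dbh_cm must be positive")
    bad = set(records["crown_class"]) - set(CROWN_CLASSES)
    if bad:
        raise ValueError(f"unknown crown classes: {sorted(bad)}")
    if records["species"].astype(str).str.len().eq(0).any():
        raise ValueError("species names must be nonempty")
    return records


def filter_upper_canopy(records: pd.DataFrame) -> pd.DataFrame:
    """Keep dominant/co-dominant trees with DBH >= 5 cm (order preserved)."""
    keep = (records["dbh_cm"] >= MIN_DBH_CM) & records["crown_class"].isin(UPPER_CANOPY_CLASSES)
    out = records[keep]
    if len(out) == 0:
        warnings.warn("upper-canopy filter removed every record", stacklevel=2)
    return out


def abundance(records: pd.DataFrame, plot_id: str | None = None) -> AbundanceVector:
    """Species counts for one plot's records."""
    if plot_id is not None:
        records = records[records["plot_id"] == plot_id]
    elif records["plot_id"].nunique() > 1:
        raise ValueError("records span several plots; pass plot_id")
    else:
        plot_id = records["plot_id"].iloc[0] if len(records) else ""
    counts = records["species"].value_counts().sort_index()
    return AbundanceVector(plot_id=str(plot_id), counts=counts)


def richness(av: AbundanceVector) -> int:
    """Number of distinct species present (count >= 1)."""
    s = int((av.counts > 0).sum())
    if s == 0:
        warnings.warn(f"plot {av.plot_id}: empty abundance vector, richness 0", stacklevel=2)
    return s


def shannon(av: AbundanceVector) -> float:
    """Shannon–Wiener index H = −Σ p_i ln p_i (nats)."""
    if len(av.counts) == 0:
        raise ValueError("cannot compute Shannon index of an empty community")
    p = av.proportions
    return float(-(p * np.log(p)).sum())


def simpson(av: AbundanceVector) -> float:
    """Simpson index D = 1 − Σ p_i²."""
    if len(av.counts) == 0:
        raise ValueError("cannot compute Simpson index of an empty community")
    p = av.proportions
    return float(1.0 - (p**2).sum())


def plot_diversity(records: pd.DataFrame, upper_canopy_only: bool = True) -> pd.DataFrame:
    """Per-plot S, H, D (and tree count) from an inventory table.

    Plots whose filtered record set is empty are omitted with a warning.
    """
    records = validate_inventory(records)
    if upper_canopy_only:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            records = filter_upper_canopy(records)
    rows = []
    for pid, grp in records.groupby("plot_id", sort=True):
        av = abundance(grp, plot_id=str(pid))
        rows.append(
            {
                "plot_id": str(pid),
                "S": richness(av),
                "H": shannon(av),
                "D": simpson(av),
                "n_trees": av.n_individuals,
            }
        )
    return pd.DataFrame(rows, columns=["plot_id", "S", "H", "D", "n_trees"]).set_index("plot_id")


def read_inventory_csv(path) -> pd.DataFrame:
    """Read and validate a tree inventory CSV."""
    return validate_inventory(pd.read_csv(path))
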