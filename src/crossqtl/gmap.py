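"""Ordered genetic map container shared by the simulator, the mapper and
the QTL machinery."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GeneticMap:
    """Markers ordered within linkage groups with cumulative cM positions.

    ``table`` has one row per marker (index = marker name) and columns
    ``lg`` (linkage group label) and ``cm`` (cumulative position, first
    marker of each group at 0).  Optional ``scaffold`` / ``bp`` columns
    carry physical placements when known.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        if not {"lg", "cm"}.issubset(t.columns):
            raise ValueError("map table needs 'lg' and 'cm' columns")
        for lg, sub in t.groupby("lg", sort=False):
            pos = sub["cm"].to_numpy(dtype=float)
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions not non-decreasing in group {lg}")

    @property
    def groups(self) -> list:
        return list(dict.fromkeys(self.table["lg"]))

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_table(self, lg) -> pd.DataFrame:
        return self.table[self.table["lg"] == lg]

    def group_length(self, lg) -> float:
        cm = self.group_table(lg)["cm"]
        return float(cm.max() - cm.min()) if len(cm) else 0.0

    @property
    def total_length_cm(self) -> float:
        return float(sum(self.group_length(lg) for lg in self.groups))

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def marker_density_cm(self) -> float:
        """Average map distance per marker (total length / marker count)."""
        n = self.n_markers
        return self.total_length_cm / n if n else float("nan")

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "marker", out.index)
        cols = ["marker", "lg", "cm"] + [c for c in ("scaffold", "bp") if c in out.columns]
        out[cols].to_csv(path, sep="\t", index=False, float_format="%.4f")

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        t = pd.read_csv(path, sep="\t").set_index("marker")
        return cls(t)
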