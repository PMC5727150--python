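"""Binary trait matrices: one (x, y) state pair per taxon.

The two traits are presence/absence calls — in the motivating analysis,
NHEJ (trait x) and a type II CRISPR-Cas subtype (trait y) — but nothing
here is specific to those systems.  Missing states are allowed and are
marginalized over by the likelihood machinery.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TraitMatrix", "MISSING"]

MISSING = "?"

_VALID = {0, 1, None}


@dataclass
class TraitMatrix:
    """Mapping taxon label -> (x, y) with x, y in {0, 1} or None (missing)."""

    states: dict[str, tuple[int | None, int | None]]
    x_name: str = "trait_x"
    y_name: str = "trait_y"

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("trait matrix is empty")
        clean: dict[str, tuple[int | None, int | None]] = {}
        for label, (x, y) in self.states.items():
            if x not in _VALID or y not in _VALID:
                raise ValueError(f"invalid state {(x, y)!r} for {label!r}")
            clean[str(label)] = (x, y)
        self.states = clean

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.states)

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, label: str) -> tuple[int | None, int | None]:
        return self.states[label]

    def validate_against(self, tip_labels) -> None:
        tips = set(tip_labels)
        mine = set(self.states)
        if tips != mine:
            missing = sorted(tips - mine)
            extra = sorted(mine - tips)
            raise ValueError(
                f"trait labels do not match tree tips; missing={missing[:5]}, "
                f"extra={extra[:5]}"
            )

    def tip_partials(self, tip_labels) -> np.ndarray:
        """Indicator partial vectors over the joint state space (00,01,10,11).

        A missing trait contributes an all-ones factor (marginalization).
        Rows follow ``tip_labels`` order.
        """
        self.validate_against(tip_labels)
        out = np.zeros((len(tip_labels := list(tip_labels)), 4))
        for i, label in enumerate(tip_labels):
            x, y = self.states[label]
            for s in range(4):
                sx, sy = s >> 1, s & 1
                if (x is None or x == sx) and (y is None or y == sy):
                    out[i, s] = 1.0
        return out

    # -- counts ------------------------------------------------------------

    def joint_counts(self) -> dict[tuple[int, int], int]:
        """Counts of the four complete state pairs (missing excluded)."""
        counts = {(0, 0): 0, (0, 1): 0, (1, 0): 0, (1, 1): 0}
        for x, y in self.states.values():
            if x is not None and y is not None:
                counts[(x, y)] += 1
        return counts

    # -- I/O ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (t, MISSING if x is None else x, MISSING if y is None else y)
            for t, (x, y) in self.states.items()
        ]
        return pd.DataFrame(rows, columns=["taxon", self.x_name, self.y_name])

    def to_tsv(self) -> str:
        buf = io.StringIO()
        self.to_frame().to_csv(buf, sep="\t", index=False)
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "TraitMatrix":
        df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
        if df.shape[1] < 3:
            raise ValueError("trait table needs columns: taxon, trait_x, trait_y")
        taxon_col, x_col, y_col = df.columns[:3]
        if df[taxon_col].duplicated().any():
            dup = df[taxon_col][df[taxon_col].duplicated()].tolist()
            raise ValueError(f"duplicated taxa in trait table: {dup[:5]}")

        def parse(v: str) -> int | None:
            if v == MISSING:
                return None
            iv = int(v)
            if iv not in (0, 1):
                raise ValueError(f"trait value must be 0, 1 or '?', got {v!r}")
            return iv

        states = {
            str(r[taxon_col]): (parse(r[x_col]), parse(r[y_col]))
            for _, r in df.iterrows()
        }
        return cls(states=states, x_name=str(x_col), y_name=str(y_col))
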