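"""Study design for the four-group layered-culture experiment.

The layered culture system plates transformed and nontransformed cells on
opposite faces of a porous membrane so that the two populations form
intercellular junctions while remaining separable for RNA extraction. The
four groups the transcriptome cascade contrasts are:

``N_self``
    nontransformed cells cultured over themselves (baseline).
``T_self``
    Src-transformed cells cultured over themselves (transformed baseline).
``T_vs_N``
    transformed cells cultured over cadherin-competent nontransformed cells
    (contact normalization).
``T_vs_KO``
    transformed cells cultured over cadherin-knockout nontransformed cells
    (contact without adherens junctions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

GROUPS: tuple[str, ...] = ("N_self", "T_self", "T_vs_N", "T_vs_KO")


@dataclass(frozen=True)
class StudyDesign:
    """Mapping of sample identifiers to layered-culture groups.

    Parameters
    ----------
    assignments:
        Ordered mapping ``sample_id -> group``; every group must be one of
        :data:`GROUPS`.
    """

    assignments: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValueError("study design is empty")
        bad = {g for g in self.assignments.values() if g not in GROUPS}
        if bad:
            raise ValueError(
                f"unknown group name(s) {sorted(bad)}; expected one of {GROUPS}"
            )
        object.__setattr__(self, "assignments", dict(self.assignments))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignments)

    def samples_in(self, group: str) -> list[str]:
        """Sample identifiers assigned to ``group``, in design order."""
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
        return [s for s, g in self.assignments.items() if g == group]

    def replicates(self) -> dict[str, int]:
        """Replicate count per group (groups with zero samples included)."""
        return {g: len(self.samples_in(g)) for g in GROUPS}

    def require_groups(self, groups: Iterable[str] = GROUPS, min_replicates: int = 2) -> None:
        """Raise if any requested group has fewer than ``min_replicates`` samples."""
        reps = self.replicates()
        for g in groups:
            if reps.get(g, 0) < min_replicates:
                raise ValueError(
                    f"group {g!r} has {reps.get(g, 0)} replicate(s); "
                    f"at least {min_replicates} required"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids,
             "group": [self.assignments[s] for s in self.sample_ids]}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StudyDesign":
        if list(frame.columns[:2]) != ["sample_id", "group"]:
            raise ValueError(
                "design table must have columns 'sample_id' and 'group', "
                f"got {list(frame.columns)}"
            )
        dup = frame["sample_id"][frame["sample_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample id(s) in design: {sorted(set(dup))}")
        return cls(dict(zip(frame["sample_id"], frame["group"])))

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> StudyDesign:
    """Read a two-column ``sample_id<TAB>group`` table."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    try:
        return StudyDesign.from_frame(frame)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from None
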