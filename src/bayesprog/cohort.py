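"""Model-ready cohort container.

A :class:`CohortFrame` is the rectangular participant-by-column table that the
network learner and the simulators operate on.  Columns are either
time-invariant (``"age"``) or time-indexed (``"moca@5"`` = MoCA at visit year
5); every column carries a role tag that drives the structural constraints of
the learner (who may be a parent, who may be a child).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: closed role vocabulary
ROLES = ("baseline", "outcome", "intervention", "genetic", "genetic_pc", "imaging")

#: roles that can never be children of the learned network
EXOGENOUS_ROLES = ("baseline", "genetic", "genetic_pc", "intervention", "imaging")

TIME_SEP = "@"


def make_column(variable: str, time: int | None) -> str:
    """Column id for ``variable`` at visit ``time`` (``None`` = time-invariant)."""
    if TIME_SEP in variable:
        raise ValueError(f"variable name may not contain {TIME_SEP!r}: {variable!r}")
    return variable if time is None else f"{variable}{TIME_SEP}{time}"


def split_column(column: str) -> tuple[str, int | None]:
    """Inverse of :func:`make_column`."""
    if TIME_SEP not in column:
        return column, None
    var, t = column.rsplit(TIME_SEP, 1)
    return var, int(t)


@dataclass
class CohortFrame:
    """Participant x (variable, time) table with roles and cell provenance.

    Parameters
    ----------
    data
        Wide table, index = participant ids, one column per (variable, time)
        pair.  No missing values after assembly.
    roles
        Column -> role, role in :data:`ROLES`.
    snp_group
        Maps each genetic coding column (additive/dominant/recessive) to the
        SNP it encodes; used to forbid multiple codings of one SNP inside a
        single parent set and to clamp codings coherently in simulations.
    provenance
        Optional same-shaped table of {"observed","imputed","interpolated"}.
    """

    data: pd.DataFrame
    roles: dict[str, str]
    snp_group: dict[str, str] = field(default_factory=dict)
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data.index.name = "participant_id"
        if self.provenance is not None:
            self.provenance.index.name = "participant_id"
        missing_roles = [c for c in self.data.columns if c not in self.roles]
        if missing_roles:
            raise ValueError(f"columns without a role tag: {missing_roles}")
        bad = {c: r for c, r in self.roles.items() if r not in ROLES}
        if bad:
            raise ValueError(f"unknown roles: {bad}")

    # -- column queries -------------------------------------------------
    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_participants(self) -> int:
        return len(self.data)

    def time_index(self, column: str) -> int | None:
        return split_column(column)[1]

    def columns_with_role(self, *roles: str) -> list[str]:
        return [c for c in self.data.columns if self.roles[c] in roles]

    def dependent_columns(self) -> list[str]:
        """Columns modeled as children: outcome-role (time-indexed) columns."""
        return self.columns_with_role("outcome")

    def times_of(self, variable: str) -> list[int]:
        ts = sorted(
            t for c in self.data.columns
            for v, t in [split_column(c)] if v == variable and t is not None
        )
        return ts

    # -- persistence ----------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write the frame plus a ``<path>.meta.json`` sidecar of roles."""
        path = Path(path)
        self.data.to_csv(path, index_label="participant_id")
        meta = {"roles": self.roles, "snp_group": self.snp_group}
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(meta, indent=1))
        if self.provenance is not None:
            self.provenance.to_csv(path.with_suffix(".provenance.csv"),
                                   index_label="participant_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortFrame":
        path = Path(path)
        data = pd.read_csv(path, index_col="participant_id")
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        return cls(data=data, roles=meta["roles"], snp_group=meta.get("snp_group", {}))
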