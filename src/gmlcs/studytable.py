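"""Tidy long-format container for longitudinal multimodal study data.

A :class:`StudyTable` holds every observed measurement of a two-group
longitudinal study in long form — one row per (participant, variable,
occasion) — together with a per-participant demographics table (group,
age, sex, years of education, intracranial volume).  Missing measurements
are *absent rows*, never sentinel values, which is what a full-information
likelihood downstream expects.

Variable naming convention: ROI indicators are ``"<ROI>_<HEMI>.<MODALITY>"``
(e.g. ``"ACC_R.VBM"``), cardiovascular fitness is ``"VO2peak"`` and is only
ever observed at occasions 1 and 3.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("ACG", "EG")
MODALITIES = ("VBM", "MT", "MD")
ROI_BASES = ("HC", "ACC", "PCC", "PCG", "JLC", "IFG")
HEMISPHERES = ("L", "R")
#: The 12 regions of interest, e.g. "HC_L", "ACC_R", ...
ROI_ROSTER = tuple(f"{b}_{h}" for b in ROI_BASES for h in HEMISPHERES)
FITNESS_VARIABLE = "VO2peak"
FITNESS_OCCASIONS = (1, 3)

MEASUREMENT_COLUMNS = ["participant_id", "group", "variable", "occasion", "value"]
PARTICIPANT_COLUMNS = ["participant_id", "group", "age", "sex", "education_years", "icv"]


def roi_variable(roi: str, modality: str) -> str:
    """Canonical indicator name for a region/modality pair."""
    if roi not in ROI_ROSTER:
        raise ValueError(f"unknown ROI {roi!r}; roster is {ROI_ROSTER}")
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    return f"{roi}.{modality}"


@dataclass
class StudyTable:
    """Long-format measurements plus a participants table.

    Parameters
    ----------
    measurements
        DataFrame with columns ``participant_id, group, variable, occasion,
        value``.  The triple (participant, variable, occasion) must be unique.
    participants
        DataFrame with columns ``participant_id, group, age, sex,
        education_years, icv``; one row per participant.
    latents
        Optional wide per-participant table of the latent draws that produced
        a synthetic table (generator bookkeeping; empty for real data).
    """

    measurements: pd.DataFrame
    participants: pd.DataFrame
    latents: pd.DataFrame | None = field(default=None, repr=False)
    meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.measurements = self.measurements.reset_index(drop=True)
        self.participants = self.participants.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        missing = set(MEASUREMENT_COLUMNS) - set(self.measurements.columns)
        if missing:
            raise ValueError(f"measurements table lacks columns {sorted(missing)}")
        missing = set(PARTICIPANT_COLUMNS) - set(self.participants.columns)
        if missing:
            raise ValueError(f"participants table lacks columns {sorted(missing)}")
        key = self.measurements[["participant_id", "variable", "occasion"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate measurement row for {dup}")
        fit = self.measurements[self.measurements["variable"] == FITNESS_VARIABLE]
        bad = set(fit["occasion"].unique()) - set(FITNESS_OCCASIONS)
        if bad:
            raise ValueError(
                f"{FITNESS_VARIABLE} observed at occasions {sorted(bad)}; "
                f"allowed occasions are {FITNESS_OCCASIONS}"
            )
        if self.measurements["value"].isna().any():
            raise ValueError("missing values must be absent rows, not NaN cells")

    # ------------------------------------------------------------------
    # views
    # ------------------------------------------------------------------
    @property
    def participant_ids(self) -> list[str]:
        return self.participants["participant_id"].tolist()

    def variables(self) -> list[str]:
        return sorted(self.measurements["variable"].unique())

    def group_of(self) -> pd.Series:
        """participant_id -> group."""
        return self.participants.set_index("participant_id")["group"]

    def wide(
        self,
        variables: list[str],
        occasions: dict[str, tuple[int, ...]] | None = None,
    ) -> pd.DataFrame:
        """Pivot to one row per participant, columns ``"<variable>@<occasion>"``.

        Missing measurements become NaN.  Column order follows ``variables``
        then occasion; row order follows the participants table.  ``occasions``
        optionally restricts which occasions of each variable are emitted
        (default: all occasions present for that variable).
        """
        m = self.measurements[self.measurements["variable"].isin(variables)]
        pivot = m.pivot_table(
            index="participant_id",
            columns=["variable", "occasion"],
            values="value",
            aggfunc="first",
        )
        cols: list[str] = []
        out = pd.DataFrame(index=pd.Index(self.participant_ids, name="participant_id"))
        for v in variables:
            occs: tuple[int, ...]
            if occasions and v in occasions:
                occs = occasions[v]
            elif v in pivot.columns.get_level_values(0):
                occs = tuple(sorted(pivot[v].columns))
            else:
                occs = ()
            for t in occs:
                name = f"{v}@{t}"
                cols.append(name)
                if v in pivot.columns.get_level_values(0) and t in pivot[v].columns:
                    out[name] = pivot[(v, t)].reindex(out.index)
                else:
                    out[name] = np.nan
        out["group"] = self.group_of().reindex(out.index)
        return out[cols + ["group"]]

    # ------------------------------------------------------------------
    # mutation helpers (return new tables; StudyTable is treated as immutable)
    # ------------------------------------------------------------------
    def drop_cells(self, cells: list[tuple[str, str, int]]) -> "StudyTable":
        """Return a copy with the given (participant, variable, occasion) rows removed."""
        if not cells:
            return StudyTable(
                self.measurements.copy(), self.participants.copy(), self.latents, dict(self.meta)
            )
        key = pd.MultiIndex.from_frame(
            self.measurements[["participant_id", "variable", "occasion"]]
        )
        drop = key.isin(pd.MultiIndex.from_tuples(cells))
        return StudyTable(
            self.measurements.loc[~drop].copy(),
            self.participants.copy(),
            self.latents,
            dict(self.meta),
        )

    def with_values(self, measurements: pd.DataFrame) -> "StudyTable":
        return StudyTable(measurements, self.participants.copy(), self.latents, dict(self.meta))

    # ------------------------------------------------------------------
    # I/O
    # ------------------------------------------------------------------
    def to_csv(self, measurements_path, participants_path, header_comment: str | None = None) -> None:
        """Write the two tidy CSVs; an optional ``#``-prefixed comment line
        (e.g. recording the generator seed) is placed above the header."""
        for path, frame in (
            (measurements_path, self.measurements[MEASUREMENT_COLUMNS]),
            (participants_path, self.participants[PARTICIPANT_COLUMNS]),
        ):
            buf = io.StringIO()
            if header_comment:
                buf.write(f"# {header_comment}\n")
            frame.to_csv(buf, index=False)
            with open(path, "w") as fh:
                fh.write(buf.getvalue())

    @classmethod
    def from_csv(cls, measurements_path, participants_path) -> "StudyTable":
        meas = pd.read_csv(measurements_path, comment="#")
        part = pd.read_csv(participants_path, comment="#")
        return cls(meas, part)
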