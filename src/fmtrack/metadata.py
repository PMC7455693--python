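"""Sample metadata: the single source of truth linking sample ids to
subjects, roles, time points and donor assignments.

Abundance tables and strain inputs carry bare sample identifiers; all
cohort structure (who is a donor, which patient received which donor's
stool, which visit a sample represents) lives in one metadata table with
columns ``sample_id, subject_id, role, time_point, donor_id``:

* role ``donor``: a donor stool sample; ``subject_id`` and ``donor_id``
  are both the donor's id, ``time_point`` is ``donor``.
* role ``dfmt``: a treated patient's sample at ``pre``/``wk1``/``wk2``/
  ``wk4``; ``donor_id`` names the assigned donor.
* role ``pfmt``: a placebo patient's single baseline sample,
  ``time_point`` ``control_pre``; no donor link.
"""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd

ROLES = ("donor", "dfmt", "pfmt")
TIME_POINTS = ("donor", "pre", "wk1", "wk2", "wk4", "control_pre")
POST_TIME_POINTS = ("wk1", "wk2", "wk4")

METADATA_COLUMNS = ["sample_id", "subject_id", "role", "time_point", "donor_id"]


class CohortMetadata:
    """Indexed view over the sample metadata table."""

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        frame["donor_id"] = frame["donor_id"].where(
            frame["donor_id"].notna() & (frame["donor_id"] != ""), None
        )
        if frame["sample_id"].duplicated().any():
            dups = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in metadata: {dups}")
        bad_roles = set(frame["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown roles {sorted(bad_roles)}; expected {ROLES}")
        bad_tp = set(frame["time_point"]) - set(TIME_POINTS)
        if bad_tp:
            raise ValueError(f"unknown time points {sorted(bad_tp)}")
        no_link = frame[(frame["role"] == "dfmt") & frame["donor_id"].isna()]
        if len(no_link):
            raise ValueError(
                "D-FMT samples without donor link: "
                f"{no_link['sample_id'].tolist()}"
            )
        self.frame = frame.reset_index(drop=True)
        self._by_sample = self.frame.set_index("sample_id")

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_sample.index

    @property
    def sample_ids(self) -> list:
        return self.frame["sample_id"].tolist()

    def row(self, sample_id: str) -> pd.Series:
        try:
            return self._by_sample.loc[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in metadata") from None

    def subject_of(self, sample_id: str) -> str:
        return str(self.row(sample_id)["subject_id"])

    def role_of(self, sample_id: str) -> str:
        return str(self.row(sample_id)["role"])

    def time_point_of(self, sample_id: str) -> str:
        return str(self.row(sample_id)["time_point"])

    def donor_of(self, sample_id: str) -> Optional[str]:
        d = self.row(sample_id)["donor_id"]
        return None if d is None or pd.isna(d) else str(d)

    def samples_at(self, time_point: str) -> list:
        """Sample ids at one time point (or any of a tuple of them)."""
        tps = (time_point,) if isinstance(time_point, str) else tuple(time_point)
        sel = self.frame["time_point"].isin(tps)
        return self.frame.loc[sel, "sample_id"].tolist()

    def donor_sample_of(self, donor_id: str) -> str:
        sel = self.frame[
            (self.frame["role"] == "donor") & (self.frame["subject_id"] == donor_id)
        ]
        if len(sel) != 1:
            raise KeyError(
                f"expected exactly one donor sample for {donor_id!r}, found {len(sel)}"
            )
        return str(sel["sample_id"].iloc[0])

    def dfmt_patients(self) -> list:
        sel = self.frame[self.frame["role"] == "dfmt"]
        return sorted(sel["subject_id"].unique().tolist())

    def donor_of_patient(self, subject_id: str) -> str:
        sel = self.frame[
            (self.frame["role"] == "dfmt") & (self.frame["subject_id"] == subject_id)
        ]
        if not len(sel):
            raise KeyError(f"no D-FMT samples for patient {subject_id!r}")
        donors = set(sel["donor_id"])
        if len(donors) != 1:
            raise ValueError(f"patient {subject_id!r} linked to multiple donors")
        return str(donors.pop())

    def sample_of(self, subject_id: str, time_point: str) -> Optional[str]:
        sel = self.frame[
            (self.frame["subject_id"] == subject_id)
            & (self.frame["time_point"] == time_point)
        ]
        if not len(sel):
            return None
        if len(sel) > 1:
            raise ValueError(
                f"multiple samples for ({subject_id}, {time_point})"
            )
        return str(sel["sample_id"].iloc[0])
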