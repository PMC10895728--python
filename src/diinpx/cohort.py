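"""Median split of a cohort on the DII.

Subjects at or above the sample median are labelled ``high``, the rest
``low`` (tie-to-upper).  With an odd number of distinct values this puts
the median subject in the high group, e.g. 663 distinct DII values split
332 high / 331 low.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

HIGH, LOW = "high", "low"


@dataclass(frozen=True)
class CohortSplit:
    """High/low DII labels around the sample median."""

    table: pd.DataFrame  # subject_id, dii, group
    median_dii: float

    @property
    def labels(self) -> pd.Series:
        return self.table.set_index("subject_id")["group"]

    def subjects(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == group, "subject_id"])

    @property
    def n_high(self) -> int:
        return int((self.table["group"] == HIGH).sum())

    @property
    def n_low(self) -> int:
        return int((self.table["group"] == LOW).sum())


def median_split(dii: Mapping[str, float] | pd.Series) -> CohortSplit:
    """Split subjects at the sample median DII, ties going high.

    Requires at least two subjects with finite values.
    """
    s = pd.Series(dict(dii) if not isinstance(dii, pd.Series) else dii, dtype=float)
    if len(s) < 2:
        raise ValueError(f"median split needs >= 2 subjects, got {len(s)}")
    if not np.isfinite(s.to_numpy()).all():
        bad = sorted(s.index[~np.isfinite(s.to_numpy())])
        raise ValueError(f"non-finite DII values for subjects: {bad}")
    med = float(np.median(s.to_numpy()))
    table = pd.DataFrame(
        {
            "subject_id": s.index.astype(str),
            "dii": s.to_numpy(),
            "group": np.where(s.to_numpy() >= med, HIGH, LOW),
        }
    ).sort_values("subject_id", ignore_index=True)
    return CohortSplit(table=table, median_dii=med)
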