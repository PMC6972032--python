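"""Long-format panel file reading/writing and cohort conversions.

The on-disk format is delimited text (CSV by default), one row per
subject-visit, with the reserved columns

    subject_id, t_years, age, state, death_time_years

and one column per covariate.  ``state`` is one of A/B/C/D (death is
never a visit row); ``death_time_years`` repeats the subject's exact
death time on every row, empty for subjects alive or censored at the
registry cut-off.  Validation is strict and reports file line numbers
(header = line 1).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .likelihood import MONOTONE_COVARIATES, PanelObservation, SubjectHistory
from .model import LIVING_STATES, InputError

RESERVED_COLUMNS = ("subject_id", "t_years", "age", "state", "death_time_years")


def dataframe_to_cohort(df: pd.DataFrame) -> list[SubjectHistory]:
    """Validate a long-format panel frame and build SubjectHistory objects.

    Raises InputError listing the offending file lines (data rows start
    at line 2) for schema violations, unsorted times, states after
    death, or decreasing DM/CVD paths.
    """
    missing = [c for c in RESERVED_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"panel file missing required columns: {missing}")
    covariate_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    errors: list[str] = []

    def err(i: int, msg: str) -> None:
        if len(errors) < 25:
            errors.append(f"line {i + 2}: {msg}")

    for i, row in enumerate(df.itertuples(index=False)):
        if getattr(row, "state") not in LIVING_STATES:
            err(i, f"state {getattr(row, 'state')!r} not one of {LIVING_STATES}")
        t = getattr(row, "t_years")
        if not np.isfinite(t) or t < 0:
            err(i, f"invalid t_years {t!r}")
    if errors:
        raise InputError("panel validation failed:\n" + "\n".join(errors))

    cohort: list[SubjectHistory] = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.reset_index(drop=True)
        first_lines = grp.index  # relative; good enough with sid in message
        ts = grp["t_years"].to_numpy(dtype=float)
        if np.any(np.diff(ts) <= 0):
            raise InputError(f"subject {sid}: t_years not strictly increasing")
        death_vals = grp["death_time_years"].to_numpy()
        death_time = None
        finite = pd.notna(death_vals)
        if finite.any():
            uniq = np.unique(np.asarray(death_vals[finite], dtype=float))
            if len(uniq) > 1:
                raise InputError(f"subject {sid}: inconsistent death_time_years values {uniq}")
            death_time = float(uniq[0])
            if death_time <= ts[-1]:
                raise InputError(
                    f"subject {sid}: death_time_years {death_time} not after "
                    f"last visit at t={ts[-1]}"
                )
        for name in MONOTONE_COVARIATES:
            if name in covariate_cols:
                vals = grp[name].to_numpy(dtype=float)
                if np.any(np.diff(vals) < 0):
                    raise InputError(
                        f"subject {sid}: {name} decreases over time; it may only "
                        "develop, not resolve"
                    )
        obs = [
            PanelObservation(
                t=float(r["t_years"]),
                age=float(r["age"]),
                state=str(r["state"]),
                covariates={c: float(r[c]) for c in covariate_cols},
            )
            for _, r in grp.iterrows()
        ]
        cohort.append(SubjectHistory(str(sid), obs, death_time))
    return cohort


def cohort_to_dataframe(cohort: Sequence[SubjectHistory]) -> pd.DataFrame:
    """Inverse of dataframe_to_cohort (covariate columns from first subject)."""
    rows = []
    for h in cohort:
        for o in h.observations:
            row = {
                "subject_id": h.subject_id,
                "t_years": o.t,
                "age": o.age,
                "state": o.state,
                "death_time_years": h.death_time if h.death_time is not None else np.nan,
            }
            row.update(o.covariates)
            rows.append(row)
    return pd.DataFrame(rows)


def read_panel(path) -> list[SubjectHistory]:
    """Read and validate a long-format panel file."""
    df = pd.read_csv(path)
    return dataframe_to_cohort(df)


def write_panel(df: pd.DataFrame, path) -> None:
    """Write a panel frame with a stable column order and float format."""
    cols = [c for c in RESERVED_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False, float_format="%.6f")
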