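"""Luciferase reporter-assay arithmetic.

Each well yields a firefly-luciferase reading (the activity driven by the
tested construct) and a beta-galactosidase reading (a co-transfected control
for transfection efficiency).  The per-well ratio luciferase / beta-gal is the
transfection-normalized activity; a construct's fold activity is its mean
ratio divided by the basal promoter construct's mean ratio, so the basal
construct is exactly 1 by construction.  Significance against the basal
construct comes from a two-sample unpaired t-test (Student's equal-variance
by default, Welch optional).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

REPORTER_COLUMNS = ("construct_id", "replicate_id", "luciferase", "beta_gal")


@dataclass(frozen=True)
class RelativeActivity:
    construct_id: str
    fold: float
    sem: float
    n: int
    t: float | None
    df: float | None
    p_value: float | None


def read_reporter_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(REPORTER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reporter table missing columns: {sorted(missing)}")
    return df


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    bad = table.index[table["beta_gal"] <= 0]
    if len(bad):
        row = table.loc[bad[0]]
        raise ValueError(
            f"non-positive beta_gal in row {bad[0]} "
            f"(construct {row['construct_id']!r}, replicate {row['replicate_id']!r})"
        )
    return table


def unpaired_t(
    group: Sequence[float], basal: Sequence[float], variant: str = "student"
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test; returns (t, df, p).

    ``student`` pools the variances; ``welch`` does not.  Two groups with zero
    variance and equal means give p = 1 by convention; zero pooled variance
    with unequal means is degenerate and raises.
    """
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    a = np.asarray(group, float)
    b = np.asarray(basal, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            df = len(a) + len(b) - 2 if variant == "student" else float("nan")
            return 0.0, float(df), 1.0
        raise ValueError("degenerate t-test: zero variance in both groups, unequal means")
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def relative_activity(
    table: pd.DataFrame,
    basal_id: str,
    variant: str = "student",
    fold_method: str = "ratio_of_means",
) -> list[RelativeActivity]:
    """Fold activity of every construct relative to the basal promoter.

    Per-well ratios r = luciferase / beta_gal; with ``ratio_of_means`` the
    fold is mean(r_construct) / mean(r_basal) (default); ``mean_of_ratios``
    pairs replicates by position and averages r_construct_i / r_basal_i
    (requires equal replicate counts).  The basal construct is reported as
    exactly 1 in either case.
    """
    if fold_method not in ("ratio_of_means", "mean_of_ratios"):
        raise ValueError("fold_method must be 'ratio_of_means' or 'mean_of_ratios'")
    table = _validate(table)
    if basal_id not in set(table["construct_id"]):
        raise ValueError(f"basal construct {basal_id!r} not in table")
    ratios = {
        cid: (grp["luciferase"] / grp["beta_gal"]).to_numpy(float)
        for cid, grp in table.groupby("construct_id", sort=False)
    }
    basal = ratios[basal_id]
    basal_mean = basal.mean()
    if basal_mean <= 0:
        raise ValueError("basal construct has non-positive mean ratio")

    out = []
    for cid, r in ratios.items():
        n = len(r)
        if fold_method == "ratio_of_means" or cid == basal_id:
            rel = r / basal_mean
        else:
            if len(r) != len(basal):
                raise ValueError(
                    f"mean_of_ratios needs equal replicate counts ({cid}: {len(r)} vs basal {len(basal)})"
                )
            rel = r / basal
        fold = 1.0 if cid == basal_id else float(rel.mean())
        sem = float(rel.std(ddof=1) / math.sqrt(n)) if n >= 2 else float("nan")
        if cid == basal_id or n < 2:
            t = df = p = None
        else:
            try:
                t, df, p = unpaired_t(r, basal, variant=variant)
            except ValueError:
                t = df = p = None  # degenerate (zero-variance) groups: no test
        out.append(RelativeActivity(cid, fold, sem, n, t, df, p))
    return out


def activity_table(results: Sequence[RelativeActivity]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "construct_id": [r.construct_id for r in results],
            "fold": [r.fold for r in results],
            "sem": [r.sem for r in results],
            "n": [r.n for r in results],
            "t": [r.t for r in results],
            "df": [r.df for r in results],
            "p_value": [r.p_value for r in results],
        }
    )


def write_activity_table(path: str | Path, results: Sequence[RelativeActivity]) -> None:
    activity_table(results).to_csv(path, sep="\t", index=False)
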