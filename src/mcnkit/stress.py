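"""Early-life stress exposure scoring and group assignment.

The cumulative count of invasive NICU procedures (skin-breaking procedures,
days of cerebral monitoring and mechanical ventilation, suctioning) up to
the first scan is weighted by the duration of the NICU stay — implemented
as procedures per day — and then standardized over the cohort. Groups are
formed by a median split (primary), a zero-mean split, or a tertile split
(dose-response), each with a deterministic tie rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

SCHEMES = ("median", "zero_mean", "tertile")


def compute_stress_scores(
    procedure_counts,
    nicu_days,
    subject_ids=None,
    ddof: int = 0,
) -> pd.DataFrame:
    """Weighted and standardized stress-exposure scores.

    weighted = procedure_count / nicu_days (procedures per day of NICU stay);
    stress_score = (weighted - mean) / SD over the cohort. The population-SD
    convention (``ddof=0``) is the default; set ``ddof=1`` for the sample SD.

    Returns a DataFrame indexed by subject with columns ``procedure_count``,
    ``nicu_days``, ``weighted_score``, ``stress_score``.
    """
    counts = np.asarray(procedure_counts, dtype=float)
    days = np.asarray(nicu_days, dtype=float)
    if counts.shape != days.shape:
        raise ValidationError("procedure counts and NICU days must be aligned")
    if subject_ids is None:
        subject_ids = [f"S{i:04d}" for i in range(1, counts.size + 1)]
    subject_ids = pd.Index([str(s) for s in subject_ids], name="subject_id")
    if (counts < 0).any():
        bad = subject_ids[counts < 0].tolist()
        raise ValidationError(f"negative procedure count for subject(s): {bad}")
    if (days <= 0).any():
        bad = subject_ids[days <= 0].tolist()
        raise ValidationError(f"NICU days must be > 0; violated by subject(s): {bad}")
    weighted = counts / days
    sd = weighted.std(ddof=ddof)
    if sd == 0:
        raise ValidationError("all weighted stress scores identical; standardization undefined")
    z = (weighted - weighted.mean()) / sd
    return pd.DataFrame(
        {
            "procedure_count": counts,
            "nicu_days": days,
            "weighted_score": weighted,
            "stress_score": z,
        },
        index=subject_ids,
    )


def _rank_order(scores: pd.Series) -> pd.Index:
    """Subjects sorted by (score, subject_id) — the documented tie rule."""
    df = pd.DataFrame({"score": scores.astype(float)})
    df["sid"] = df.index.astype(str)
    return df.sort_values(["score", "sid"], kind="mergesort").index


def _tertile_sizes(n: int) -> tuple[int, int, int]:
    # near-equal thirds; any remainder goes to the lower groups first,
    # so 180 -> 60/60/60 and 181 -> 61/60/60
    base, rem = divmod(n, 3)
    return (base + (rem > 0), base + (rem > 1), base)


def assign_groups(scores: pd.DataFrame | pd.Series, scheme: str = "median") -> pd.Series:
    """Assign each subject a stress-exposure group label.

    * ``median`` — lowest 50% of standardized scores -> ``low``, highest 50%
      -> ``high`` (ties resolved by subject id; odd n puts the extra subject
      in ``low``).
    * ``zero_mean`` — standardized score < 0 -> ``low``, >= 0 -> ``high``.
    * ``tertile`` — three rank-based groups ``low`` / ``mild`` / ``high`` at
      the 33.3% and 66.6% empirical quantiles.

    Returns a Series of labels aligned to the input index (original order).
    """
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    s = scores["stress_score"] if isinstance(scores, pd.DataFrame) else scores
    s = s.astype(float)
    n = len(s)
    labels = pd.Series(index=s.index, dtype=object, name="group")
    if scheme == "zero_mean":
        labels[:] = np.where(s.values < 0, "low", "high")
    elif scheme == "median":
        order = _rank_order(s)
        n_low = n - n // 2
        labels.loc[order[:n_low]] = "low"
        labels.loc[order[n_low:]] = "high"
    else:  # tertile
        order = _rank_order(s)
        n1, n2, _ = _tertile_sizes(n)
        labels.loc[order[:n1]] = "low"
        labels.loc[order[n1 : n1 + n2]] = "mild"
        labels.loc[order[n1 + n2 :]] = "high"
    counts = labels.value_counts()
    # zero_mean is a fixed sign rule, so a group may legitimately be small;
    # the rank-based schemes must yield usable group sizes
    min_size = 1 if scheme == "zero_mean" else 2
    if (counts < min_size).any() or counts.size < (3 if scheme == "tertile" else 2):
        raise ValidationError(
            f"each group needs >= {min_size} subject(s); got {counts.to_dict()} "
            f"under scheme {scheme!r}"
        )
    return labels
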