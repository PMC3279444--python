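"""Weekly physical-activity derivation and the day-redistribution
Monte Carlo sensitivity analysis.

One weekday diary per participant is scaled by 7 to weekly minutes and
classified into the WHO three-tier scheme: inactive (0 min/week),
insufficiently active (1-150), active (>150). The Monte Carlo relaxes the
constant-by-day assumption: within demographic strata, total person-minutes
are conserved while the set of nonsedentary people grows roughly k-fold
(active every other / every third day), each doing proportionally fewer
minutes.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import MonteCarloScheme

TIERS = ("inactive", "insufficient", "active")
PURPOSES = ("transport", "recreation")
WEEKLY_SCALE = 7.0
ACTIVE_CUTOFF = 150.0


def assign_tier(total_weekly: np.ndarray | float) -> np.ndarray:
    """WHO tier from total weekly minutes: 0 -> inactive, (0, 150] ->
    insufficient, > 150 -> active."""
    t = np.asarray(total_weekly, dtype=float)
    return np.select([t == 0, t <= ACTIVE_CUTOFF], ["inactive", "insufficient"], default="active")


def weekly_minutes(entries: pd.DataFrame) -> dict:
    """Weekly activity for one participant's single diary day (x7 scaling)."""
    if (entries.minutes_per_day < 0).any():
        raise ValueError("negative diary minutes")
    if entries.participant_id.nunique() > 1:
        raise ValueError("entries must belong to a single participant")
    per_purpose = entries.groupby("purpose").minutes_per_day.sum() * WEEKLY_SCALE
    transport = float(per_purpose.get("transport", 0.0))
    recreation = float(per_purpose.get("recreation", 0.0))
    total = transport + recreation
    return {
        "participant_id": entries.participant_id.iloc[0],
        "transport": transport,
        "recreation": recreation,
        "total": total,
        "tier": str(assign_tier(total)),
    }


def weekly_activity_table(diary: pd.DataFrame, participants: pd.DataFrame | None = None) -> pd.DataFrame:
    """Vectorized weekly-activity table for the whole cohort.

    Participants with no diary rows (if a participant table is supplied)
    get zeros, keeping the cohort accounting explicit.
    """
    if (diary.minutes_per_day < 0).any():
        raise ValueError("negative diary minutes")
    bad = set(diary.purpose) - set(PURPOSES)
    if bad:
        raise ValueError(f"unknown diary purpose(s): {sorted(bad)}")
    wide = (
        diary.pivot_table(index="participant_id", columns="purpose", values="minutes_per_day",
                          aggfunc="sum", fill_value=0.0)
        .reindex(columns=list(PURPOSES), fill_value=0.0)
        * WEEKLY_SCALE
    )
    if participants is not None:
        wide = wide.reindex(participants.participant_id, fill_value=0.0)
    out = wide.reset_index().rename_axis(columns=None)
    out["total"] = out.transport + out.recreation
    out["tier"] = assign_tier(out.total.to_numpy())
    return out


def cohort_activity_summary(weekly: pd.DataFrame, grouping: pd.Series | None = None) -> pd.DataFrame:
    """Per-group activity descriptives: mean minutes over everyone and over
    nonsedentary people only, tier shares, nonsedentary share."""
    if weekly.empty:
        raise ValueError("empty weekly activity table")
    df = weekly.copy()
    df["_group"] = "cohort" if grouping is None else np.asarray(grouping)
    rows = []
    for group, grp in df.groupby("_group"):
        nonsed = grp[grp.total > 0]
        row = {
            "group": group,
            "n": len(grp),
            "mean_minutes": grp.total.mean(),
            "mean_minutes_nonsedentary": nonsed.total.mean() if len(nonsed) else 0.0,
            "nonsedentary_share": len(nonsed) / len(grp),
            "transport_share": (grp.transport.sum() / grp.total.sum()) if grp.total.sum() else 0.0,
        }
        shares = grp.tier.value_counts(normalize=True)
        for tier in TIERS:
            row[f"share_{tier}"] = float(shares.get(tier, 0.0))
        rows.append(row)
    return pd.DataFrame(rows)


def _strata_labels(participants: pd.DataFrame, age_bins: list[float]) -> pd.Series:
    edges = [-np.inf] + list(age_bins) + [np.inf]
    age_bin = pd.cut(participants.age, bins=edges).astype(str)
    labels = age_bin + "|" + participants.sex.astype(str) + "|" + participants.ethnicity.astype(str)
    return pd.Series(labels.to_numpy(), index=participants.participant_id, name="stratum")


def monte_carlo_redistribution(
    weekly: pd.DataFrame,
    participants: pd.DataFrame,
    scheme: MonteCarloScheme,
    n_reps: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Redistribute weekly minutes as if nonsedentary people were active
    every k-th day.

    Per stratum (age bin x sex x ethnicity) and replicate: pooled
    nonsedentary minutes are conserved exactly; a new nonsedentary set of
    size min(stratum size, k x current count) is drawn uniformly without
    replacement and the pool is split equally within it. The per-person
    transport/recreation split follows the stratum's original transport
    share. Returns (replicate tables, per-replicate tier-share summary).
    """
    n_reps = n_reps if n_reps is not None else scheme.n_reps
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(scheme.seed)
    k = scheme.k
    strata = _strata_labels(participants, scheme.age_bins)
    missing = set(weekly.participant_id) - set(strata.index)
    if missing:
        raise ValueError(f"strata do not cover all participants, e.g. {sorted(missing)[:3]}")
    df = weekly.merge(strata.rename("stratum"), left_on="participant_id", right_index=True)

    replicates = []
    summaries = []
    for rep in range(n_reps):
        new_total = df.total.to_numpy().copy()
        new_transport = df.transport.to_numpy().copy()
        if k > 1:
            for _, grp in df.groupby("stratum", sort=True):
                idx = grp.index.to_numpy()
                pool = grp.total.sum()
                m = int((grp.total > 0).sum())
                if m == 0 or pool == 0:
                    continue
                new_m = min(len(idx), k * m)
                chosen = rng.choice(idx, size=new_m, replace=False)
                tshare = grp.transport.sum() / pool
                new_total[df.index.get_indexer(idx)] = 0.0
                new_transport[df.index.get_indexer(idx)] = 0.0
                sel = df.index.get_indexer(chosen)
                new_total[sel] = pool / new_m
                new_transport[sel] = pool / new_m * tshare
        rep_df = pd.DataFrame(
            {
                "participant_id": df.participant_id.to_numpy(),
                "transport": new_transport,
                "recreation": new_total - new_transport,
                "total": new_total,
            }
        )
        rep_df["tier"] = assign_tier(rep_df.total.to_numpy())
        replicates.append(rep_df)
        shares = rep_df.tier.value_counts(normalize=True)
        summaries.append(
            {"replicate": rep, **{f"share_{t}": float(shares.get(t, 0.0)) for t in TIERS}}
        )
    return replicates, pd.DataFrame(summaries)
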