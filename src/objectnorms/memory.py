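"""Item-wise recognition-memory scoring.

Trial-level old/new responses are aggregated per item and test into hit rate
(HR, proportion of "old" responses to old-status trials), false-alarm rate
(FAR, proportion of "old" responses to new-status trials), outcome-wise mean
response times, and signal-detection measures:

    d' = Z(HR) - Z(FAR)        (sensitivity)
    c  = -0.5 (Z(HR) + Z(FAR)) (response bias / criterion)

with Z the standard-normal quantile. Rates of exactly 0 or 1 are corrected
before the quantile transform; the default is the 1/(2N) rule (0 -> 1/(2N),
1 -> 1 - 1/(2N)), with an additive (count + 0.5)/(N + 1) alternative.

Analyses are item-level throughout: each item is scored from the raters who
saw it, with no participant-level modeling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

TESTS = ("visual", "lexical")
OUTCOMES = ("hit", "miss", "correct_rejection", "false_alarm")


def _outcome(status: str, response: str) -> str:
    if status == "old":
        return "hit" if response == "old" else "miss"
    return "false_alarm" if response == "old" else "correct_rejection"


def _validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    required = {"participant_id", "item_id", "test", "status", "response"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trials missing columns: {sorted(missing)}")
    for col, allowed in (("status", ("old", "new")), ("response", ("old", "new"))):
        bad = ~trials[col].isin(allowed)
        if bad.any():
            raise ValueError(f"invalid {col} value at row {trials.index[bad][0]}")
    dup = trials.duplicated(subset=["participant_id", "item_id", "test"])
    if dup.any():
        raise ValueError("multiple responses for one (participant, item, test)")
    both = trials.groupby(["participant_id", "item_id", "test"])["status"].nunique()
    if (both > 1).any():
        raise ValueError("an item appears as both old and new for one participant")
    return trials


def item_rates(trials: pd.DataFrame) -> pd.DataFrame:
    """Aggregate trials into per (item, test) rates, counts, and RT means.

    Returns a DataFrame indexed by (item_id, test) with columns ``HR``,
    ``FAR``, ``n_old_raters``, ``n_new_raters``, and ``rt_<outcome>`` means.
    An item with no old-status (new-status) trials gets a missing HR (FAR) —
    rates are never imputed.
    """
    trials = _validate_trials(trials)
    t = trials.copy()
    t["said_old"] = (t["response"] == "old").astype(float)

    grouped = t.groupby(["item_id", "test", "status"])
    agg = grouped["said_old"].agg(["mean", "count"]).unstack("status")

    out = pd.DataFrame(index=agg.index)
    if ("mean", "old") in agg.columns:
        out["HR"] = agg[("mean", "old")]
        out["n_old_raters"] = agg[("count", "old")].fillna(0).astype(int)
    else:
        out["HR"], out["n_old_raters"] = np.nan, 0
    if ("mean", "new") in agg.columns:
        out["FAR"] = agg[("mean", "new")]
        out["n_new_raters"] = agg[("count", "new")].fillna(0).astype(int)
    else:
        out["FAR"], out["n_new_raters"] = np.nan, 0

    if "rt_ms" in t.columns:
        t["outcome"] = [
            _outcome(s, r) for s, r in zip(t["status"], t["response"])
        ]
        rts = (
            t.dropna(subset=["rt_ms"])
            .groupby(["item_id", "test", "outcome"])["rt_ms"]
            .mean()
            .unstack("outcome")
        )
        for oc in OUTCOMES:
            col = rts[oc] if oc in rts.columns else np.nan
            out[f"rt_{oc}"] = col
    return out


def correct_extreme_rate(rate: np.ndarray, n: np.ndarray, correction: str = "half-n") -> np.ndarray:
    """Correct rates of exactly 0 or 1 so the normal quantile is finite.

    ``"half-n"``: 0 -> 1/(2N), 1 -> 1 - 1/(2N), other rates untouched.
    ``"add-half"``: every rate becomes (rate * N + 0.5) / (N + 1).
    """
    rate = np.asarray(rate, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValueError("rater counts must be positive")
    if np.any((rate < 0) | (rate > 1)):
        raise ValueError("rates must lie in [0, 1]")
    if correction == "half-n":
        lo, hi = 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)
        return np.clip(rate, lo, hi)
    if correction == "add-half":
        return (rate * n + 0.5) / (n + 1)
    raise ValueError(f"unknown correction policy {correction!r}")


def signal_detection(
    hr, far, n_old, n_new, correction: str = "half-n"
) -> pd.DataFrame:
    """Z-transformed rates, d', and criterion c (vectorized).

    Returns a DataFrame with columns ``Z_HR``, ``Z_FAR``, ``dprime``,
    ``criterion_c``; missing rates propagate to missing outputs.
    """
    hr = np.asarray(hr, dtype=float)
    far = np.asarray(far, dtype=float)
    z_hr = np.full_like(hr, np.nan)
    z_far = np.full_like(far, np.nan)
    ok_h = ~np.isnan(hr)
    ok_f = ~np.isnan(far)
    n_old = np.broadcast_to(np.asarray(n_old, dtype=float), hr.shape)
    n_new = np.broadcast_to(np.asarray(n_new, dtype=float), far.shape)
    if ok_h.any():
        z_hr[ok_h] = norm.ppf(correct_extreme_rate(hr[ok_h], n_old[ok_h], correction))
    if ok_f.any():
        z_far[ok_f] = norm.ppf(correct_extreme_rate(far[ok_f], n_new[ok_f], correction))
    return pd.DataFrame(
        {
            "Z_HR": z_hr,
            "Z_FAR": z_far,
            "dprime": z_hr - z_far,
            "criterion_c": -0.5 * (z_hr + z_far),
        }
    )


def score_items(trials: pd.DataFrame, correction: str = "half-n") -> pd.DataFrame:
    """Full item-wise score table: rates, counts, RTs, and SDT measures."""
    rates = item_rates(trials)
    sdt = signal_detection(
        rates["HR"].to_numpy(),
        rates["FAR"].to_numpy(),
        rates["n_old_raters"].to_numpy().clip(min=1),
        rates["n_new_raters"].to_numpy().clip(min=1),
        correction=correction,
    )
    sdt.index = rates.index
    return pd.concat([rates, sdt], axis=1)


def summarize_test(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD across items of HR/FAR (and RTs) per test.

    SDs are across items; participant-level spread is not recoverable from
    item-wise scores and is reported by the trial-level pipeline instead.
    """
    cols = [c for c in scores.columns if c in ("HR", "FAR") or c.startswith("rt_")]
    g = scores.reset_index().groupby("test")[cols]
    out = pd.concat({"mean": g.mean(), "sd_items": g.std()}, axis=1)
    return out


def category_summary(
    scores: pd.DataFrame, category_map: pd.Series, min_items: int = 5
) -> pd.DataFrame:
    """Per-category mean HR by test; categories below ``min_items`` dropped."""
    df = scores.reset_index()
    df["category"] = df["item_id"].map(category_map)
    if df["category"].isna().any():
        raise ValueError("every item must map to one category")
    out = (
        df.groupby(["category", "test"])["HR"]
        .agg(mean_HR="mean", n_items="count")
        .reset_index()
    )
    out = out[out["n_items"] >= min_items]
    return out.set_index(["category", "test"])


def top_bottom_items(scores: pd.DataFrame, k: int = 10) -> dict[str, dict[str, list[str]]]:
    """The k most- and least-remembered items (by HR) per test.

    Ties are broken by item_id so rankings are reproducible.
    """
    out: dict[str, dict[str, list[str]]] = {}
    df = scores.reset_index().dropna(subset=["HR"])
    for test, sub in df.groupby("test"):
        if len(sub) < 2 * k:
            raise ValueError(f"test {test!r}: need at least {2 * k} scored items")
        ranked = sub.sort_values(["HR", "item_id"], ascending=[False, True])
        out[test] = {
            "top": ranked["item_id"].head(k).tolist(),
            "bottom": ranked.sort_values(["HR", "item_id"], ascending=[True, True])["item_id"].head(k).tolist(),
        }
    return out


def read_trials(path) -> pd.DataFrame:
    """Read a trials CSV (participant_id, item_id, test, status, response[, rt_ms])."""
    df = pd.read_csv(path, dtype={"participant_id": str, "item_id": str})
    if "rt_ms" in df.columns:
        df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="coerce")
    return df
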