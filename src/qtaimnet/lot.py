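"""Descriptor and connectivity robustness between two dataset tiers.

Two tiers of the same molecules (e.g. densities from two levels of theory)
are matched by molecule id; their critical points are matched deterministically
by atom index (nuclear CPs) or sorted endpoint pair (bond CPs).  Robustness is
summarized by

* the median absolute base-10 log ratio per descriptor,
  Delta = |log10 max(|a|, eps) - log10 max(|b|, eps)|, pooled over all matched
  CPs dataset-wide (pairs whose values disagree in sign are excluded from the
  median but counted — the Laplacian and eigenvalues can legitimately change
  sign between tiers and a signed log is undefined), and
* per-molecule bond-path count differences: a histogram of |count_A - count_B|
  and the percentage of molecules within k of each other.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Log-safety floor applied to descriptor magnitudes.
LOG_EPS = 1e-12


class DuplicateIdError(ValueError):
    pass


def match_complexes(ids_a, ids_b) -> tuple[list, list, list]:
    """Intersection by molecule id; returns (matched, only_a, only_b)."""
    ids_a, ids_b = list(ids_a), list(ids_b)
    for name, ids in (("A", ids_a), ("B", ids_b)):
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateIdError(f"duplicate ids within tier {name}: {dup}")
    set_a, set_b = set(ids_a), set(ids_b)
    matched = [i for i in ids_a if i in set_b]
    return matched, [i for i in ids_a if i not in set_b], [i for i in ids_b if i not in set_a]


def median_log_difference(values_a, values_b, eps: float = LOG_EPS):
    """Median |log10| ratio over paired values; sign-mismatched pairs excluded.

    Returns (median, n_used, n_sign_excluded); the median is NaN with zero
    comparable pairs.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired value arrays must have equal length")
    finite = np.isfinite(a) & np.isfinite(b)
    a, b = a[finite], b[finite]
    sign_ok = np.sign(a) * np.sign(b) >= 0  # zeros never count as mismatches
    n_excluded = int((~sign_ok).sum())
    a, b = a[sign_ok], b[sign_ok]
    if a.size == 0:
        return math.nan, 0, n_excluded
    delta = np.abs(np.log10(np.maximum(np.abs(a), eps))
                   - np.log10(np.maximum(np.abs(b), eps)))
    return float(np.median(delta)), int(a.size), n_excluded


def bond_count_stats(counts_a: dict, counts_b: dict, ks=(0, 1, 2)) -> dict:
    """Histogram of per-molecule |bond path count difference| and percent_within.

    ``counts_a``/``counts_b`` map molecule id -> bond path count; only ids
    present in both are used.
    """
    matched, _, _ = match_complexes(list(counts_a), list(counts_b))
    diffs = [abs(int(counts_a[i]) - int(counts_b[i])) for i in matched]
    hist = dict(sorted(Counter(diffs).items()))
    n = len(diffs)

    def percent_within(k):
        if n == 0:
            return math.nan
        return 100.0 * sum(1 for d in diffs if d <= k) / n

    return {
        "n": n,
        "histogram": hist,
        "percent_within": {int(k): percent_within(k) for k in ks},
        "diffs": diffs,
    }


@dataclass
class LOTComparisonReport:
    matched_ids: list[str]
    unmatched_a: list[str]
    unmatched_b: list[str]
    #: (cp_kind, descriptor) -> {"median_log_diff", "n_pairs", "n_sign_excluded"}
    descriptor_stats: dict[tuple[str, str], dict] = field(default_factory=dict)
    bond_counts: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cp_kind": kind, "descriptor": name, **stats}
            for (kind, name), stats in self.descriptor_stats.items()
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "matched": len(self.matched_ids),
            "unmatched_a": self.unmatched_a,
            "unmatched_b": self.unmatched_b,
            "descriptors": [
                {"cp_kind": k, "descriptor": d, **s}
                for (k, d), s in self.descriptor_stats.items()
            ],
            "bond_counts": {
                k: v for k, v in self.bond_counts.items() if k != "diffs"
            },
        }


def compare_tiers(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    counts_a: dict | None = None,
    counts_b: dict | None = None,
    descriptors: list[str] | None = None,
    ks=(0, 1, 2),
) -> LOTComparisonReport:
    """Full tier comparison from flattened descriptor tables.

    The tables are the CSV layout of :func:`qtaimnet.io.descriptor_table`
    (columns id, cp_kind, key, one column per descriptor); CPs are joined on
    (id, cp_kind, key).  Extra columns in externally produced tables are
    tolerated and ignored unless named in ``descriptors``.
    """
    ids_a = sorted(table_a["id"].unique())
    ids_b = sorted(table_b["id"].unique())
    matched, only_a, only_b = match_complexes(ids_a, ids_b)

    join_cols = ["id", "cp_kind", "key"]
    if descriptors is None:
        skip = set(join_cols)
        descriptors = [
            c for c in table_a.columns
            if c not in skip and c in table_b.columns
            and pd.api.types.is_numeric_dtype(table_a[c])
        ]
    merged = table_a.merge(table_b, on=join_cols, suffixes=("_a", "_b"))

    stats = {}
    for kind in ("nuclear", "bond"):
        sub = merged[merged["cp_kind"] == kind]
        for name in descriptors:
            ca, cb = f"{name}_a", f"{name}_b"
            if ca not in sub.columns:
                continue
            med, n_used, n_exc = median_log_difference(sub[ca], sub[cb])
            stats[(kind, name)] = {
                "median_log_diff": med,
                "n_pairs": n_used,
                "n_sign_excluded": n_exc,
            }

    report = LOTComparisonReport(
        matched_ids=matched, unmatched_a=only_a, unmatched_b=only_b,
        descriptor_stats=stats,
    )
    if counts_a is not None and counts_b is not None:
        report.bond_counts = bond_count_stats(counts_a, counts_b, ks=ks)
    return report
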