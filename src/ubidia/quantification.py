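"""Label-free quantification: precursor quantities, normalization,
peptide aggregation (mean and MaxLFQ) and CV diagnostics.

The precursor quantity is the area of the candidate window under the
mean of the k fragment traces most correlated with the best fragment — a
documented, transparent peak-area rule.  Aggregation to peptides is
available two ways: averaging of normalized precursor intensities, and
the MaxLFQ algorithm (median pairwise log-ratios solved in least
squares).  Matrices are normalized by median sample scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import ScoredCandidate
from .synthetic_data import ChromatogramSet

__all__ = [
    "QuantTable",
    "precursor_quantity",
    "quantify_precursors",
    "median_scale",
    "aggregate_mean",
    "aggregate_maxlfq",
    "maxlfq_profile",
    "cv_percent",
    "cv_table",
]


@dataclass
class QuantTable:
    """A feature × sample intensity matrix with provenance.

    ``data`` holds positive intensities with NaN for missing values;
    ``level`` is one of precursor / peptide / site / protein.
    """

    level: str
    data: pd.DataFrame
    feature_meta: pd.DataFrame | None = None
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.level not in {"precursor", "peptide", "site", "protein"}:
            raise ValueError(f"unknown level {self.level!r}")
        if not self.data.index.is_unique or not self.data.columns.is_unique:
            raise ValueError("feature/sample ids must be unique")
        vals = self.data.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError("intensities must be > 0 where present")

    def copy_with(self, data: pd.DataFrame, level: str | None = None,
                  feature_meta: pd.DataFrame | None = None) -> "QuantTable":
        return QuantTable(
            level=level or self.level,
            data=data,
            feature_meta=feature_meta,
            sample_meta=self.sample_meta,
        )


# ---------------------------------------------------------------------------
# Precursor quantities
# ---------------------------------------------------------------------------

def precursor_quantity(
    candidate: ScoredCandidate, cs: ChromatogramSet, k: int = 3
) -> float:
    """Window area of the mean trace of the k fragments most correlated
    with the best fragment (the best fragment itself included, r = 1)."""
    lo, hi = candidate.window
    if hi < lo:
        return 0.0
    n_frag = cs.fragment_traces.shape[0]
    best_idx = next(
        i for i, a in enumerate(cs.fragments)
        if a.fragment_id == candidate.best_fragment
    )
    r = np.asarray(candidate.corr, dtype=float).copy()
    r[best_idx] = np.inf  # the best fragment always makes the top-k
    k_eff = min(k, n_frag)
    top = np.argsort(-r, kind="stable")[:k_eff]
    return float(cs.fragment_traces[np.ix_(top, range(lo, hi + 1))].mean(axis=0).sum())


def quantify_precursors(
    search_result,
    runs: dict[str, dict[str, ChromatogramSet]],
    k: int = 3,
    targets_only: bool = True,
) -> QuantTable:
    """Precursor-level QuantTable (precursor × run) from retained candidates."""
    reported = set(
        zip(search_result.report["run"], search_result.report["precursor_id"])
    )
    rows: dict[str, dict[str, float]] = {}
    for (run, pid), cand in search_result.retained.items():
        if targets_only and (run, pid) not in reported:
            continue
        qty = precursor_quantity(cand, runs[run][pid], k=k)
        cand.quantity = qty
        if qty > 0:
            rows.setdefault(pid, {})[run] = qty
    df = pd.DataFrame(rows).T.sort_index()
    df = df.reindex(sorted(df.columns), axis=1)
    return QuantTable(level="precursor", data=df)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def median_scale(qt: QuantTable) -> QuantTable:
    """Median sample scaling: every sample is multiplied so that all
    per-sample medians (over present values) equal the global median of
    the original per-sample medians."""
    med = qt.data.median(axis=0, skipna=True)
    if med.isna().any():
        bad = med.index[med.isna()][0]
        raise ValueError(f"sample {bad!r} has no present values")
    target = float(med.median())
    scaled = qt.data * (target / med)
    return qt.copy_with(scaled, feature_meta=qt.feature_meta)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_mean(qt: QuantTable, mapping: pd.Series,
                   level: str = "peptide") -> QuantTable:
    """Presence-aware arithmetic mean of each group's precursors."""
    groups = mapping.reindex(qt.data.index)
    if groups.isna().any():
        missing = groups.index[groups.isna()][0]
        raise ValueError(f"no group for feature {missing!r}")
    out = qt.data.groupby(groups).mean()
    return qt.copy_with(out, level=level)


def maxlfq_profile(block: np.ndarray, min_shared: int = 1) -> np.ndarray:
    """MaxLFQ for one group: ``block`` is (precursors × samples) raw
    intensities with NaN for missing.

    Pairwise sample log-ratios are medians of per-precursor log-ratios
    over precursors present in both samples; per-sample log-abundances
    solve the least-squares system; the free scale of each connected
    component is fixed so its summed output equals its summed input.
    Samples disconnected from the ratio graph stay missing.
    """
    block = np.asarray(block, dtype=float)
    n_prec, n_samp = block.shape
    present = ~np.isnan(block)
    sample_has = present.any(axis=0)
    if n_prec == 1:
        return block[0].copy()
    log = np.log(block)
    ratio = np.full((n_samp, n_samp), np.nan)
    for j in range(n_samp):
        for k in range(j + 1, n_samp):
            both = present[:, j] & present[:, k]
            if both.sum() >= min_shared:
                ratio[j, k] = np.median(log[both, j] - log[both, k])
                ratio[k, j] = -ratio[j, k]

    # connected components of the ratio graph
    adj = ~np.isnan(ratio)
    comp = np.full(n_samp, -1)
    n_comp = 0
    for s in range(n_samp):
        if comp[s] >= 0 or not sample_has[s]:
            continue
        stack = [s]
        comp[s] = n_comp
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(adj[u]):
                if comp[v] < 0:
                    comp[v] = n_comp
                    stack.append(v)
        n_comp += 1

    out = np.full(n_samp, np.nan)
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        if members.size == 1:
            j = members[0]
            vals = block[present[:, j], j]
            out[j] = vals.mean() if vals.size else np.nan
            continue
        # least squares on a_j - a_k = ratio_jk, plus a gauge row
        rows, rhs = [], []
        for ji, j in enumerate(members):
            for ki, k in enumerate(members):
                if ki <= ji or np.isnan(ratio[j, k]):
                    continue
                r = np.zeros(members.size)
                r[ji], r[ki] = 1.0, -1.0
                rows.append(r)
                rhs.append(ratio[j, k])
        rows.append(np.ones(members.size))
        rhs.append(0.0)
        a, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
        prof = np.exp(a)
        total_in = np.nansum(block[:, members])
        out[members] = prof * (total_in / prof.sum())
    return out


def aggregate_maxlfq(qt: QuantTable, mapping: pd.Series,
                     level: str = "peptide", min_shared: int = 1) -> QuantTable:
    """MaxLFQ aggregation of precursors to the given grouping."""
    groups = mapping.reindex(qt.data.index)
    if groups.isna().any():
        missing = groups.index[groups.isna()][0]
        raise ValueError(f"no group for feature {missing!r}")
    out_rows = {}
    for g, sub in qt.data.groupby(groups):
        out_rows[g] = maxlfq_profile(sub.to_numpy(), min_shared=min_shared)
    out = pd.DataFrame.from_dict(out_rows, orient="index", columns=qt.data.columns)
    out = out.sort_index()
    # all-missing rows cannot occur (groups come from present precursors)
    return qt.copy_with(out, level=level)


# ---------------------------------------------------------------------------
# CV diagnostics
# ---------------------------------------------------------------------------

def cv_percent(values) -> float:
    """Percent coefficient of variation on raw intensities (sample SD,
    n−1 denominator); NaN for fewer than two present values."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        return float("nan")
    return float(100.0 * v.std(ddof=1) / v.mean())


def cv_table(qt: QuantTable, group_cols: tuple[str, ...] = ("condition", "time_min")):
    """Per-feature CV within each replicate group (raw intensities)."""
    if qt.sample_meta is None:
        return qt.data.apply(cv_percent, axis=1).to_frame("cv_percent")
    meta = qt.sample_meta.loc[qt.data.columns]
    keys = [meta[c] for c in group_cols if c in meta.columns]
    out = {}
    for name, cols in meta.groupby(keys, observed=True).groups.items():
        out[name] = qt.data[list(cols)].apply(cv_percent, axis=1)
    return pd.DataFrame(out)
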