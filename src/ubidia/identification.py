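"""Precursor-level search orchestration with two-pass target-decoy FDR.

The search scores every (precursor × run) pair including pseudo-reversed
decoys, estimates q-values by target-decoy counting, and follows the
two-step workflow of library-free DIA engines: pass 1 searches the full
retention-time range and builds an internal library from precursors
passing BOTH the experiment-wide (global) and the run-specific 1 % FDR
filters; pass 2 re-scores only library precursors inside calibrated
retention-time windows (per-run linear fit of pass-1 apexes against the
library reference RT), which is the match-between-runs semantics — a
precursor may be reported in runs where only pass 2 found it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import CompositeScorer, ScoredCandidate, score_chromatograms
from .synthetic_data import ChromatogramSet

__all__ = [
    "SearchResult",
    "qvalues",
    "two_pass_search",
    "empirical_fdr",
]


@dataclass
class SearchResult:
    report: pd.DataFrame                 # final filtered target report
    all_candidates: pd.DataFrame         # retained best per (precursor, run), incl. decoys
    retained: dict[tuple[str, str], ScoredCandidate]  # (run, precursor_id) -> candidate
    rt_calibration: dict[str, tuple[float, float, float]]  # run -> (a, b, resid_sd)
    pass1_candidates: pd.DataFrame | None = None  # full-space pass-1 q-values
    pass_number: int = 2
    scorer: CompositeScorer | None = None


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------

def estimate_pi0(scores: np.ndarray, decoy: np.ndarray) -> float:
    """Decoy-anchored estimate of the null fraction among targets.

    Nulls among the targets distribute like decoys, while true hits
    rarely score below the decoy median, so the fraction of targets at
    or below the decoy median estimates pi0 / 2.  Falls back to 1 (the
    plain target-decoy estimator) when there are too few decoys to
    anchor the null.
    """
    scores = np.asarray(scores, dtype=float)
    decoy = np.asarray(decoy, dtype=bool)
    n_t = int((~decoy).sum())
    if decoy.sum() < 20 or n_t == 0:
        return 1.0
    m = float(np.median(scores[decoy]))
    below = int((scores[~decoy] <= m).sum())
    return float(min(1.0, 2.0 * (below + 1) / n_t))


def qvalues(scores: np.ndarray, decoy: np.ndarray,
            pi0: float | str | None = None) -> np.ndarray:
    """Target-decoy q-values.

    For each score threshold t (descending), FDR(t) = pi0 × #decoys >= t /
    max(1, #targets >= t); the q-value is the running minimum of FDR
    over all thresholds at or below the entry's score, hence monotone
    non-decreasing as the score decreases.  Ties share one threshold.

    ``pi0`` scales the decoy count by the estimated null fraction of the
    target list: ``None``/1 gives the plain estimator, ``"auto"``
    estimates it from the low-score region (see :func:`estimate_pi0`),
    which keeps realized FDP tracking nominal q even when a large
    fraction of searched targets is truly present.
    """
    scores = np.asarray(scores, dtype=float)
    decoy = np.asarray(decoy, dtype=bool)
    if scores.size == 0:
        return np.zeros(0)
    if not (~decoy).any():
        raise ValueError("q-value estimation requires at least one target")
    if not decoy.any():
        warnings.warn("no decoys: q-values are all 0 (uninformative null)")
    if pi0 == "auto":
        pi0 = estimate_pi0(scores, decoy)
    elif pi0 is None:
        pi0 = 1.0
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    d = decoy[order]
    cum_d = np.cumsum(d)
    cum_t = np.cumsum(~d)
    # counts at the end of each tie block (all entries with score >= s_i)
    _, inv, counts = np.unique(-s, return_inverse=True, return_counts=True)
    ends = np.cumsum(counts) - 1
    hi = ends[inv]
    fdr = np.minimum(1.0, pi0 * cum_d[hi] / np.maximum(1, cum_t[hi]))
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def _assign_q(candidates: list[ScoredCandidate]) -> None:
    """Fill q_run per run and q_global (best composite per precursor)."""
    if not candidates:
        return
    df = pd.DataFrame({
        "run": [c.run for c in candidates],
        "pid": [c.precursor_id for c in candidates],
        "decoy": [c.decoy for c in candidates],
        "score": [c.composite for c in candidates],
    })
    # run-specific q over each run's retained candidates
    for run, sub in df.groupby("run"):
        q = qvalues(sub["score"].to_numpy(), sub["decoy"].to_numpy(), pi0="auto")
        for i, qi in zip(sub.index, q):
            candidates[i].q_run = float(qi)
    # global q over best score per precursor across runs
    best = df.groupby("pid").agg(score=("score", "max"), decoy=("decoy", "first"))
    qg = pd.Series(
        qvalues(best["score"].to_numpy(), best["decoy"].to_numpy(), pi0="auto"),
        index=best.index,
    )
    for i, pid in enumerate(df["pid"]):
        candidates[i].q_global = float(qg[pid])


def _retain_best(candidates: list[ScoredCandidate]) -> list[ScoredCandidate]:
    """At most one candidate per (run, precursor): the top composite."""
    best: dict[tuple[str, str], ScoredCandidate] = {}
    for c in candidates:
        key = (c.run, c.precursor_id)
        if key not in best or c.composite > best[key].composite:
            best[key] = c
    return list(best.values())


def _candidates_frame(candidates: list[ScoredCandidate]) -> pd.DataFrame:
    from .scoring import SCORE_COMPONENTS

    rows = []
    for c in candidates:
        row = {
            "run": c.run,
            "precursor_id": c.precursor_id,
            "decoy": c.decoy,
            "composite": c.composite,
            "q_global": c.q_global,
            "q_run": c.q_run,
            "apex_rt": c.apex_rt,
            "best_fragment": c.best_fragment,
            "quantity": c.quantity,
        }
        row.update({k: c.components[k] for k in SCORE_COMPONENTS})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Two-pass search
# ---------------------------------------------------------------------------

def _score_pass(
    runs: dict[str, dict[str, ChromatogramSet]],
    is_decoy: dict[str, bool],
    config,
    restrict: dict[str, dict[str, tuple[float, float]]] | None = None,
) -> list[ScoredCandidate]:
    out: list[ScoredCandidate] = []
    for run_name, chroms in runs.items():
        windows = restrict.get(run_name, {}) if restrict is not None else None
        for pid, cs in chroms.items():
            if restrict is not None and pid not in windows:
                continue
            out.extend(
                score_chromatograms(
                    pid, is_decoy[pid], cs, config=config,
                    rt_window=None if restrict is None else windows[pid],
                    run=run_name,
                )
            )
    return out


def two_pass_search(
    runs: dict[str, dict[str, ChromatogramSet]],
    pairs: dict[str, str],
    config=None,
    seed: int = 0,
) -> SearchResult:
    """Score all precursors in all runs, then re-search with calibrated
    RT windows restricted to the pass-1 library.

    ``pairs`` maps each target precursor id to its decoy's id; every id
    in ``pairs`` (both sides) must be present in each run's
    chromatogram collection.
    """
    from .config import RunConfig

    cfg = config or RunConfig()
    if not runs:
        raise ValueError("at least one run is required")
    is_decoy = {pid: False for pid in pairs}
    is_decoy.update({did: True for did in pairs.values()})

    # ---- pass 1: unrestricted search ----
    cands1 = _score_pass(runs, is_decoy, cfg)
    scorer = CompositeScorer(fdr_level=cfg.fdr_level, seed=seed).fit(cands1)
    comp = scorer.score(cands1)
    for c, s in zip(cands1, comp):
        c.composite = float(s)
    retained1 = _retain_best(cands1)
    _assign_q(retained1)

    # ---- library: global AND run-specific 1 % FDR in >= 1 run ----
    by_pid: dict[str, list[ScoredCandidate]] = {}
    for c in retained1:
        by_pid.setdefault(c.precursor_id, []).append(c)
    library: dict[str, float] = {}          # target id -> reference RT
    for pid, decoy_id in pairs.items():
        cands = by_pid.get(pid, [])
        if not cands:
            continue
        if min(c.q_global for c in cands) <= cfg.fdr_level and any(
            c.q_run <= cfg.fdr_level for c in cands
        ):
            ref = max(cands, key=lambda c: c.composite)
            library[pid] = ref.apex_rt

    grid = next(iter(next(iter(runs.values())).values())).rt
    step = float(grid[1] - grid[0]) if grid.size > 1 else 1.0

    # ---- per-run linear RT calibration from pass-1 confident hits ----
    calibration: dict[str, tuple[float, float, float]] = {}
    windows: dict[str, dict[str, tuple[float, float]]] = {}
    for run_name in runs:
        pts = [
            (library[c.precursor_id], c.apex_rt)
            for c in retained1
            if c.run == run_name and c.precursor_id in library
            and c.q_run <= cfg.fdr_level
        ]
        if len(pts) < 2:
            a, b, resid_sd = 0.0, 1.0, float("inf")
            warnings.warn(f"{run_name}: <2 library precursors; identity RT map")
        else:
            ref = np.array([p[0] for p in pts])
            obs = np.array([p[1] for p in pts])
            b, a = np.polyfit(ref, obs, 1)
            resid_sd = float(np.std(obs - (a + b * ref), ddof=1)) if len(pts) > 2 else 0.0
        calibration[run_name] = (float(a), float(b), resid_sd)
        half = max(
            cfg.rt_window_sds * (0.0 if not np.isfinite(resid_sd) else resid_sd),
            cfg.rt_window_floor * step,
        )
        if not np.isfinite(resid_sd):
            half = float(grid[-1] - grid[0])
        wins = {}
        for pid, ref_rt in library.items():
            center = a + b * ref_rt
            wins[pid] = (center - half, center + half)
            wins[pairs[pid]] = wins[pid]  # the paired decoy shares the window
        windows[run_name] = wins

    # ---- pass 2: restricted re-search, rescored with the pass-1 model ----
    cands2 = _score_pass(runs, is_decoy, cfg, restrict=windows)
    comp2 = scorer.score(cands2)
    for c, s in zip(cands2, comp2):
        c.composite = float(s)
    retained2 = _retain_best(cands2)
    if not retained2:
        retained2 = retained1  # degenerate: empty library
    _assign_q(retained2)

    all_df = _candidates_frame(retained2)
    report = all_df[(~all_df["decoy"]) & (all_df["q_global"] <= cfg.fdr_level)]
    report = report.sort_values(["run", "q_global", "precursor_id"]).reset_index(drop=True)
    return SearchResult(
        report=report,
        all_candidates=all_df,
        retained={(c.run, c.precursor_id): c for c in retained2},
        rt_calibration=calibration,
        pass1_candidates=_candidates_frame(retained1),
        pass_number=2,
        scorer=scorer,
    )


def empirical_fdr(report: pd.DataFrame, present_ids: set[str]) -> float:
    """Realized false-discovery proportion of a target report against
    synthetic ground truth: the fraction of reported target precursors
    absent from the set of truly present ones."""
    ids = report.loc[~report["decoy"], "precursor_id"].unique()
    if len(ids) == 0:
        return 0.0
    false = sum(1 for pid in ids if pid not in present_ids)
    return false / len(ids)
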