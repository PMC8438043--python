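"""Correlation-based evidence scoring for modified-peptide candidates.

In DIA, a peptide is matched to a series of consecutive spectra, so each
fragment ion traces an elution profile; co-eluting fragments of a truly
present peptide correlate, interference does not.  For every candidate
elution peak the scorer designates a "best" fragment (the one whose
profile best correlates with all the others) and summarizes evidence as
sums of Pearson correlations to the best fragment, partitioned by
whether a fragment's sequence span covers the K-GG–modified lysine
and/or another candidate (unmodified) lysine:

========================  =========================  ===========================
component                 covers modified K          covers other candidate K
========================  =========================  ===========================
S_site_determining        yes                        no
S_site_containing         yes                        yes
S_other_site              no                         yes
S_shared                  no                         no
========================  =========================  ===========================

plus the MS1-to-best-fragment correlation and the count of fragments
with r above a threshold.  A transparent linear discriminant (logistic
regression trained targets-vs-decoys, one Percolator-style iteration)
combines the components into a composite score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .masses_digestion import FragmentAnnotation, Precursor
from .synthetic_data import ChromatogramSet

__all__ = [
    "SCORE_COMPONENTS",
    "ScoredCandidate",
    "pearson",
    "correlation_matrix",
    "find_candidate_peaks",
    "best_fragment",
    "kgg_evidence_scores",
    "score_chromatograms",
    "CompositeScorer",
]

SCORE_COMPONENTS = (
    "S_site_determining",
    "S_site_containing",
    "S_other_site",
    "S_shared",
    "ms1_corr",
    "n_corr_gt",
)


@dataclass
class ScoredCandidate:
    """One candidate elution peak for one precursor in one run."""

    precursor_id: str
    decoy: bool
    apex_index: int
    window: tuple[int, int]              # [lo, hi] grid indices, inclusive
    apex_rt: float
    best_fragment: str
    corr: np.ndarray                     # per-fragment r to the best fragment
    components: dict[str, float]
    composite: float = np.nan
    q_global: float = np.nan
    q_run: float = np.nan
    run: str = ""
    quantity: float = np.nan
    low_evidence: bool = False

    def component_vector(self) -> np.ndarray:
        return np.array([self.components[k] for k in SCORE_COMPONENTS])


# ---------------------------------------------------------------------------
# Correlation primitives
# ---------------------------------------------------------------------------

def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r with the degenerate-case contract: constant input or
    fewer than 3 points gives r = 0 (never NaN)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size < 3:
        return 0.0
    da = a - a.mean()
    db = b - b.mean()
    na = np.sqrt(da @ da)
    nb = np.sqrt(db @ db)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip((da @ db) / (na * nb), -1.0, 1.0))


def correlation_matrix(x: np.ndarray) -> np.ndarray:
    """Pairwise Pearson matrix over rows, constant rows giving r = 0."""
    x = np.asarray(x, dtype=float)
    n, m = x.shape
    if m < 3:
        return np.zeros((n, n))
    d = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((d * d).sum(axis=1))
    ok = norms > 0
    dn = np.where(ok[:, None], d / np.where(norms[:, None] == 0, 1.0, norms[:, None]), 0.0)
    r = np.clip(dn @ dn.T, -1.0, 1.0)
    r[~ok, :] = 0.0
    r[:, ~ok] = 0.0
    return r


# ---------------------------------------------------------------------------
# Candidate peak discovery
# ---------------------------------------------------------------------------

def _moving_mean(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return y.astype(float)
    kernel = np.ones(width) / width
    return np.convolve(y, kernel, mode="same")


def find_candidate_peaks(
    cs: ChromatogramSet,
    min_points: int = 3,
    smooth_width: int = 3,
    max_halfwidth: int = 8,
    max_candidates: int | None = None,
    rt_window: tuple[float, float] | None = None,
) -> list[tuple[int, tuple[int, int]]]:
    """Local maxima of the lightly smoothed summed fragment trace.

    Windows extend to the surrounding local minima, clipped to
    ``max_halfwidth`` grid points either side; candidates are ordered by
    summed apex intensity.  ``rt_window`` restricts apexes to a
    retention-time interval (used by the calibrated second search pass).
    """
    if min_points < 3:
        raise ValueError("min_points must be >= 3")
    total = cs.fragment_traces.sum(axis=0)
    if not np.any(total > 0):
        return []
    smoothed = _moving_mean(total, smooth_width)
    n = smoothed.size
    lo_idx, hi_idx = 0, n - 1
    if rt_window is not None:
        lo_idx = int(np.searchsorted(cs.rt, rt_window[0], side="left"))
        hi_idx = int(np.searchsorted(cs.rt, rt_window[1], side="right")) - 1
        if hi_idx < lo_idx:
            return []
    interior = smoothed[1:-1]
    is_max = (interior >= smoothed[:-2]) & (interior > smoothed[2:]) & (interior > 0)
    apexes = np.flatnonzero(is_max) + 1
    apexes = apexes[(apexes >= lo_idx) & (apexes <= hi_idx)]
    candidates = []
    for apex in apexes:
        lo = apex
        while lo > 0 and smoothed[lo - 1] < smoothed[lo] and apex - lo < max_halfwidth:
            lo -= 1
        hi = apex
        while hi < n - 1 and smoothed[hi + 1] < smoothed[hi] and hi - apex < max_halfwidth:
            hi += 1
        if hi - lo + 1 < min_points:
            # widen symmetrically to the minimum window length
            need = min_points - (hi - lo + 1)
            lo = max(0, lo - (need + 1) // 2)
            hi = min(n - 1, lo + min_points - 1)
            lo = max(0, hi - min_points + 1)
        candidates.append((int(apex), (int(lo), int(hi))))
    candidates.sort(key=lambda c: (-total[c[0]], c[0]))
    if max_candidates is not None:
        candidates = candidates[:max_candidates]
    return candidates


# ---------------------------------------------------------------------------
# Best fragment and evidence components
# ---------------------------------------------------------------------------

def best_fragment(
    cs: ChromatogramSet, window: tuple[int, int]
) -> tuple[int, np.ndarray, bool]:
    """Index of the fragment whose profile best correlates with the rest.

    Returns ``(best_index, r_vector, low_evidence)`` where ``r_vector``
    holds each fragment's correlation to the best fragment on the
    window.  Ties break on (series, index, charge); fragments are stored
    in that order, so the first argmax wins.
    """
    lo, hi = window
    sub = cs.fragment_traces[:, lo: hi + 1]
    n_frag = sub.shape[0]
    if n_frag == 0:
        raise ValueError("no fragment traces")
    if n_frag == 1:
        return 0, np.ones(1), True
    r = correlation_matrix(sub)
    sums = r.sum(axis=1) - np.diag(r)
    # lowest (series, index, charge) wins on ties; a small tolerance keeps
    # the tie-break stable under floating-point jitter of exact ties
    top = sums.max()
    best = int(np.flatnonzero(sums >= top - 1e-9 * max(1.0, abs(top)))[0])
    return best, r[best], False


def kgg_evidence_scores(
    cs: ChromatogramSet,
    window: tuple[int, int],
    best_idx: int,
    r_to_best: np.ndarray,
    corr_count_threshold: float = 0.75,
) -> dict[str, float]:
    """Correlation-sum components partitioned by site content.

    The best fragment is excluded from every sum; an empty class
    contributes 0.
    """
    comps = {k: 0.0 for k in SCORE_COMPONENTS}
    for i, ann in enumerate(cs.fragments):
        if i == best_idx:
            continue
        r = float(r_to_best[i])
        if ann.contains_mod_site and not ann.contains_other_candidate_site:
            comps["S_site_determining"] += r
        elif ann.contains_mod_site and ann.contains_other_candidate_site:
            comps["S_site_containing"] += r
        elif ann.contains_other_candidate_site:
            comps["S_other_site"] += r
        else:
            comps["S_shared"] += r
        if r > corr_count_threshold:
            comps["n_corr_gt"] += 1
    lo, hi = window
    comps["ms1_corr"] = pearson(
        cs.ms1_trace[lo: hi + 1], cs.fragment_traces[best_idx, lo: hi + 1]
    )
    return comps


def score_chromatograms(
    precursor_id: str,
    decoy: bool,
    cs: ChromatogramSet,
    config=None,
    rt_window: tuple[float, float] | None = None,
    run: str = "",
) -> list[ScoredCandidate]:
    """All scored candidate peaks for one precursor in one run."""
    from .config import RunConfig

    cfg = config or RunConfig()
    peaks = find_candidate_peaks(
        cs,
        min_points=cfg.min_peak_points,
        smooth_width=cfg.smooth_width,
        max_halfwidth=cfg.max_peak_halfwidth,
        max_candidates=cfg.max_candidates_per_precursor,
        rt_window=rt_window,
    )
    out = []
    for apex, window in peaks:
        b, r_vec, low = best_fragment(cs, window)
        comps = kgg_evidence_scores(
            cs, window, b, r_vec, corr_count_threshold=cfg.corr_count_threshold
        )
        out.append(
            ScoredCandidate(
                precursor_id=precursor_id,
                decoy=decoy,
                apex_index=apex,
                window=window,
                apex_rt=float(cs.rt[apex]),
                best_fragment=cs.fragments[b].fragment_id,
                corr=r_vec,
                components=comps,
                low_evidence=low,
                run=run,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Composite score
# ---------------------------------------------------------------------------

class CompositeScorer:
    """Linear discriminant over the score components.

    Percolator-style single iteration: rank candidates by the
    equal-weight component sum, pick confident targets (q <= fdr_level
    under that ranking) as positives against all decoys, fit an
    L2-regularized logistic regression, and use its decision function as
    the composite score.  Falls back to the equal-weight sum when either
    class is too small or the fit degenerates.
    """

    def __init__(self, fdr_level: float = 0.01, min_class_size: int = 50,
                 seed: int = 0):
        self.fdr_level = fdr_level
        self.min_class_size = min_class_size
        self.seed = seed
        self.fallback = False
        self._model = None
        self._mu = None
        self._sd = None

    @staticmethod
    def equal_weight(x: np.ndarray) -> np.ndarray:
        return x.sum(axis=1)

    def fit(self, candidates: list[ScoredCandidate]) -> "CompositeScorer":
        from .identification import qvalues

        x = np.array([c.component_vector() for c in candidates])
        decoy = np.array([c.decoy for c in candidates])
        init = self.equal_weight(x)
        q = qvalues(init, decoy)
        pos = (~decoy) & (q <= self.fdr_level)
        if pos.sum() < self.min_class_size:
            # fall back to the best-ranked targets to keep training possible
            order = np.argsort(-init)
            tgt = order[~decoy[order]][: self.min_class_size]
            pos = np.zeros_like(decoy)
            pos[tgt] = True
        neg = decoy
        if pos.sum() < self.min_class_size or neg.sum() < self.min_class_size:
            self.fallback = True
            return self
        from sklearn.linear_model import LogisticRegression

        xt = np.concatenate([x[pos], x[neg]])
        yt = np.concatenate([np.ones(int(pos.sum())), np.zeros(int(neg.sum()))])
        self._mu = xt.mean(axis=0)
        sd = xt.std(axis=0)
        self._sd = np.where(sd == 0, 1.0, sd)
        model = LogisticRegression(C=1.0, max_iter=1000, random_state=self.seed)
        model.fit((xt - self._mu) / self._sd, yt)
        if not np.all(np.isfinite(model.coef_)):
            self.fallback = True
            return self
        self._model = model
        return self

    def score(self, candidates: list[ScoredCandidate]) -> np.ndarray:
        x = np.array([c.component_vector() for c in candidates])
        if x.size == 0:
            return np.zeros(0)
        if self._model is None or self.fallback:
            return self.equal_weight(x)
        return self._model.decision_function((x - self._mu) / self._sd)
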