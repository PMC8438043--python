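"""K-GG site mapping, protein inference, moderated differential
statistics and ubiquitinome/proteome integration.

The end point of the pipeline: map di-glycine–remnant peptides onto
protein lysine coordinates, infer parsimonious protein groups from
peptide evidence (greedy set cover over indistinguishable groups),
test drug-vs-control contrasts per time point with an empirical-Bayes
moderated t-test, and combine early ubiquitination with later protein
loss to call deubiquitinase substrates as degradative, non-degradative
or unregulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "map_kgg_sites",
    "infer_proteins",
    "fit_f_dist",
    "moderated_ttest",
    "classify_substrates",
    "peaking_time",
    "inhibitor_consensus",
    "interactor_annotation",
    "bh_qvalues",
]


# ---------------------------------------------------------------------------
# Site mapping
# ---------------------------------------------------------------------------

def map_kgg_sites(peptides, proteins: dict[str, str]) -> pd.DataFrame:
    """Map K-GG peptides to protein lysine positions.

    ``peptides`` is an iterable of ModifiedPeptide carrying
    ``protein_links`` (accession, 1-based start) and KGG positions.
    Each modified position maps to protein site = start + position − 1;
    the residue must be K in every linked accession.  Records sharing
    the same per-accession site set merge their peptide evidence.
    """
    records: dict[frozenset, dict] = {}
    for pep in peptides:
        if not pep.kgg_positions:
            continue
        for kpos in pep.kgg_positions:
            sites = []
            for acc, start in pep.protein_links:
                site = start + kpos - 1
                seq = proteins.get(acc)
                if seq is None:
                    raise ValueError(f"accession {acc!r} not in the sequence database")
                if site > len(seq):
                    raise ValueError(
                        f"{pep.peptide_id}: site {site} beyond {acc} "
                        f"(length {len(seq)})"
                    )
                if seq[site - 1] != "K":
                    raise ValueError(
                        f"{pep.peptide_id}: position {site} in {acc} is "
                        f"{seq[site - 1]!r}, expected K"
                    )
                sites.append((acc, site))
            key = frozenset(sites)
            rec = records.setdefault(
                key,
                {
                    "protein_group": ";".join(sorted(a for a, _ in sites)),
                    "site_positions": ";".join(
                        f"{a}:{s}" for a, s in sorted(sites)
                    ),
                    "residue": "K",
                    "supporting_peptides": set(),
                },
            )
            rec["supporting_peptides"].add(pep.peptide_id)
    rows = []
    for rec in records.values():
        rows.append({
            **{k: v for k, v in rec.items() if k != "supporting_peptides"},
            "supporting_peptides": ";".join(sorted(rec["supporting_peptides"])),
            "n_peptides": len(rec["supporting_peptides"]),
        })
    return (
        pd.DataFrame(rows)
        .sort_values(["protein_group", "site_positions"])
        .reset_index(drop=True)
        if rows
        else pd.DataFrame(
            columns=["protein_group", "site_positions", "residue",
                     "supporting_peptides", "n_peptides"]
        )
    )


# ---------------------------------------------------------------------------
# Parsimonious protein inference (ID-Picker logic)
# ---------------------------------------------------------------------------

def _greedy_cover(groups, unexplained):
    """Greedy set cover: most still-unexplained peptides first (ties:
    larger total peptide set, then lexicographically first accession)."""
    chosen = []
    remaining = list(groups)
    while unexplained and remaining:
        remaining.sort(
            key=lambda g: (-len(g[1] & unexplained), -len(g[1]), g[0][0])
        )
        top = remaining.pop(0)
        if not top[1] & unexplained:
            break
        chosen.append(top)
        unexplained = unexplained - top[1]
    return chosen


def _exact_cover(groups, universe):
    """Smallest cover by exhaustive search over subset sizes; ties broken
    by lexicographic combination order over accession-sorted groups."""
    import itertools

    ordered = sorted(groups, key=lambda g: g[0])
    for r in range(1, len(ordered) + 1):
        for combo in itertools.combinations(ordered, r):
            covered = set()
            for _, peps in combo:
                covered |= peps
            if covered == universe:
                return list(combo)
    return list(ordered)


_EXACT_COVER_MAX_GROUPS = 16


def infer_proteins(incidence: dict[str, set[str]]) -> pd.DataFrame:
    """Parsimonious protein grouping from peptide evidence.

    1. proteins with identical peptide sets collapse into one
       indistinguishable group;
    2. the minimal set of groups explaining every peptide is selected —
       exactly (exhaustive minimal cover) when the collapsed instance is
       small, by greedy cover (most unexplained peptides first; ties:
       larger total peptide set, then lexicographically first accession)
       for large instances, where greedy is the standard parsimony
       heuristic;
    3. proteins whose peptide set is a subset of a chosen group's are
       absorbed into it;
    4. peptides are assigned to every chosen group containing them and
       flagged unique/shared.
    """
    if not incidence:
        return pd.DataFrame(columns=["group", "accessions", "peptides",
                                     "absorbed", "n_unique"])
    by_set: dict[frozenset, list[str]] = {}
    for acc, peps in incidence.items():
        by_set.setdefault(frozenset(peps), []).append(acc)
    groups = [
        (tuple(sorted(accs)), set(peps)) for peps, accs in by_set.items() if peps
    ]
    universe = set().union(*(peps for _, peps in groups)) if groups else set()
    if len(groups) <= _EXACT_COVER_MAX_GROUPS:
        chosen = _exact_cover(groups, universe)
    else:
        chosen = _greedy_cover(groups, universe)

    chosen_sets = [set(peps) for _, peps in chosen]
    absorbed: list[list[str]] = [[] for _ in chosen]
    for accs, peps in groups:
        if (accs, peps) in chosen:
            continue
        for i, cset in enumerate(chosen_sets):
            if peps <= cset:
                absorbed[i].extend(accs)
                break

    pep_owner_count: dict[str, int] = {}
    for cset in chosen_sets:
        for p in cset:
            pep_owner_count[p] = pep_owner_count.get(p, 0) + 1
    rows = []
    for (accs, peps), absorbed_accs in zip(chosen, absorbed):
        unique = {p for p in peps if pep_owner_count[p] == 1}
        rows.append({
            "group": ";".join(accs),
            "accessions": accs,
            "peptides": tuple(sorted(peps)),
            "absorbed": tuple(sorted(absorbed_accs)),
            "n_unique": len(unique),
        })
    rows.sort(key=lambda r: r["group"])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Moderated t-test (empirical-Bayes variance shrinkage)
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration on 1/y (monotone)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of a scaled-F prior to residual variances.

    Matches the mean and variance of log s² to the moments implied by
    s² ~ s0² F(df, d0) via digamma/trigamma identities; returns
    (d0, s0²) with d0 = inf when the observed spread of log s² does not
    exceed its sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return 0.0, float(np.nanmedian(s2[np.isfinite(s2)]) if np.isfinite(s2).any() else 1.0)
    z = np.log(s2[ok])
    dfo = df[ok]
    e = z - special.digamma(dfo / 2.0) + np.log(dfo / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, dfo / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s20 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s20 = float(np.exp(emean))
    return float(d0), s20


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def moderated_ttest(
    qt,
    condition_col: str = "condition",
    time_col: str = "time_min",
    treatment: str = "drug",
    control: str = "DMSO",
    presence_fraction: float = 0.5,
    prior: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-time-point moderated two-sample t-tests on log2 intensities.

    Each time point is one unpaired two-arm contrast (treatment vs its
    time-matched control).  Features must be present in strictly more
    than ``presence_fraction`` of the contrast's samples and have at
    least two present replicates per arm.  Residual variances are shrunk
    toward an empirical-Bayes prior (d0, s0²) fitted across all features
    of the contrast; ``prior`` overrides the fit (d0 = 0 gives the
    ordinary t-test, d0 = inf fully shrinks to s0²).  BH q-values are
    computed within each contrast.
    """
    meta = qt.sample_meta.loc[qt.data.columns]
    results = []
    for t in sorted(meta[time_col].unique()):
        trt_cols = meta.index[(meta[condition_col] == treatment) & (meta[time_col] == t)]
        ctl_cols = meta.index[(meta[condition_col] == control) & (meta[time_col] == t)]
        if len(trt_cols) < 2 or len(ctl_cols) < 2:
            raise ValueError(
                f"contrast at {time_col}={t}: need >= 2 replicates per arm"
            )
        x1 = np.log2(qt.data[list(trt_cols)].to_numpy(dtype=float))
        x0 = np.log2(qt.data[list(ctl_cols)].to_numpy(dtype=float))
        n1 = np.sum(~np.isnan(x1), axis=1)
        n0 = np.sum(~np.isnan(x0), axis=1)
        n_total = len(trt_cols) + len(ctl_cols)
        keep = ((n1 + n0) > presence_fraction * n_total) & (n1 >= 2) & (n0 >= 2)

        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            m1 = np.nanmean(x1, axis=1)
            m0 = np.nanmean(x0, axis=1)
            ss1 = np.nansum((x1 - m1[:, None]) ** 2, axis=1)
            ss0 = np.nansum((x0 - m0[:, None]) ** 2, axis=1)
        df_resid = n1 + n0 - 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            s2 = (ss1 + ss0) / df_resid
        log2fc = m1 - m0

        if prior is None:
            d0, s20 = fit_f_dist(s2[keep], df_resid[keep])
        else:
            d0, s20 = prior
        with np.errstate(invalid="ignore", divide="ignore"):
            if np.isinf(d0):
                s2_post = np.full_like(s2, s20)
            elif d0 == 0:
                s2_post = s2
            else:
                s2_post = (d0 * s20 + df_resid * s2) / (d0 + df_resid)
            se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
            tstat = log2fc / se
        df_total = df_resid + (0.0 if not np.isfinite(d0) else d0)
        with np.errstate(invalid="ignore"):
            if np.isinf(d0):
                p = 2.0 * stats.norm.sf(np.abs(tstat))
            else:
                p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
        p = np.where(keep, p, np.nan)
        q = bh_qvalues(np.where(keep, p, np.nan))
        res = pd.DataFrame({
            "feature": qt.data.index,
            "time_min": t,
            "log2fc": np.where(keep, log2fc, np.nan),
            "t": np.where(keep, tstat, np.nan),
            "p": p,
            "q": q,
            "n_treatment": n1,
            "n_control": n0,
            "d0": d0,
            "s2_prior": s20,
            "tested": keep,
        })
        results.append(res)
    return pd.concat(results, ignore_index=True)


# ---------------------------------------------------------------------------
# Substrate calling and time-course integration
# ---------------------------------------------------------------------------

def _disaggregate(group: str) -> list[str]:
    return [a for a in str(group).split(";") if a]


def classify_substrates(
    ubi_diff: pd.DataFrame,
    prot_diff: pd.DataFrame,
    ubi_protein: pd.Series,
    prot_group: pd.Series | None = None,
    early_time=None,
    fc_thresh: float = 1.0,
    down_thresh: float = 0.2,
    q_thresh: float = 0.05,
    endpoint_only: bool = False,
) -> pd.DataFrame:
    """Integrate ubiquitinome and proteome time courses per protein group.

    Site condition: some K-GG peptide of the group is significant
    (q < ``q_thresh``) with log2fc > ``fc_thresh`` at ``early_time``
    (default: earliest time point).  Degradation condition: the protein
    is significant with relative level < 1 − ``down_thresh`` at ≥ 1 time
    point (or the last one only with ``endpoint_only``).  Verdicts:
    degradative (both hold), non-degradative (site only),
    degradation-unknown (site holds, protein never detected),
    unregulated (no site condition).
    """
    times = sorted(ubi_diff["time_min"].unique())
    if early_time is None:
        early_time = times[0]
    last_time = max(times)
    down_log2 = np.log2(1.0 - down_thresh)

    # proteome hits, disaggregated to single accessions
    if prot_group is None:
        prot_group = pd.Series(
            {f: f for f in prot_diff["feature"].unique()}, name="group"
        )
    acc_down: dict[str, list] = {}
    acc_detected: set[str] = set()
    for _, row in prot_diff.iterrows():
        accs = _disaggregate(prot_group.get(row["feature"], row["feature"]))
        tested = bool(row.get("tested", np.isfinite(row["q"])))
        for acc in accs:
            if tested:
                acc_detected.add(acc)
            if (
                tested
                and row["q"] < q_thresh
                and row["log2fc"] < down_log2
                and (not endpoint_only or row["time_min"] == last_time)
            ):
                acc_down.setdefault(acc, []).append(
                    (row["time_min"], row["log2fc"])
                )

    early = ubi_diff[ubi_diff["time_min"] == early_time]
    sig_early = early[(early["q"] < q_thresh) & (early["log2fc"] > fc_thresh)]

    rows = []
    for group in sorted(set(ubi_protein.loc[ubi_diff["feature"].unique()].dropna())):
        members = ubi_protein.index[ubi_protein == group]
        grp_early = sig_early[sig_early["feature"].isin(members)]
        site_ok = not grp_early.empty
        accs = _disaggregate(group)
        detected = any(a in acc_detected for a in accs)
        downs = [d for a in accs for d in acc_down.get(a, [])]
        if not site_ok:
            verdict = "unregulated"
        elif downs:
            verdict = "degradative"
        elif detected:
            verdict = "non-degradative"
        else:
            verdict = "degradation-unknown"
        grp_all = ubi_diff[ubi_diff["feature"].isin(members)]
        sig_any = grp_all[(grp_all["q"] < q_thresh) & (grp_all["log2fc"] > fc_thresh)]
        rows.append({
            "protein_group": group,
            "verdict": verdict,
            "earliest_up_time": sig_any["time_min"].min() if not sig_any.empty else np.nan,
            "max_site_log2fc": grp_all["log2fc"].max() if not grp_all.empty else np.nan,
            "min_protein_relative_level": (
                2.0 ** min(d[1] for d in downs) if downs else np.nan
            ),
            "n_sites_up_early": len(grp_early),
            "protein_detected": detected,
        })
    return pd.DataFrame(rows)


def peaking_time(
    profiles: pd.DataFrame, membership: dict[str, list[str]]
) -> pd.Series:
    """Per protein: time point where the mean log2fc profile of its
    significantly upregulated features peaks (ties -> earliest time).

    ``profiles``: feature × time-point log2 fold changes, columns sorted
    in time order.
    """
    times = list(profiles.columns)
    out = {}
    for protein, feats in membership.items():
        feats = [f for f in feats if f in profiles.index]
        if not feats:
            continue
        mean_prof = profiles.loc[feats].mean(axis=0)
        out[protein] = times[int(np.argmax(mean_prof.to_numpy()))]
    return pd.Series(out, name="peaking_time")


def inhibitor_consensus(
    per_compound: dict[str, pd.DataFrame],
    feature_protein: pd.Series,
    k: int = 3,
    fc_thresh: float = 1.0,
    q_thresh: float = 0.05,
    reference: set[str] | None = None,
) -> tuple[set[str], float]:
    """Proteins with >= 1 significant, > fc_thresh site in >= k of the
    tested compounds; optionally the overlap fraction against a
    reference set (|consensus ∩ reference| / |reference|)."""
    n = len(per_compound)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of compounds ({n})")
    counts: dict[str, int] = {}
    for diff in per_compound.values():
        hits = diff[(diff["q"] < q_thresh) & (diff["log2fc"] > fc_thresh)]
        prots = set(feature_protein.reindex(hits["feature"]).dropna())
        for prot in prots:
            counts[prot] = counts.get(prot, 0) + 1
    consensus = {p for p, c in counts.items() if c >= k}
    overlap = float("nan")
    if reference is not None:
        overlap = (len(consensus & reference) / len(reference)) if reference else float("nan")
    return consensus, overlap


def interactor_annotation(
    interactions: pd.DataFrame,
    substrates: pd.DataFrame,
    peaking: pd.Series | None = None,
    min_evidence: int = 4,
) -> pd.DataFrame:
    """Filter an interaction table to partners with >= ``min_evidence``
    evidences and join substrate verdicts and signal peaking times.
    Partners without significant sites stay in the table with empty
    annotation."""
    kept = interactions[interactions["evidence"] >= min_evidence].copy()
    sub = substrates.set_index("protein_group")
    kept["verdict"] = kept["partner"].map(sub["verdict"]) if not sub.empty else np.nan
    kept["n_sites_up_early"] = (
        kept["partner"].map(sub["n_sites_up_early"]) if not sub.empty else np.nan
    )
    if peaking is not None:
        kept["peaking_time"] = kept["partner"].map(peaking)
    else:
        kept["peaking_time"] = np.nan
    return kept.reset_index(drop=True)
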