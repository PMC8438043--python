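"""Site mapping, protein inference, moderated statistics, substrate calls."""

import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest

from ubidia.masses_digestion import MOD_DELTAS, ModifiedPeptide
from ubidia.quantification import QuantTable
from ubidia.site_analysis import (
    bh_qvalues,
    classify_substrates,
    fit_f_dist,
    infer_proteins,
    inhibitor_consensus,
    interactor_annotation,
    map_kgg_sites,
    moderated_ttest,
    peaking_time,
)


def _kgg(seq, pos, links):
    return ModifiedPeptide(seq, protein_links=tuple(links),
                           modifications=((pos, "KGG", MOD_DELTAS["KGG"]),))


class TestSiteMapping:
    def test_index_arithmetic(self):
        pep = _kgg("AAKAR", 3, [("P1", 5)])
        out = map_kgg_sites([pep], {"P1": "MAGAAAKARDD"})
        assert out.loc[0, "site_positions"] == "P1:7"

    def test_shared_peptide_produces_one_group_record(self):
        pep = _kgg("AAKAR", 3, [("P2", 5), ("P1", 5)])
        seq = "MAGAAAKARDD"
        out = map_kgg_sites([pep], {"P1": seq, "P2": seq})
        assert len(out) == 1
        assert out.loc[0, "protein_group"] == "P1;P2"
        assert out.loc[0, "site_positions"] == "P1:7;P2:7"

    def test_distinct_peptides_merge_on_same_site(self):
        # different missed-cleavage forms covering the same lysine
        p1 = _kgg("AAKAR", 3, [("P1", 5)])
        p2 = _kgg("GAAKAR", 4, [("P1", 4)])
        out = map_kgg_sites([p1, p2], {"P1": "MAGAAAKARDD"})
        assert len(out) == 1
        assert out.loc[0, "n_peptides"] == 2

    def test_non_lysine_position_is_an_error(self):
        pep = _kgg("AAKAR", 3, [("P1", 1)])
        with pytest.raises(ValueError, match="expected K"):
            map_kgg_sites([pep], {"P1": "AAGARKKKK"})

    def test_roundtrip_on_random_proteome(self, small_space):
        """digest -> enumerate -> map recovers exactly the planted K
        coordinates for every K-GG form in the search space."""
        proteins, space = small_space
        seqs = {p.accession: p.sequence for p in proteins}
        peptides = {pr.peptide.peptide_id: pr.peptide for pr in space}.values()
        out = map_kgg_sites(peptides, seqs)  # raises internally on any mismatch
        expected = set()
        for pep in peptides:
            for acc, start in pep.protein_links:
                for kpos in pep.kgg_positions:
                    expected.add((acc, start + kpos - 1))
        mapped = set()
        for _, row in out.iterrows():
            for item in row["site_positions"].split(";"):
                acc, pos = item.split(":")
                mapped.add((acc, int(pos)))
        assert mapped == expected
        for acc, pos in mapped:
            assert seqs[acc][pos - 1] == "K"


class TestProteinInference:
    def test_subset_absorbed_by_greedy_winner(self):
        out = infer_proteins({"P1": {"a", "b", "c"}, "P2": {"a"}, "P3": {"d"}})
        groups = set(out["group"])
        assert groups == {"P1", "P3"}
        assert tuple(out.loc[out["group"] == "P1", "absorbed"].iloc[0]) == ("P2",)

    def test_indistinguishable_proteins_share_group(self):
        out = infer_proteins({"P1": {"a", "b"}, "P2": {"a", "b"}})
        assert list(out["group"]) == ["P1;P2"]

    def test_disjoint_sets_one_group_each(self):
        out = infer_proteins({"P1": {"a"}, "P2": {"b"}, "P3": {"c"}})
        assert len(out) == 3

    def test_shared_peptides_flagged_via_unique_counts(self):
        out = infer_proteins({"P1": {"a", "s"}, "P2": {"b", "s"}})
        assert set(out["group"]) == {"P1", "P2"}
        assert (out["n_unique"] == 1).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_greedy_matches_exhaustive_minimal_cover(self, seed):
        """On random instances with <= 12 proteins the greedy cover uses
        exactly as many groups as the brute-force minimal cover."""
        rng = np.random.default_rng(seed)
        n_prot = int(rng.integers(3, 13))
        n_pep = int(rng.integers(4, 15))
        incidence = {}
        for i in range(n_prot):
            k = int(rng.integers(1, max(2, n_pep // 2)))
            incidence[f"P{i:02d}"] = set(
                f"pep{j}" for j in rng.choice(n_pep, size=k, replace=False)
            )
        out = infer_proteins(incidence)
        # brute force over indistinguishable groups
        by_set = {}
        for acc, peps in incidence.items():
            by_set.setdefault(frozenset(peps), []).append(acc)
        sets = list(by_set)
        universe = frozenset().union(*sets)
        best = None
        for r in range(1, len(sets) + 1):
            for combo in itertools.combinations(sets, r):
                if frozenset().union(*combo) == universe:
                    best = r
                    break
            if best is not None:
                break
        assert len(out) == best


def _two_group_qt(x_ctl, x_trt, time=15):
    n0, n1 = x_ctl.shape[1], x_trt.shape[1]
    cols = [f"DMSO_t{time}_r{i}" for i in range(n0)] + [
        f"drug_t{time}_r{i}" for i in range(n1)
    ]
    data = pd.DataFrame(np.hstack([x_ctl, x_trt]), columns=cols)
    meta = pd.DataFrame({
        "condition": ["DMSO"] * n0 + ["drug"] * n1,
        "time_min": time,
        "replicate": list(range(n0)) + list(range(n1)),
    }, index=cols)
    return QuantTable(level="peptide", data=data, sample_meta=meta)


class TestModeratedTTest:
    def test_d0_zero_equals_ordinary_t(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        x0 = rng.lognormal(10, 0.3, size=(200, 4))
        x1 = rng.lognormal(10, 0.3, size=(200, 4))
        qt = _two_group_qt(x0, x1)
        out = moderated_ttest(qt, prior=(0.0, 1.0))
        t_ref, p_ref = stats.ttest_ind(np.log2(x1), np.log2(x0), axis=1)
        assert np.allclose(out["t"], t_ref, atol=1e-10)
        assert np.allclose(out["p"], p_ref, atol=1e-10)

    def test_d0_infinite_uses_prior_variance_only(self):
        rng = np.random.default_rng(1)
        x0 = rng.lognormal(10, 0.3, size=(50, 4))
        x1 = rng.lognormal(10, 0.3, size=(50, 4))
        qt = _two_group_qt(x0, x1)
        s20 = 0.17
        out = moderated_ttest(qt, prior=(np.inf, s20))
        fc = np.log2(x1).mean(axis=1) - np.log2(x0).mean(axis=1)
        expected = fc / np.sqrt(s20 * (0.25 + 0.25))
        assert np.allclose(out["t"], expected, atol=1e-10)

    def test_matches_limma_oracle(self, tmp_path):
        """Moderated t, p and the fitted prior agree with the reference
        empirical-Bayes implementation (limma via Rscript)."""
        rng = np.random.default_rng(7)
        sd = rng.uniform(0.1, 0.6, size=200)
        x0 = np.exp(rng.normal(8, sd[:, None], size=(200, 4)) * np.log(2))
        x1 = np.exp(rng.normal(8.2, sd[:, None], size=(200, 4)) * np.log(2))
        qt = _two_group_qt(x0, x1)
        out = moderated_ttest(qt)

        mat = np.log2(np.hstack([x0, x1]))
        mat_path = tmp_path / "mat.tsv"
        np.savetxt(mat_path, mat, delimiter="\t")
        r_out = tmp_path / "limma.tsv"
        script = tmp_path / "oracle.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            "args <- commandArgs(TRUE)\n"
            "x <- as.matrix(read.table(args[1], sep='\\t'))\n"
            "grp <- factor(rep(c('ctl','trt'), each=4), levels=c('ctl','trt'))\n"
            "fit <- eBayes(lmFit(x, model.matrix(~grp)))\n"
            "out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],\n"
            "                  d0=fit$df.prior, s20=fit$s2.prior)\n"
            "write.table(out, args[2], sep='\\t', quote=FALSE, row.names=FALSE)\n"
        )
        subprocess.run(["Rscript", str(script), str(mat_path), str(r_out)],
                       check=True, capture_output=True)
        ref = pd.read_csv(r_out, sep="\t")
        assert out["d0"].iloc[0] == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert out["s2_prior"].iloc[0] == pytest.approx(ref["s20"].iloc[0], rel=1e-6)
        assert np.allclose(out["t"], ref["t"], atol=1e-8)
        assert np.allclose(out["p"], ref["p"], atol=1e-8)

    def test_presence_filter_is_strict(self):
        rng = np.random.default_rng(2)
        x0 = rng.lognormal(10, 0.2, size=(10, 4))
        x1 = rng.lognormal(10, 0.2, size=(10, 4))
        x0[0, :2] = np.nan  # feature 0: 6/8 present -> tested
        x0[1, :] = np.nan   # feature 1: 4/8 present -> not > 50%
        qt = _two_group_qt(x0, x1)
        out = moderated_ttest(qt)
        assert bool(out.loc[0, "tested"])
        assert not bool(out.loc[1, "tested"])

    def test_too_few_replicates_refused(self):
        rng = np.random.default_rng(3)
        qt = _two_group_qt(rng.lognormal(10, 0.2, (5, 1)),
                           rng.lognormal(10, 0.2, (5, 4)))
        with pytest.raises(ValueError, match="replicates"):
            moderated_ttest(qt)


class TestBH:
    def test_matches_textbook_oracle(self):
        def bh_oracle(p):
            m = len(p)
            order = np.argsort(p)
            q = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * m / rank)
                q[i] = prev
            return q

        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 500) ** 2
        assert np.allclose(bh_qvalues(p), bh_oracle(p), atol=1e-12)


def _diff(rows):
    return pd.DataFrame(rows, columns=["feature", "time_min", "log2fc", "q",
                                       "tested"])


class TestSubstrateCalls:
    def _ubi(self):
        return _diff([
            ("pepA", 15, 1.5, 0.01, True), ("pepA", 360, 0.2, 0.5, True),
            ("pepB", 15, 2.0, 0.001, True), ("pepB", 360, 1.0, 0.2, True),
            ("pepC", 15, 0.1, 0.9, True), ("pepC", 360, 0.0, 0.9, True),
            ("pepD", 15, 1.8, 0.02, True), ("pepD", 360, 0.5, 0.4, True),
        ])

    def _prot(self):
        return _diff([
            ("PA", 15, 0.0, 0.9, True), ("PA", 360, np.log2(0.65), 0.02, True),
            ("PB", 15, 0.0, 0.9, True), ("PB", 360, -0.1, 0.5, True),
            ("PC", 15, 0.0, 0.9, True), ("PC", 360, -0.8, 0.001, True),
        ])

    def _mapping(self):
        return pd.Series({"pepA": "PA", "pepB": "PB", "pepC": "PC", "pepD": "PD"})

    def test_verdicts(self):
        calls = classify_substrates(self._ubi(), self._prot(), self._mapping())
        v = calls.set_index("protein_group")["verdict"]
        assert v["PA"] == "degradative"        # site up early, protein down later
        assert v["PB"] == "non-degradative"    # site up, protein stable
        assert v["PC"] == "unregulated"        # no significant site
        assert v["PD"] == "degradation-unknown"  # protein never detected

    def test_unregulated_regardless_of_protein(self):
        # PC's protein drops strongly, but without the site condition the
        # verdict must stay unregulated (gate ordering)
        calls = classify_substrates(self._ubi(), self._prot(), self._mapping())
        assert calls.set_index("protein_group").loc["PC", "verdict"] == "unregulated"

    def test_threshold_semantics(self):
        # down by exactly 20% (level 0.8) must NOT satisfy "more than 20%"
        prot = _diff([
            ("PA", 360, np.log2(0.80), 0.001, True),
        ])
        ubi = _diff([("pepA", 15, 1.5, 0.01, True), ("pepA", 360, 0.1, 0.9, True)])
        calls = classify_substrates(ubi, prot, pd.Series({"pepA": "PA"}))
        assert calls.loc[0, "verdict"] == "non-degradative"

    def test_endpoint_only_flag(self):
        prot = _diff([
            ("PA", 60, np.log2(0.6), 0.001, True),
            ("PA", 360, 0.0, 0.9, True),
        ])
        ubi = _diff([("pepA", 15, 1.5, 0.01, True),
                     ("pepA", 60, 1.0, 0.2, True),
                     ("pepA", 360, 0.1, 0.9, True)])
        mapping = pd.Series({"pepA": "PA"})
        any_time = classify_substrates(ubi, prot, mapping)
        endpoint = classify_substrates(ubi, prot, mapping, endpoint_only=True)
        assert any_time.loc[0, "verdict"] == "degradative"
        assert endpoint.loc[0, "verdict"] == "non-degradative"

    def test_group_disaggregation_matches_proteome(self):
        ubi = _diff([("pepA", 15, 1.5, 0.01, True)])
        prot = _diff([("Q1;PA", 360, np.log2(0.5), 0.001, True)])
        mapping = pd.Series({"pepA": "PA;PX"})
        calls = classify_substrates(
            ubi, prot, mapping,
            prot_group=pd.Series({"Q1;PA": "Q1;PA"}),
        )
        assert calls.loc[0, "verdict"] == "degradative"


class TestPeakingTime:
    def test_argmax_of_mean_profile(self):
        profiles = pd.DataFrame(
            {15: [0.5, 1.0], 60: [2.0, 1.5], 360: [1.0, 2.6]},
            index=["f1", "f2"],
        )
        out = peaking_time(profiles, {"P1": ["f1"], "P2": ["f1", "f2"]})
        assert out["P1"] == 60
        # mean profile: [0.75, 1.75, 1.8] -> 360
        assert out["P2"] == 360

    def test_tie_prefers_earliest(self):
        profiles = pd.DataFrame({15: [1.0], 60: [1.0]}, index=["f1"])
        assert peaking_time(profiles, {"P": ["f1"]})["P"] == 15


class TestInhibitorConsensus:
    def _compounds(self):
        def d(fc_by_feature):
            return _diff([(f, 15, fc, 0.01, True) for f, fc in fc_by_feature.items()])

        return {
            "FT671": d({"f1": 2.0, "f2": 1.5}),
            "FT827": d({"f1": 1.8}),
            "GNE-6776": d({"f1": 1.2, "f2": 0.5}),
            "GNE-6640": d({"f2": 0.2}),
        }

    def test_three_of_four_rule(self):
        mapping = pd.Series({"f1": "P1", "f2": "P2"})
        consensus, _ = inhibitor_consensus(self._compounds(), mapping, k=3)
        assert consensus == {"P1"}   # P2 significant+>2-fold in only 1 compound

    def test_overlap_against_reference(self):
        mapping = pd.Series({"f1": "P1", "f2": "P2"})
        consensus, overlap = inhibitor_consensus(
            self._compounds(), mapping, k=3, reference={"P1"}
        )
        assert overlap == 1.0

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            inhibitor_consensus(self._compounds(), pd.Series(dtype=object), k=5)


class TestInteractorAnnotation:
    def test_evidence_filter_and_join(self):
        interactions = pd.DataFrame({
            "partner": ["PA", "PB", "PC"],
            "evidence": [5, 3, 4],
        })
        substrates = pd.DataFrame({
            "protein_group": ["PA"],
            "verdict": ["degradative"],
            "n_sites_up_early": [2],
        })
        peaks = pd.Series({"PA": 15})
        out = interactor_annotation(interactions, substrates, peaks)
        assert list(out["partner"]) == ["PA", "PC"]   # PB dropped (3 < 4)
        assert out.loc[out["partner"] == "PA", "verdict"].iloc[0] == "degradative"
        # PC retained with empty annotation
        assert pd.isna(out.loc[out["partner"] == "PC", "verdict"]).all()
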