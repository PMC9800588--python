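"""Signature construction, Spearman matching, pruning, and PTSP aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from estrocycle import synthdata
from estrocycle.errors import InputError
from estrocycle.tascomp import (
    TAS,
    build_tas,
    is_hit,
    label_hierarchy_summary,
    match_library,
    prune_redundant,
    ptsp_aggregate,
    ptsp_calls,
    scc_pvalue,
    spearman,
)

from conftest import make_profile
from oracles import spearman_oracle


def tas_from(values, tissue="heart", tas_id="t", outcome="none", label_path=(), genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes if genes is not None else np.array([f"g{i}" for i in range(len(values))])
    return TAS(id=tas_id, tissue=tissue, genes=genes, values=values, outcome=outcome, label_path=label_path)


class TestBuildTAS:
    def test_identical_profiles_zero_signature(self):
        counts = [[10, 20], [5, 5], [100, 80]]
        a = make_profile("heart", "estrus", counts)
        b = make_profile("heart", "diestrus", counts)
        tas = build_tas(a, b)
        assert np.allclose(tas.values, 0.0)

    def test_length_is_retained_shared_genes(self):
        a = make_profile("heart", "estrus", [[0], [10], [20]])
        b = make_profile("heart", "diestrus", [[0], [5], [10]])
        tas = build_tas(a, b)
        assert len(tas) == 2  # the both-zero gene is dropped

    def test_no_shared_genes_rejected(self):
        a = make_profile("heart", "estrus", [[1]], genes=["gA"])
        b = make_profile("heart", "diestrus", [[1]], genes=["gB"])
        with pytest.raises(InputError):
            build_tas(a, b)


class TestSpearman:
    def test_self_correlation(self, rng):
        x = rng.normal(size=30)
        assert spearman(x, x) == pytest.approx(1.0)

    def test_decreasing_transform(self, rng):
        x = rng.normal(size=30)
        assert spearman(x, np.exp(-x)) == pytest.approx(-1.0)

    def test_tied_example_matches_oracle(self):
        assert spearman([1, 2, 3, 3], [2, 1, 4, 4]) == pytest.approx(7 / 9, abs=1e-12)

    def test_zero_rank_variance_undefined(self):
        assert np.isnan(spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_short_input_rejected(self):
        with pytest.raises(InputError):
            spearman([1, 2], [3, 4])

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(st.integers(min_value=-50, max_value=50), min_size=4, max_size=25),
        st.sampled_from(["cube", "exp", "affine"]),
    )
    def test_invariant_under_strictly_monotone_transforms(self, values, transform):
        rng = np.random.default_rng(abs(hash(tuple(values))) % 2**31)
        x = np.asarray(values, dtype=float)
        y = rng.normal(size=len(x))
        fx = {"cube": x**3, "exp": np.exp(x / 50.0), "affine": 3.0 * x + 7.0}[transform]
        base = spearman(x, y)
        if np.isnan(base):
            assert np.isnan(spearman(fx, y))
        else:
            assert spearman(fx, y) == pytest.approx(base, abs=1e-12)


class TestSCCPValue:
    def test_zero_correlation(self):
        assert scc_pvalue(0.0, 50) == 1.0

    def test_perfect_correlation(self):
        assert scc_pvalue(1.0, 50) == 0.0

    def test_t_distribution_oracle(self):
        # frozen from the t statistic evaluated independently
        assert scc_pvalue(0.5, 100) == pytest.approx(1.1804920270376289e-07, rel=1e-9)

    def test_nan_propagates(self):
        assert np.isnan(scc_pvalue(float("nan"), 10))


class TestPruning:
    def _member(self, values, tas_id, tissue="heart"):
        return tas_from(values, tissue=tissue, tas_id=tas_id)

    def test_exact_duplicate_removed(self, rng):
        v = rng.normal(size=200)
        library = [self._member(v, "A"), self._member(v.copy(), "B")]
        assert [m.id for m in prune_redundant(library, min_overlap=100)] == ["A"]

    def test_uncorrelated_library_unchanged(self, rng):
        library = [self._member(rng.normal(size=200), f"M{i}") for i in range(5)]
        assert len(prune_redundant(library, min_overlap=100)) == 5

    def test_greedy_chain_rule(self, rng):
        """A~B and B~C redundant, A~C not: greedy order keeps A and C."""
        n = 400
        a = rng.normal(size=n)
        noise = rng.normal(size=n)
        b = (a + noise) / np.sqrt(2)  # correlates ~0.7 with both a and noise
        c = 0.95 * noise + 0.312 * rng.normal(size=n)  # SCC(b,c) ~ 0.65, SCC(a,c) ~ 0
        library = [self._member(a, "A"), self._member(b, "B"), self._member(c, "C")]
        sab = spearman(a, b)
        sbc = spearman(b, c)
        sac = spearman(a, c)
        assert sab >= 0.5 and sbc >= 0.5 and sac < 0.5
        assert [m.id for m in prune_redundant(library, min_overlap=100)] == ["A", "C"]

    def test_different_tissues_never_redundant(self, rng):
        v = rng.normal(size=200)
        library = [self._member(v, "A", "heart"), self._member(v.copy(), "B", "aorta")]
        assert len(prune_redundant(library, min_overlap=100)) == 2

    def test_postcondition_all_pairs_below_cut(self, rng):
        shared = rng.normal(size=300)
        library = [
            self._member(w * shared + np.sqrt(1 - w**2) * rng.normal(size=300), f"M{i}")
            for i, w in enumerate(rng.uniform(0, 1, size=12))
        ]
        kept = prune_redundant(library, min_overlap=100)
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert spearman(a.values, b.values) < 0.5


class TestMatching:
    def test_hit_boundary_inclusive(self):
        assert is_hit(0.1) and is_hit(-0.1)
        assert not is_hit(0.05) and not is_hit(-0.099)

    def test_planted_correlation_detected(self, rng):
        query = tas_from(rng.normal(size=2000), tas_id="q")
        config = synthdata.SimConfig(seed=5, tas_rho=0.3, tas_library_size=20, tas_correlated_fraction=0.5)
        members, truth = synthdata.simulate_tas_library(config, query)
        hits = match_library(query, members)
        sig = set(hits.loc[hits["significant"], "library_id"])
        assert set(truth.correlated_tas) <= sig

    def test_min_overlap_skips_pairs(self, rng):
        query = tas_from(rng.normal(size=150), tas_id="q")
        small = tas_from(rng.normal(size=50), genes=np.array([f"g{i}" for i in range(50)]), tas_id="small")
        hits = match_library(query, [small], min_overlap=100)
        assert hits.empty

    def test_other_tissue_members_ignored(self, rng):
        query = tas_from(rng.normal(size=150), tissue="heart", tas_id="q")
        other = tas_from(rng.normal(size=150), tissue="aorta", tas_id="o")
        assert match_library(query, [other]).empty


class TestPTSP:
    def _hits(self, sccs, outcomes):
        return pd.DataFrame(
            {
                "scc": sccs,
                "outcome": outcomes,
                "significant": [True] * len(sccs),
                "label_path": ["x"] * len(sccs),
            }
        )

    def test_eight_beneficial_positive_hits(self):
        call = ptsp_aggregate(self._hits([0.3] * 8, ["beneficial"] * 8), "aorta")
        assert call.verdict == "estrus-protective"
        assert call.protective_votes == 8 and call.harmful_votes == 0
        assert call.sign_test_p == pytest.approx(2 * 0.5**8, rel=1e-12)

    def test_tie_is_indeterminate(self):
        call = ptsp_aggregate(
            self._hits([0.2, 0.2, 0.2, -0.2, -0.2, -0.2], ["beneficial"] * 3 + ["beneficial"] * 3),
            "heart",
        )
        assert call.verdict == "indeterminate"

    def test_no_labelled_hits_indeterminate(self):
        call = ptsp_aggregate(self._hits([0.5], ["none"]), "liver")
        assert call.verdict == "indeterminate" and np.isnan(call.sign_test_p)

    def test_deleterious_negative_is_protective(self):
        call = ptsp_aggregate(self._hits([-0.3] * 5, ["deleterious"] * 5), "aorta")
        assert call.verdict == "estrus-protective"

    def test_antisymmetry_under_sign_flip(self, rng):
        sccs = rng.uniform(-0.5, 0.5, size=11)
        outcomes = list(rng.choice(["beneficial", "deleterious"], size=11))
        call = ptsp_aggregate(self._hits(sccs, outcomes), "t")
        flipped = ptsp_aggregate(self._hits(-sccs, outcomes), "t")
        mirror = {
            "estrus-protective": "diestrus-protective",
            "diestrus-protective": "estrus-protective",
            "indeterminate": "indeterminate",
        }
        assert flipped.verdict == mirror[call.verdict]
        assert flipped.sign_test_p == pytest.approx(call.sign_test_p, rel=1e-12)

    def test_reproductive_tissues_excluded_by_default(self):
        hits = {t: self._hits([0.3] * 4, ["beneficial"] * 4) for t in ("ovary", "uterus", "heart")}
        calls = ptsp_calls(hits)
        assert set(calls) == {"heart"}
        assert set(ptsp_calls(hits, exclude_tissues=())) == {"ovary", "uterus", "heart"}


class TestLabelSummary:
    def _library(self):
        return [
            tas_from(np.arange(5.0), tas_id="L1", outcome="deleterious",
                     label_path=("deleterious", "disease", "cancer")),
            tas_from(np.arange(5.0), tas_id="L2", outcome="beneficial",
                     label_path=("beneficial", "chemical treatment")),
        ]

    def test_single_hit_three_prefixes(self):
        hits = pd.DataFrame(
            {
                "scc": [0.4],
                "significant": [True],
                "outcome": ["deleterious"],
                "label_path": ["deleterious/disease/cancer"],
            }
        )
        summary = label_hierarchy_summary(hits, self._library())
        assert summary["positive"] == {
            "deleterious": 1,
            "deleterious/disease": 1,
            "deleterious/disease/cancer": 1,
        }
        assert summary["negative"] == {}

    def test_empty_hits_background_only(self):
        hits = pd.DataFrame(columns=["scc", "significant", "outcome", "label_path"])
        summary = label_hierarchy_summary(hits, self._library())
        assert summary["positive"] == {} and summary["negative"] == {}
        assert summary["background"]["deleterious"] == 1

    def test_parent_counts_sum_children(self, rng):
        members, _ = synthdata.simulate_tas_library(
            synthdata.SimConfig(seed=8, tas_library_size=40),
            tas_from(rng.normal(size=300), tas_id="q"),
        )
        summary = label_hierarchy_summary(
            pd.DataFrame(columns=["scc", "significant", "outcome", "label_path"]), members
        )
        counts = summary["background"]
        for outcome in ("beneficial", "deleterious"):
            children = sum(v for k, v in counts.items() if k.count("/") == 1 and k.startswith(outcome))
            leaves_at_depth1 = sum(
                1 for m in members if len(m.label_path) == 1 and m.label_path[0] == outcome
            )
            assert counts.get(outcome, 0) == children + leaves_at_depth1
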