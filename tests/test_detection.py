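import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diadetect.detection import (
    RuleSet,
    build_detection_matrix,
    classify_all,
    classify_protein,
    detection_summary,
    preferred_sets,
    sensitivity_scan,
    top_k_specific,
)
from diadetect.diann_io import ReportError

# Printed detection counts and tiers for every Dep-preferred (k_dep, k_nondep)
# and NonDep-preferred (k_nondep, k_dep) protein of the reference study.
DEP_TABLE = [
    ("MMP2", 4, 0, "Strong"), ("CTL2A", 4, 0, "Strong"), ("PGS2", 4, 0, "Strong"),
    ("BIP", 4, 1, "Strong"), ("GFAP", 3, 0, "Strong"), ("LAG3", 3, 0, "Strong"),
    ("NPTX1", 3, 0, "Strong"), ("CHI3L1", 3, 1, "Strong"), ("ACTA", 3, 1, "Strong"),
    ("LAMB2", 3, 1, "Strong"), ("CSPG5", 4, 1, "Strong"), ("NFASC", 4, 1, "Strong"),
    ("RELN", 4, 1, "Strong"), ("C1QA", 2, 0, "Moderate"), ("VCAM1", 2, 0, "Moderate"),
    ("CADH5", 2, 1, "Moderate"), ("CX3CL1", 2, 0, "Moderate"), ("UCHL1", 2, 1, "Moderate"),
]
NONDEP_TABLE = [
    ("TAGL3", 4, 0, "Strong"), ("KV5AB", 4, 1, "Strong"), ("CALB1", 4, 1, "Strong"),
    ("LV1C", 3, 0, "Moderate"), ("SUMO2/3", 3, 1, "Moderate"),
]


def make_summary(counts):
    """Summary frame from {protein: (k_dep, k_nondep)} at n=4/5."""
    return pd.DataFrame(
        {
            "k_dep": {p: k[0] for p, k in counts.items()},
            "n_dep": 4,
            "k_nondep": {p: k[1] for p, k in counts.items()},
            "n_nondep": 5,
        }
    )


class TestBuildDetectionMatrix:
    def test_presence_counts(self, meta45):
        quant = pd.DataFrame(
            {r: [100.0 if r in ("D1", "D2", "D3") else np.nan] for r in meta45["run_id"]},
            index=["P1"],
        )
        det = build_detection_matrix(quant, meta45)
        summary = detection_summary(det, meta45)
        assert summary.loc["P1", "k_dep"] == 3
        assert summary.loc["P1", "k_nondep"] == 0

    def test_full_detection(self, meta45):
        quant = pd.DataFrame({r: [1.0] for r in meta45["run_id"]}, index=["P1"])
        summary = detection_summary(build_detection_matrix(quant, meta45), meta45)
        assert (summary.loc["P1", ["k_dep", "n_dep", "k_nondep", "n_nondep"]]
                == [4, 4, 5, 5]).all()

    def test_empty_group_errors(self, meta45):
        meta = meta45[meta45["group"] == "Dep"]
        quant = pd.DataFrame({r: [1.0] for r in meta["run_id"]}, index=["P1"])
        with pytest.raises(ReportError, match="NonDep"):
            build_detection_matrix(quant, meta)

    def test_counts_match_generator_truth(self, bundle):
        # Bernoulli layer equals detection truth when quantification is lossless:
        # read directly from the truth matrix
        summary = detection_summary(bundle.detection_truth, bundle.metadata)
        dep_runs = bundle.metadata.loc[bundle.metadata["group"] == "Dep", "run_id"]
        expected = bundle.detection_truth[list(dep_runs)].sum(axis=1)
        assert (summary["k_dep"] == expected).all()


class TestClassifyProtein:
    @pytest.mark.parametrize("protein,k_dep,k_nondep,tier", DEP_TABLE)
    def test_dep_preferred_rows(self, protein, k_dep, k_nondep, tier):
        assert classify_protein(k_dep, 4, k_nondep, 5) == ("Dep", tier)

    @pytest.mark.parametrize("protein,k_nondep,k_dep,tier", NONDEP_TABLE)
    def test_nondep_preferred_rows(self, protein, k_nondep, k_dep, tier):
        assert classify_protein(k_dep, 4, k_nondep, 5) == ("NonDep", tier)

    @pytest.mark.parametrize(
        "k_dep,k_nondep,expected",
        [
            (1, 1, ("None", "None")),       # below all thresholds
            (0, 0, ("None", "None")),
            (3, 2, ("Dep", "Weak")),        # >=2 in both groups demotes to Weak
            (2, 2, ("Dep", "Weak")),
            (0, 2, ("NonDep", "Weak")),     # 2/5 = 40% < the 60% moderate cut
            (4, 5, ("None", "None")),       # equal full detection: no preference
        ],
    )
    def test_boundary_patterns(self, k_dep, k_nondep, expected):
        assert classify_protein(k_dep, 4, k_nondep, 5) == expected

    def test_counts_outside_group_size_rejected(self):
        with pytest.raises(ValueError):
            classify_protein(5, 4, 0, 5)

    def test_fractional_thresholds_scale_with_ceiling(self):
        # at n=8/10 the strong Dep cut is ceil(0.75*8)=6
        assert classify_protein(6, 8, 1, 10) == ("Dep", "Strong")
        assert classify_protein(5, 8, 1, 10) == ("Dep", "Moderate")

    def test_evidence_implies_preference(self):
        for k_dep in range(5):
            for k_nondep in range(6):
                group, tier = classify_protein(k_dep, 4, k_nondep, 5)
                assert (tier == "None") == (group == "None")

    def test_classify_all_matches_scalar(self):
        summary = make_summary({"A": (4, 0), "B": (1, 1), "C": (2, 2)})
        out = classify_all(summary)
        assert list(out["evidence"]) == ["Strong", "None", "Weak"]


class TestPreferredSets:
    def test_constructed_partition(self):
        summary = make_summary({
            "d1": (3, 0), "d2": (2, 1),           # Dep-preferred
            "n1": (0, 4),                          # NonDep-preferred
            "s1": (2, 2), "s2": (4, 5), "s3": (0, 2),
        })
        # s3 is NonDep-preferred too (k_nondep>=2, k_dep<=1)
        sets = preferred_sets(summary)
        assert sets["dep_preferred"] == {"d1", "d2"}
        assert sets["nondep_preferred"] == {"n1", "s3"}
        assert sets["shared"] == {"s1", "s2"}

    def test_single_detections_excluded_from_universe(self):
        summary = make_summary({"x": (1, 1)})
        sets = preferred_sets(summary)
        assert all(len(s) == 0 for s in sets.values())

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 4), st.integers(0, 5)), min_size=1, max_size=30))
    def test_partition_property(self, counts):
        summary = make_summary({f"p{i}": c for i, c in enumerate(counts)})
        sets = preferred_sets(summary)
        universe = {
            p for p, (k1, k2) in zip(summary.index, counts) if k1 >= 2 or k2 >= 2
        }
        union = sets["dep_preferred"] | sets["nondep_preferred"] | sets["shared"]
        assert union == universe
        total = sum(len(s) for s in sets.values())
        assert total == len(universe)  # pairwise disjoint


class TestTopK:
    def test_ranked_by_preferred_count(self):
        summary = make_summary({"a": (4, 0), "b": (3, 0), "c": (2, 0)})
        assert top_k_specific(summary, k=2) == ["a", "b"]

    def test_tie_broken_lexicographically(self):
        summary = make_summary({"LAG3": (3, 0), "GFAP": (3, 0)})
        assert top_k_specific(summary, k=2) == ["GFAP", "LAG3"]

    def test_opposite_group_must_be_zero(self):
        summary = make_summary({"a": (4, 1), "b": (2, 0), "n": (0, 5)})
        assert top_k_specific(summary, k=10) == ["n", "b"]


class TestSensitivityScan:
    def test_default_cell_matches_preferred_sets(self):
        summary = make_summary({"a": (4, 0), "b": (2, 1), "c": (0, 3), "d": (2, 2)})
        scan = sensitivity_scan(summary, [(2, 1)])
        sets = preferred_sets(summary)
        assert scan.loc[0, "n_dep_preferred"] == len(sets["dep_preferred"])
        assert scan.loc[0, "n_nondep_preferred"] == len(sets["nondep_preferred"])

    def test_monotone_in_thresholds(self, bundle):
        summary = detection_summary(bundle.detection_truth, bundle.metadata)
        scan = sensitivity_scan(summary, [(2, 1), (3, 1), (4, 1), (2, 0), (3, 0), (4, 0)])
        idx = scan.set_index(["min_preferred_count", "max_other_count"])
        for col in ("n_dep_preferred", "n_nondep_preferred"):
            assert idx.loc[(2, 1), col] >= idx.loc[(3, 1), col] >= idx.loc[(4, 1), col]
            assert idx.loc[(2, 1), col] >= idx.loc[(2, 0), col] >= idx.loc[(4, 0), col]

    def test_matches_per_cell_brute_force(self, bundle):
        summary = detection_summary(bundle.detection_truth, bundle.metadata)
        grid = [(2, 1), (3, 0), (4, 1)]
        scan = sensitivity_scan(summary, grid).set_index(["min_preferred_count", "max_other_count"])
        for min_pref, max_other in grid:
            dep = ((summary["k_dep"] >= min_pref) & (summary["k_nondep"] <= max_other)).sum()
            assert scan.loc[(min_pref, max_other), "n_dep_preferred"] == dep

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_scan(make_summary({"a": (1, 1)}), [])


def test_ruleset_rejects_inverted_thresholds():
    with pytest.raises(ValueError):
        RuleSet(strong_min_frac_dep=0.4, moderate_min_frac_dep=0.5)
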