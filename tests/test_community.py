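"""KO pooling, overlap grouping, scaling, and gene-set selection."""

import numpy as np
import pandas as pd
import pytest

from bacterivory import community as C
from bacterivory.errors import DegenerateInputError, InputError


def table(rows, samples=("s1", "s2", "s3")):
    """rows: list of (transcript_id, ko_ids, tpm-tuple)."""
    recs = []
    for tid, kos, tpm in rows:
        recs.append({"transcript_id": tid, "ko_ids": kos, "taxon": "x",
                     **dict(zip(samples, tpm))})
    return pd.DataFrame(recs)


class TestFilterExpressed:
    @pytest.mark.parametrize("tpm,kept", [
        ((0.0, 1.9, 0.5), False),   # below threshold everywhere
        ((2.0, 0.0, 0.0), True),    # inclusive boundary
        ((0.0, 0.0, 300.0), True),
    ])
    def test_threshold_is_inclusive_per_sample_max(self, tpm, kept):
        t = table([("t1", "K1", tpm)])
        out = C.filter_expressed(t)
        assert (len(out) == 1) is kept

    def test_toy_table_counts(self):
        maxima = [0.1, 1.99, 2.0, 5, 0, 300]
        t = table([(f"t{i}", "K1", (m, 0, 0)) for i, m in enumerate(maxima)])
        assert len(C.filter_expressed(t)) == 3

    def test_idempotent_and_not_renormalized(self):
        t = table([("t1", "K1", (5, 0, 0)), ("t2", "K2", (1, 1, 1))])
        once = C.filter_expressed(t)
        twice = C.filter_expressed(once)
        pd.testing.assert_frame_equal(once, twice)
        assert once[["s1", "s2", "s3"]].to_numpy().sum() == 5  # original scale kept

    def test_negative_tpm_rejected(self):
        with pytest.raises(InputError):
            C.filter_expressed(table([("t1", "K1", (-1, 0, 0))]))


class TestPoolKos:
    def test_additive_and_duplicating(self):
        t = table([("t1", "K1", (10, 0, 0)),
                   ("t2", "K1", (5, 1, 0)),
                   ("t3", "", (7, 7, 7)),
                   ("t4", "K1;K2", (7, 0, 2))])
        ko, members = C.pool_kos(t)
        assert ko.loc["K1", "s1"] == 22            # 10 + 5 + 7
        assert ko.loc["K2", "s1"] == 7             # full TPM to each of its KOs
        assert "t3" not in set().union(*members.values())
        assert members["K1"] == frozenset({"t1", "t2", "t4"})

    def test_unannotated_only_gives_empty_table(self):
        ko, members = C.pool_kos(table([("t1", "", (1, 1, 1))]))
        assert ko.empty and not members


class TestOverlap:
    def test_asymmetric_formula(self):
        members = {"A": frozenset(f"t{i}" for i in range(100)),
                   "B": frozenset(f"t{i}" for i in range(80))}
        m = C.compute_ko_overlap(members)
        assert m.loc["B", "A"] == 100.0
        assert m.loc["A", "B"] == 80.0
        assert m.loc["A", "A"] == 100.0

    def test_disjoint_and_hand_counts(self):
        members = {"A": frozenset(f"a{i}" for i in range(60)) | frozenset(f"ab{i}" for i in range(30)),
                   "B": frozenset(f"ab{i}" for i in range(30)) | frozenset(f"b{i}" for i in range(10)),
                   "C": frozenset(f"c{i}" for i in range(5))}
        # A has 90 transcripts of which 30 shared with B; B∩C empty
        m = C.compute_ko_overlap(members)
        assert m.loc["A", "B"] == pytest.approx(100 * 30 / 90)
        assert m.loc["B", "C"] == 0.0
        assert m.loc["C", "B"] == 0.0

    def test_empty_ko_excluded_with_warning(self):
        members = {"A": frozenset({"t1"}), "B": frozenset()}
        with pytest.warns(UserWarning, match="without transcripts"):
            m = C.compute_ko_overlap(members)
        assert list(m.index) == ["A"]


class TestGrouping:
    @staticmethod
    def overlap_of(members, threshold=50.0):
        return C.group_overlapping_kos(C.compute_ko_overlap(members), threshold)

    def test_chain_is_one_group_by_single_linkage(self):
        # A-B 60%, B-C 60%, A-C 0
        members = {"A": frozenset(list("abcde")),          # 5 transcripts, 3 shared with B
                   "B": frozenset(list("cde") + list("xy")),
                   "C": frozenset(list("xy") + list("pq"))}
        # overlap(A,B)=60, overlap(B,C)=40 but overlap(C,B)=50 -> edge via max
        groups = self.overlap_of(members)
        assert groups == [{"A", "B", "C"}]

    def test_no_edges_gives_singletons(self):
        members = {"A": frozenset({"a"}), "B": frozenset({"b"}), "C": frozenset({"c"})}
        assert self.overlap_of(members) == [{"A"}, {"B"}, {"C"}]

    def test_peptidase_topology_collapses_to_six_groups(self):
        """20 peptidase KOs with a planted overlap topology collapse into 6
        groups; the cysteine-peptidase group holds all 9 cathepsin-type KOs."""
        cysteine = ["catB", "catF", "catH", "catK", "catL", "catO", "catX",
                    "KDEL", "xylem"]
        aspartyl = ["catD", "catE", "phytepsin", "saccharopepsin"]
        serine = ["catA", "scpI", "scpII", "vitellogenic"]
        singles = ["tpp1", "prep", "metallo"]
        members = {}
        for fam, kos in (("cys", cysteine), ("asp", aspartyl), ("ser", serine)):
            shared = frozenset(f"{fam}_sh{i}" for i in range(6))
            for j, ko in enumerate(kos):
                own = frozenset(f"{fam}_{ko}_{i}" for i in range(4))
                members[ko] = shared | own
        for ko in singles:
            members[ko] = frozenset(f"{ko}_{i}" for i in range(8))
        groups = self.overlap_of(members)
        assert len(groups) == 6
        assert set(cysteine) in [g for g in groups]
        assert set(aspartyl) in groups and set(serine) in groups

    def test_group_tpm_counts_each_transcript_once(self):
        t = table([("t1", "K1", (10, 0, 0)),
                   ("t2", "K1;K2", (4, 4, 0)),
                   ("t3", "K2", (1, 1, 1))])
        ko, members = C.pool_kos(t)
        groups = C.group_overlapping_kos(C.compute_ko_overlap(members))
        assert groups == [{"K1", "K2"}]
        pooled = C.pool_groups(t, groups, members)
        # union of transcripts: 10+4+1 in s1; the per-KO table double counts t2
        assert pooled.loc["K1+K2", "s1"] == 15
        assert ko.loc[["K1", "K2"], "s1"].sum() == 19


class TestScaleCategories:
    def test_formula_and_per_incubation_scaling(self):
        ko = pd.DataFrame({"a1": [5.0, 1.0], "a2": [10.0, 2.0], "a3": [20.0, 0.0],
                           "b1": [5.0, 5.0], "b2": [10.0, 10.0]},
                          index=["K1", "K2"])
        cats = pd.Series({"K1": "cat", "K2": "cat"})
        inc = pd.Series({"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B"})
        out = C.scale_categories(ko, cats, inc)
        assert list(out.loc["K1", ["a1", "a2", "a3"]]) == [25, 50, 100]
        assert list(out.loc["K1", ["b1", "b2"]]) == [50, 100]
        assert out.to_numpy().max() == 100.0

    def test_unmapped_dropped_and_zero_category_warned(self):
        ko = pd.DataFrame({"a1": [0.0], "a2": [0.0]}, index=["K1"])
        cats = pd.Series({"K1": "cat"})
        inc = pd.Series({"a1": "A", "a2": "A"})
        with pytest.warns(UserWarning, match="all zero"):
            out = C.scale_categories(ko, cats, inc)
        assert (out.to_numpy() == 0).all()
        ko2 = pd.DataFrame({"a1": [1.0]}, index=["K9"])
        assert C.scale_categories(ko2, cats, inc).empty


class TestSelectHighlyExpressed:
    @staticmethod
    def states():
        return pd.DataFrame({
            "sample_id": ["a1", "a2", "b1", "b2"],
            "incubation": ["A", "A", "B", "B"],
            "state": ["growth", "growth", "growth", "lag"],
        })

    def test_strict_threshold_on_growth_means(self):
        ko = pd.DataFrame({"a1": [502.0, 500.0], "a2": [500.0, 500.0],
                           "b1": [10.0, 500.0], "b2": [9e9, 9e9]},
                          index=["K1", "K2"])
        out = C.select_highly_expressed(ko, self.states())
        assert out == {"K1"}   # growth-mean 501 in A; K2 sits exactly at 500

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        ko = pd.DataFrame(rng.uniform(0, 1500, (40, 4)),
                          index=[f"K{i}" for i in range(40)],
                          columns=["a1", "a2", "b1", "b2"])
        lo = C.select_highly_expressed(ko, self.states(), min_mean_tpm=300)
        hi = C.select_highly_expressed(ko, self.states(), min_mean_tpm=800)
        assert hi <= lo

    def test_planted_fixture_recovered_exactly(self):
        rng = np.random.default_rng(1)
        idx = [f"K{i}" for i in range(60)]
        ko = pd.DataFrame(rng.uniform(0, 400, (60, 4)), index=idx,
                          columns=["a1", "a2", "b1", "b2"])
        planted = set(idx[:40])
        ko.loc[sorted(planted), ["a1", "a2"]] = rng.uniform(600, 2000, (40, 2))
        assert C.select_highly_expressed(ko, self.states()) == planted


class TestLoadHousekeeping:
    def test_intersection_and_missing_warning(self, tmp_path):
        ko = pd.DataFrame({"s1": [1.0] * 4}, index=["K1", "K2", "K3", "K4"])
        f = tmp_path / "hk.txt"
        f.write_text("K1\nK2\nK3\nK4\nK9\n")
        with pytest.warns(UserWarning, match="absent"):
            present, missing = C.load_housekeeping(f, ko)
        assert present == {"K1", "K2", "K3", "K4"}
        assert missing == ["K9"]

    def test_empty_file_and_empty_intersection_error(self, tmp_path):
        ko = pd.DataFrame({"s1": [1.0]}, index=["K1"])
        f = tmp_path / "hk.txt"
        f.write_text("")
        with pytest.raises(InputError):
            C.load_housekeeping(f, ko)
        f.write_text("K8\n")
        with pytest.warns(UserWarning):
            with pytest.raises(DegenerateInputError):
                C.load_housekeeping(f, ko)

    def test_planted_truth_recovered(self, experiment):
        expressed = C.filter_expressed(experiment.transcripts)
        ko, _ = C.pool_kos(expressed)
        hk, missing = C.load_housekeeping(sorted(experiment.truth.hk_ko_ids), ko)
        assert hk == experiment.truth.hk_ko_ids
        assert missing == []
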