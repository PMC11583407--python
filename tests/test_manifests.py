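"""Manifest parsing, probe overlap, mismatch detection, probe filtering."""

import io
import string

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methcompare import (load_manifest, intersect_probes, detect_snp_mismatches,
                         filter_probes, collapse_replicate_probes, base_id,
                         generate_dataset, SimulationConfig)

HEADER = ("IlmnID,Category,Infinium_Design_Type,AlleleA_ProbeSeq,"
          "Color_Channel,Next_Base,CHR,MAPINFO\n")


def _manifest_df(rows):
    return pd.read_csv(io.StringIO(HEADER + "\n".join(rows)), dtype={"CHR": str})


def test_load_manifest_parses_rows_and_base_ids(tmp_path):
    path = tmp_path / "m.csv"
    path.write_text(HEADER
                    + "cg00000029,cg,II,ACGTACGT,none,none,16,53434200\n"
                    + "cg00000108_BC11,cg,I,TTTTACGT,Red,A,3,37417715\n")
    m = load_manifest(path)
    assert len(m) == 2
    assert m.loc[0, "base_id"] == "cg00000029"
    assert m.loc[1, "base_id"] == "cg00000108"
    assert m.loc[1, "MAPINFO"] == 37417715


@given(st.text(alphabet=string.digits, min_size=1, max_size=10),
       st.text(alphabet=string.ascii_uppercase + string.digits,
               min_size=1, max_size=6),
       st.sampled_from(["cg", "rs", "ch"]))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_base_id_strips_exactly_one_trailing_token(digits, token, prefix):
    pid = f"{prefix}{digits}"
    assert base_id(pid) == pid
    assert base_id(f"{pid}_{token}") == pid


def test_load_manifest_failures(tmp_path):
    empty = tmp_path / "empty.csv"
    empty.write_text("")
    with pytest.raises(ValueError):
        load_manifest(empty)
    missing = tmp_path / "missing.csv"
    missing.write_text("IlmnID,Category\ncg1,cg\n")
    with pytest.raises(ValueError, match="Infinium_Design_Type"):
        load_manifest(missing)
    dup = tmp_path / "dup.csv"
    dup.write_text(HEADER + "cg1,cg,II,AA,none,none,1,100\n"
                   + "cg1,cg,II,AA,none,none,1,100\n")
    with pytest.raises(ValueError, match="duplicate"):
        load_manifest(dup)


def test_intersect_identical_manifests_all_shared():
    rows = [f"cg{i},cg,II,ACGT,none,none,1,{100 + i}" for i in range(5)]
    m = _manifest_df(rows)
    res = intersect_probes({"a": m, "b": m.copy(), "c": m.copy()})
    assert len(res["shared_all"]) == 5
    assert res["n_union"] == 5


def test_intersect_disjoint_manifests_share_nothing():
    a = _manifest_df([f"cg{i},cg,II,ACGT,none,none,1,{i+1}" for i in range(3)])
    b = _manifest_df([f"cg{i+10},cg,II,ACGT,none,none,1,{i+1}" for i in range(3)])
    res = intersect_probes({"a": a, "b": b})
    assert len(res["shared_all"]) == 0
    assert res["n_union"] == 6


def test_intersect_matches_generator_bookkeeping_and_partitions(small_dataset):
    ds = small_dataset
    res = intersect_probes(ds.manifests)
    expected_shared = round(ds.config.overlap_fraction * ds.config.n_cpg)
    assert len(res["shared_all"]) == expected_shared
    assert sum(res["counts"].values()) == res["n_union"]
    # regions are disjoint
    all_ids = [pid for region in res["regions"].values() for pid in region]
    assert len(all_ids) == len(set(all_ids))


def test_detect_mismatches_identical_rows_flag_nothing():
    rows = [f"rs{i},rs,I,ACGT,Red,A,1,{i+1}" for i in range(4)]
    m = _manifest_df(rows)
    rep = detect_snp_mismatches({"a": m, "b": m.copy(), "c": m.copy()})
    assert not rep["bad_metric"].any()
    assert rep["comparable"].all()


def test_detect_mismatches_single_attribute_change():
    old = _manifest_df(["rs1,rs,I,ACGT,Red,A,1,10"])
    new = _manifest_df(["rs1,rs,I,ACGT,Grn,A,1,10"])
    rep = detect_snp_mismatches({"a": old, "b": old.copy(), "c": new})
    row = rep.loc["rs1"]
    assert row["channel_mismatch"] and row["bad_metric"]
    assert not row["seq_mismatch"] and not row["nextbase_mismatch"]


def test_detect_mismatches_disagreeing_older_arrays_not_comparable():
    a = _manifest_df(["rs1,rs,I,ACGT,Red,A,1,10"])
    b = _manifest_df(["rs1,rs,I,ACGT,Grn,A,1,10"])
    new = _manifest_df(["rs1,rs,I,ACGT,Grn,A,1,10"])
    rep = detect_snp_mismatches({"a": a, "b": b, "c": new})
    assert not rep.loc["rs1", "comparable"]
    assert not rep.loc["rs1", "bad_metric"]


def test_detect_mismatches_probe_absent_from_older_arrays_not_bad():
    old = _manifest_df(["rs1,rs,I,ACGT,Red,A,1,10"])
    new = _manifest_df(["rs1,rs,I,ACGT,Red,A,1,10",
                        "rs2,rs,I,TTTT,Grn,C,2,20"])
    rep = detect_snp_mismatches({"a": old, "b": new})
    assert not rep.loc["rs2", "comparable"]
    assert not rep.loc["rs2", "bad_metric"]


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_detect_mismatches_recovers_corrupted_set_exactly(seed):
    ds = generate_dataset(SimulationConfig(n_cpg=60, seed=seed))
    rep = detect_snp_mismatches(ds.manifests)
    flagged = sorted(rep.index[rep["bad_metric"]])
    assert flagged == sorted(ds.truth.corrupted_snp_probes)


def test_detect_mismatches_no_rs_probes_warns_empty():
    m = _manifest_df(["cg1,cg,II,ACGT,none,none,1,10"])
    with pytest.warns(UserWarning, match="no rs probes"):
        rep = detect_snp_mismatches({"a": m, "b": m.copy()})
    assert len(rep) == 0


class TestFilterProbes:
    def _inputs(self, fail_fraction, n_samples=20):
        beta = pd.DataFrame(np.full((3, n_samples), 0.5),
                            index=["p1", "p2", "p3"])
        detp = pd.DataFrame(np.zeros((3, n_samples)), index=beta.index)
        beads = pd.DataFrame(np.full((3, n_samples), 10.0), index=beta.index)
        n_fail = int(round(fail_fraction * n_samples))
        detp.iloc[1, :n_fail] = 0.5   # probe p2 fails in n_fail samples
        return beta, detp, beads

    def test_clean_data_removes_nothing(self):
        beta, detp, beads = self._inputs(0.0)
        out, removed = filter_probes(beta, detp, beads)
        assert removed == []
        pd.testing.assert_frame_equal(out, beta)

    def test_probe_failing_quarter_of_samples_removed(self):
        beta, detp, beads = self._inputs(0.25)
        _, removed = filter_probes(beta, detp, beads)
        assert removed == ["p2"]

    def test_probe_failing_exactly_twenty_percent_retained(self):
        beta, detp, beads = self._inputs(0.20)
        _, removed = filter_probes(beta, detp, beads)
        assert removed == []

    def test_bead_rule_and_idempotence(self):
        beta, detp, beads = self._inputs(0.0)
        beads.iloc[2, :6] = 2          # p3: 30% of samples below bead threshold
        out, removed = filter_probes(beta, detp, beads)
        assert removed == ["p3"]
        out2, removed2 = filter_probes(out, detp.loc[out.index],
                                       beads.loc[out.index])
        assert removed2 == []
        pd.testing.assert_frame_equal(out2, out)

    def test_dimension_mismatch_fails(self):
        beta, detp, beads = self._inputs(0.0)
        with pytest.raises(ValueError, match="shape"):
            filter_probes(beta, detp.iloc[:, :-1], beads)


class TestCollapseReplicates:
    manifest = _manifest_df([
        "cg1_BC11,cg,II,ACGT,none,none,1,10",
        "cg1_TC21,cg,II,ACGT,none,none,1,10",
        "cg2,cg,II,ACGT,none,none,1,20",
    ])

    def _beta(self):
        return pd.DataFrame({"s1": [0.2, 0.4, 0.9], "s2": [0.1, 0.3, 0.8]},
                            index=["cg1_BC11", "cg1_TC21", "cg2"])

    def test_mean_policy_averages_replicates(self):
        out = collapse_replicate_probes(self._beta(), self.manifest)
        assert out.at["cg1", "s1"] == pytest.approx(0.3)
        assert out.at["cg2", "s1"] == pytest.approx(0.9)
        assert list(out.index) == ["cg1", "cg2"]

    def test_first_policy_keeps_lexicographically_first(self):
        out = collapse_replicate_probes(self._beta(), self.manifest,
                                        policy="first")
        assert out.at["cg1", "s1"] == pytest.approx(0.2)  # cg1_BC11 < cg1_TC21

    def test_no_replicates_is_identity(self):
        manifest = _manifest_df(["cg2,cg,II,ACGT,none,none,1,20"])
        beta = pd.DataFrame({"s1": [0.9]}, index=["cg2"])
        out = collapse_replicate_probes(beta, manifest)
        assert np.allclose(out.to_numpy(), beta.to_numpy())

    def test_unknown_policy_fails(self):
        with pytest.raises(ValueError, match="policy"):
            collapse_replicate_probes(self._beta(), self.manifest,
                                      policy="median")
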