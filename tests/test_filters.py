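"""FFPE artifact filter, gene copy-number calling, purity correction,
subclone cluster filtering — boundary conventions and oracle equivalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumorhet import (
    call_amplification_deletion,
    assign_gene_copy_number,
    ffpe_artifact_filter,
    filter_subclone_clusters,
    purity_adjust_vaf,
    FFPE_PRIVATE_REASON,
    SHARED_CTRL_REASON,
)
from conftest import (
    brute_force_cluster_filter,
    brute_force_ffpe,
    brute_force_gene_cn,
    random_variant_table,
)


def _variant(sample="p1", vaf=0.10, ref="C", alt="T", cosmic=False, fwd=1, rev=1, ctrl=0, pos=100):
    return {
        "tumor_id": "T1",
        "sample_id": sample,
        "chrom": "sim1",
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "vaf": vaf,
        "alt_fwd": fwd,
        "alt_rev": rev,
        "in_cosmic": cosmic,
        "control_alt_reads": ctrl,
    }


class TestFfpeFilter:
    def test_private_low_vaf_deamination_is_removed(self):
        df = pd.DataFrame([_variant()])
        kept, removed = ffpe_artifact_filter(df)
        assert len(kept) == 0 and len(removed) == 1
        assert removed["reason"].iloc[0] == FFPE_PRIVATE_REASON

    def test_cosmic_and_strand_rescues(self):
        df = pd.DataFrame(
            [
                _variant(cosmic=True, pos=1),
                _variant(ref="G", alt="A", fwd=2, rev=2, pos=2),
            ]
        )
        kept, removed = ffpe_artifact_filter(df)
        assert len(kept) == 2 and len(removed) == 0

    def test_vaf_threshold_is_strict(self):
        df = pd.DataFrame([_variant(vaf=0.15, pos=1), _variant(vaf=0.1499999, pos=2)])
        kept, removed = ffpe_artifact_filter(df)
        assert list(kept["pos"]) == [1]
        assert list(removed["pos"]) == [2]

    def test_strand_rescue_needs_two_reads_on_each_strand(self):
        df = pd.DataFrame(
            [
                _variant(fwd=2, rev=1, pos=1),  # one strand below 2: removed
                _variant(fwd=2, rev=2, pos=2),  # inclusive >=2 both: kept
                _variant(fwd=4, rev=0, pos=3),
            ]
        )
        kept, removed = ffpe_artifact_filter(df)
        assert list(kept["pos"]) == [2]
        assert sorted(removed["pos"]) == [1, 3]

    def test_non_deamination_substitutions_untouched_by_rule1(self):
        df = pd.DataFrame([_variant(ref="A", alt="G"), _variant(ref="T", alt="C", pos=101)])
        kept, removed = ffpe_artifact_filter(df)
        assert len(kept) == 2

    def test_shared_variant_with_control_support_removed(self):
        rows = [
            _variant(sample="p1", ref="A", alt="G", vaf=0.10, ctrl=1),
            _variant(sample="p2", ref="A", alt="G", vaf=0.10, ctrl=1),
            _variant(sample="p1", ref="A", alt="C", vaf=0.10, ctrl=0, pos=200),
            _variant(sample="p2", ref="A", alt="C", vaf=0.10, ctrl=0, pos=200),
            _variant(sample="p1", ref="A", alt="T", vaf=0.20, ctrl=3, pos=300),
            _variant(sample="p2", ref="A", alt="T", vaf=0.20, ctrl=3, pos=300),
        ]
        kept, removed = ffpe_artifact_filter(pd.DataFrame(rows))
        assert (removed["reason"] == SHARED_CTRL_REASON).all()
        assert sorted(removed["pos"]) == [100, 100]

    def test_shared_rule_has_no_cosmic_rescue(self):
        rows = [
            _variant(sample="p1", vaf=0.10, ctrl=1, cosmic=True),
            _variant(sample="p2", vaf=0.10, ctrl=1, cosmic=True),
        ]
        kept, removed = ffpe_artifact_filter(pd.DataFrame(rows))
        assert len(removed) == 2

    def test_privacy_is_evaluated_within_tumor(self):
        # same substitution in two different tumors is private in each
        rows = [_variant(), _variant()]
        rows[1]["tumor_id"] = "T2"
        kept, removed = ffpe_artifact_filter(pd.DataFrame(rows))
        assert len(removed) == 2

    def test_partition_of_input(self):
        rng = np.random.default_rng(5)
        df = random_variant_table(rng)
        kept, removed = ffpe_artifact_filter(df)
        assert len(kept) + len(removed) == len(df)
        assert set(kept.index).isdisjoint(removed.index)

    def test_idempotent_without_control_support(self):
        # with no alt support in the control, rule 2 never fires, so a
        # variant's sharing status cannot change between passes
        rng = np.random.default_rng(5)
        df = random_variant_table(rng)
        df["control_alt_reads"] = 0
        kept, _ = ffpe_artifact_filter(df)
        kept2, removed2 = ffpe_artifact_filter(kept)
        assert len(removed2) == 0
        pd.testing.assert_frame_equal(kept2, kept)

    def test_piece_order_invariance(self):
        rng = np.random.default_rng(6)
        df = random_variant_table(rng)
        kept, _ = ffpe_artifact_filter(df)
        shuffled = df.sample(frac=1.0, random_state=0)
        kept_s, _ = ffpe_artifact_filter(shuffled)
        assert set(kept.index) == set(kept_s.index)

    def test_unknown_sample_id_is_an_error(self):
        sheet = pd.DataFrame({"sample_id": ["p1"], "tumor_id": ["T1"]})
        df = pd.DataFrame([_variant(sample="p9")])
        with pytest.raises(ValueError, match="p9"):
            ffpe_artifact_filter(df, sample_sheet=sheet)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(1000 + seed)
        df = random_variant_table(rng)
        kept, removed = ffpe_artifact_filter(df)
        oracle = brute_force_ffpe(df)
        assert set(removed.index) == set(oracle)
        for i, reason in oracle.items():
            assert removed.loc[i, "reason"] == reason


class TestGeneCopyNumber:
    def test_gene_inside_single_segment(self):
        seg = pd.DataFrame(
            [{"sample_id": "s1", "chrom": "sim1", "start": 1, "end": 1000, "abs_cn": 3.0}]
        )
        gene = pd.DataFrame([{"gene_id": "G1", "chrom": "sim1", "start": 100, "end": 200}])
        cn, tie = assign_gene_copy_number(seg, gene)
        assert cn.loc["G1", "s1"] == 3.0
        assert not tie.loc["G1", "s1"]

    def test_hand_computed_overlaps(self):
        # segment A overlaps gene by 51 bases, B by 50: A wins
        seg = pd.DataFrame(
            [
                {"sample_id": "s1", "chrom": "sim1", "start": 1, "end": 150, "abs_cn": 1.0},
                {"sample_id": "s1", "chrom": "sim1", "start": 151, "end": 500, "abs_cn": 5.0},
            ]
        )
        gene = pd.DataFrame([{"gene_id": "G1", "chrom": "sim1", "start": 100, "end": 200}])
        cn, _ = assign_gene_copy_number(seg, gene)
        assert cn.loc["G1", "s1"] == 1.0

    def test_no_overlap_gives_missing(self):
        seg = pd.DataFrame(
            [{"sample_id": "s1", "chrom": "sim2", "start": 1, "end": 100, "abs_cn": 2.0}]
        )
        gene = pd.DataFrame([{"gene_id": "G1", "chrom": "sim1", "start": 5, "end": 10}])
        cn, _ = assign_gene_copy_number(seg, gene)
        assert np.isnan(cn.loc["G1", "s1"])

    def test_tie_goes_to_smaller_start_and_is_flagged(self):
        seg = pd.DataFrame(
            [
                {"sample_id": "s1", "chrom": "sim1", "start": 1, "end": 150, "abs_cn": 1.0},
                {"sample_id": "s1", "chrom": "sim1", "start": 151, "end": 300, "abs_cn": 5.0},
            ]
        )
        # overlap 50 with each segment
        gene = pd.DataFrame([{"gene_id": "G1", "chrom": "sim1", "start": 101, "end": 200}])
        cn, tie = assign_gene_copy_number(seg, gene)
        assert cn.loc["G1", "s1"] == 1.0
        assert bool(tie.loc["G1", "s1"])

    def test_malformed_interval_is_an_error(self):
        seg = pd.DataFrame(
            [{"sample_id": "s1", "chrom": "sim1", "start": 100, "end": 50, "abs_cn": 2.0}]
        )
        gene = pd.DataFrame([{"gene_id": "G1", "chrom": "sim1", "start": 1, "end": 10}])
        with pytest.raises(ValueError, match="malformed"):
            assign_gene_copy_number(seg, gene)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_layouts(self, seed):
        rng = np.random.default_rng(2000 + seed)
        seg_rows, pos = [], 1
        for s in ("s1", "s2"):
            pos = 1
            while pos < 5000:
                length = int(rng.integers(50, 500))
                seg_rows.append(
                    {
                        "sample_id": s,
                        "chrom": rng.choice(["c1", "c2"]),
                        "start": pos,
                        "end": pos + length - 1,
                        "abs_cn": float(rng.integers(0, 8)),
                    }
                )
                pos += length + int(rng.integers(0, 100))
        segments = pd.DataFrame(seg_rows)
        genes = pd.DataFrame(
            [
                {
                    "gene_id": f"G{i}",
                    "chrom": rng.choice(["c1", "c2"]),
                    "start": (start := int(rng.integers(1, 5000))),
                    "end": start + int(rng.integers(10, 400)),
                }
                for i in range(30)
            ]
        )
        cn, tie = assign_gene_copy_number(segments, genes)
        oracle = brute_force_gene_cn(segments, genes)
        for (gene, sample), (exp_cn, exp_tie) in oracle.items():
            got = cn.loc[gene, sample]
            assert (np.isnan(got) and np.isnan(exp_cn)) or got == exp_cn
            assert bool(tie.loc[gene, sample]) == exp_tie


class TestAmpDelCalls:
    @pytest.mark.parametrize(
        "cn,ploidy,expected",
        [
            (7.0, 4.0, "amplified"),  # 7 > 6
            (3.0, 2.0, "neutral"),  # exactly 1.5x: strict
            (1.0, 2.0, "neutral"),  # exactly 0.5x: strict
            (0.9, 2.0, "deleted"),
            (6.001, 4.0, "amplified"),
            (0.0, 2.0, "deleted"),
        ],
    )
    def test_threshold_conventions(self, cn, ploidy, expected):
        assert call_amplification_deletion(cn, ploidy) == expected

    def test_monotone_in_copy_number(self):
        order = {"deleted": 0, "neutral": 1, "amplified": 2}
        calls = [order[call_amplification_deletion(c, 2.0)] for c in np.linspace(0, 8, 200)]
        assert all(a <= b for a, b in zip(calls, calls[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            call_amplification_deletion(2.0, 0.0)
        with pytest.raises(ValueError):
            call_amplification_deletion(-1.0, 2.0)


class TestPurityAdjustVaf:
    def test_basic_division_and_identity(self):
        adj, flag = purity_adjust_vaf(0.2, 0.5)
        assert adj == pytest.approx(0.4) and not flag
        adj, flag = purity_adjust_vaf(0.37, 1.0)
        assert adj == pytest.approx(0.37) and not flag

    def test_cap_with_overflow_flag(self):
        adj, flag = purity_adjust_vaf(0.6, 0.5)
        assert adj == 1.0 and flag

    def test_zero_purity_is_an_error(self):
        with pytest.raises(ValueError):
            purity_adjust_vaf(0.1, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        vaf=st.floats(0.0, 1.0),
        purity=st.floats(0.01, 1.0),
        scale=st.floats(0.1, 1.0),
    )
    def test_linear_below_cap(self, vaf, purity, scale):
        adj, flag = purity_adjust_vaf(vaf, purity)
        if not flag:
            adj_scaled, _ = purity_adjust_vaf(vaf * scale, purity)
            assert adj_scaled == pytest.approx(adj * scale, abs=1e-12)


class TestClusterFilter:
    def _clusters(self, rows):
        return pd.DataFrame(
            rows, columns=["tumor_id", "cluster_id", "n_mutations", "sample_id", "prevalence"]
        )

    def test_small_cluster_dropped_everywhere(self):
        df = self._clusters(
            [("T1", "c1", 9, "s1", 0.9), ("T1", "c1", 9, "s2", 0.9)]
        )
        out = filter_subclone_clusters(df)
        assert not out["retained"].any()

    def test_prevalence_boundary_is_inclusive(self):
        df = self._clusters(
            [("T1", "c1", 10, "s1", 0.05), ("T1", "c1", 10, "s2", 0.0499999)]
        )
        out = filter_subclone_clusters(df).set_index("sample_id")["retained"]
        assert bool(out["s1"]) and not bool(out["s2"])

    def test_missing_prevalence_treated_as_zero(self, caplog):
        df = self._clusters(
            [
                ("T1", "c1", 12, "s1", 0.5),
                ("T1", "c2", 12, "s1", 0.5),
                ("T1", "c2", 12, "s2", 0.5),
            ]
        )
        import logging

        with caplog.at_level(logging.WARNING):
            out = filter_subclone_clusters(df)
        sub = out.set_index(["cluster_id", "sample_id"])["retained"]
        assert not bool(sub[("c1", "s2")])  # completed pair, prevalence 0
        assert "treating as 0" in caplog.text

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(3000 + seed)
        rows = []
        for t in range(3):
            samples = [f"T{t}_s{i}" for i in range(int(rng.integers(2, 5)))]
            for c in range(int(rng.integers(1, 6))):
                n_mut = int(rng.integers(5, 15))
                for s in samples:
                    if rng.random() < 0.9:  # some missing entries
                        rows.append((f"T{t}", f"c{c}", n_mut, s, float(rng.uniform(0, 0.2))))
        df = self._clusters(rows)
        out = filter_subclone_clusters(df).set_index(["tumor_id", "cluster_id", "sample_id"])
        oracle = brute_force_cluster_filter(df)
        for key, expected in oracle.items():
            assert bool(out.loc[key, "retained"]) == expected
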