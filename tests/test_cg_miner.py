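"""Candidate-gene mining: interval overlap, keyword and expression cascades,
Welch t-test and hypergeometric enrichment against brute-force oracles."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from metaqtl.cg_miner import (
    DEFAULT_KEYWORDS,
    GeneRecord,
    MinerError,
    ResponseCall,
    cascade_filter,
    genes_in_mqtl,
    genes_in_mqtls,
    go_enrichment,
    keyword_filter,
    response_call,
    response_calls,
)
from metaqtl.mqtl_engine import MQTL


def _mqtl(start, stop, chrom=1, mqtl_id="MQTL1.1"):
    return MQTL(
        mqtl_id=mqtl_id, chromosome=chrom, position_cM=1.0, ci95_lo_cM=0.5,
        ci95_hi_cM=1.5, member_qtl_ids=["q1"], member_study_ids=["S1", "S2"],
        traits=["YLD"], avg_pve_percent=10.0, start_bp=start, stop_bp=stop,
    )


def _gene(gid, start, end, chrom=1, ann="", aliases=(), go=()):
    return GeneRecord(gid, chrom, start, end, ann, tuple(aliases), tuple(go))


class TestGeneInterval:
    def test_any_overlap_included(self):
        m = _mqtl(150, 300)
        inside = _gene("g1", 100, 200)
        outside = _gene("g2", 301, 400)
        other_chrom = _gene("g3", 150, 300, chrom=2)
        found = genes_in_mqtl(m, [inside, outside, other_chrom])
        assert [g.gene_id for g in found] == ["g1"]

    def test_pooled_union_is_nonredundant(self):
        shared = _gene("g1", 100, 200)
        m1, m2 = _mqtl(50, 250), _mqtl(150, 400, mqtl_id="MQTL1.2")
        per, pooled = genes_in_mqtls([m1, m2], [shared])
        assert len(per["MQTL1.1"]) == len(per["MQTL1.2"]) == 1
        assert len(pooled) == 1

    def test_widening_never_removes_genes(self, rng):
        genes = [
            _gene(f"g{i}", int(s), int(s) + 500)
            for i, s in enumerate(rng.integers(0, 100_000, size=40))
        ]
        narrow = {g.gene_id for g in genes_in_mqtl(_mqtl(20_000, 50_000), genes)}
        wide = {g.gene_id for g in genes_in_mqtl(_mqtl(10_000, 80_000), genes)}
        assert narrow <= wide


class TestKeywordFilter:
    def test_annotation_match(self):
        kept = keyword_filter([_gene("g1", 1, 2, ann="Phosphate transporter 4;1")])
        assert len(kept) == 1

    def test_unrelated_annotation_dropped(self):
        assert keyword_filter([_gene("g1", 1, 2, ann="tRNA ligase")]) == []

    def test_alias_only_match(self):
        g = _gene("g1", 1, 2, ann="hypothetical", aliases=("OsPhosphate1",))
        assert keyword_filter([g]) == [g]

    def test_empty_keyword_list_is_error(self):
        with pytest.raises(MinerError):
            keyword_filter([_gene("g1", 1, 2)], keywords=[])


def _expr(gene, reps_by_cond):
    rows = []
    for tp in ("6h", "24h"):
        for cond, reps in reps_by_cond[tp].items():
            rows.append({"gene_id": gene, "timepoint": tp, "condition": cond,
                         **{f"rep{i+1}": v for i, v in enumerate(reps)}})
    return pd.DataFrame(rows)


def welch_p_oracle(a, b):
    """Closed-form Welch t-test (two-sided) via the t survival function."""
    from scipy.stats import t as tdist
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    tstat = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return 2 * tdist.sf(abs(tstat), df)


class TestResponseCall:
    def test_fold_change_and_direction(self):
        df = _expr("g1", {
            "6h": {"minusP": [200, 200, 200], "control": [100, 100, 100]},
            "24h": {"minusP": [210, 190, 200], "control": [95, 105, 100]},
        })
        call = response_call(df)
        assert call.fc_6h == pytest.approx(2.0)
        assert call.direction_6h == call.direction_24h == "up"

    def test_identical_replicates_give_unit_fc_and_p_one(self):
        df = _expr("g1", {
            "6h": {"minusP": [100, 100, 100], "control": [100, 100, 100]},
            "24h": {"minusP": [100, 100, 100], "control": [100, 100, 100]},
        })
        call = response_call(df)
        assert call.fc_6h == 1.0 and call.p_6h == 1.0 and call.tier == "ns"

    def test_welch_p_matches_hand_formula(self):
        minus, ctrl = [230.0, 210.0, 260.0], [100.0, 120.0, 90.0]
        df = _expr("g1", {"6h": {"minusP": minus, "control": ctrl},
                          "24h": {"minusP": minus, "control": ctrl}})
        call = response_call(df)
        assert call.p_6h == pytest.approx(welch_p_oracle(minus, ctrl), abs=1e-12)
        assert call.tier == "p01"

    def test_missing_condition_is_no_data(self):
        df = _expr("g1", {"6h": {"minusP": [1, 2, 3], "control": [1, 2, 3]},
                          "24h": {"minusP": [1, 2, 3], "control": [1, 2, 3]}})
        df = df[~((df["timepoint"] == "24h") & (df["condition"] == "control"))]
        calls, no_data = response_calls(df)
        assert calls == [] and no_data == ["g1"]

    def test_swapping_conditions_inverts_fc_and_flips_direction(self):
        df = _expr("g1", {"6h": {"minusP": [300, 310, 290], "control": [100, 110, 90]},
                          "24h": {"minusP": [300, 310, 290], "control": [100, 110, 90]}})
        fwd = response_call(df)
        swapped = df.copy()
        swapped["condition"] = swapped["condition"].map(
            {"minusP": "control", "control": "minusP"}
        )
        rev = response_call(swapped)
        assert rev.fc_6h == pytest.approx(1.0 / fwd.fc_6h)
        assert fwd.direction_6h == "up" and rev.direction_6h == "down"


def _call(gid, fc6, fc24, p=0.01):
    return ResponseCall(
        gene_id=gid, fc_6h=fc6, fc_24h=fc24,
        direction_6h="up" if fc6 > 1 else "down",
        direction_24h="up" if fc24 > 1 else "down",
        p_6h=p, p_24h=p, tier="p01",
    )


class TestCascade:
    def test_stage_membership(self):
        calls = [
            _call("both", 1.6, 2.1),      # A, B, C
            _call("inconsistent", 1.7, 0.5),  # excluded at A
            _call("no2fold", 1.6, 1.8),   # A, B but not C
            _call("weak", 1.1, 1.2),      # A only
            _call("down", 0.5, 0.4),      # down-regulated: A, B, C
        ]
        stages = cascade_filter(calls)
        ids = {k: {c.gene_id for c in v} for k, v in stages.items()}
        assert ids["A"] == {"both", "no2fold", "weak", "down"}
        assert ids["B"] == {"both", "no2fold", "down"}
        assert ids["C"] == {"both", "down"}

    def test_stages_nested_and_counts_consistent(self, rng):
        calls = [
            _call(f"g{i}", float(rng.uniform(0.2, 4)), float(rng.uniform(0.2, 4)))
            for i in range(50)
        ]
        stages = cascade_filter(calls)
        a, b, c = (set(x.gene_id for x in stages[s]) for s in "ABC")
        assert c <= b <= a
        for s in "ABC":
            ups = sum(1 for x in stages[s] if x.direction_24h == "up")
            downs = sum(1 for x in stages[s] if x.direction_24h == "down")
            assert ups + downs == len(stages[s])


def hypergeom_upper_tail_oracle(M, n_term, N_fg, k):
    """P[X >= k] by direct combinatorial enumeration."""
    total = math.comb(M, N_fg)
    acc = 0
    for j in range(k, min(n_term, N_fg) + 1):
        acc += math.comb(n_term, j) * math.comb(M - n_term, N_fg - j)
    return acc / total


class TestEnrichment:
    def test_exact_small_example(self):
        bg = [f"g{i}" for i in range(20)]
        fg = bg[:5]
        gene2go = {g: ["T1"] for g in bg[:4]} | {bg[10]: ["T1"]}
        out = go_enrichment(fg, bg, gene2go)
        row = out[out["term"] == "T1"].iloc[0]
        assert row["p"] == pytest.approx(76 / 15504, abs=1e-12)

    def test_foreground_equals_background_is_null(self):
        bg = [f"g{i}" for i in range(10)]
        gene2go = {g: ["T1"] for g in bg[:4]}
        out = go_enrichment(bg, bg, gene2go)
        assert out["p"].to_numpy() == pytest.approx(1.0)

    def test_bh_hand_case(self):
        bg = [f"g{i}" for i in range(30)]
        # three disjoint terms engineered to give increasing p-values
        gene2go = {}
        for g in bg[:6]:
            gene2go[g] = ["T1"]
        for g in bg[6:14]:
            gene2go[g] = ["T2"]
        for g in bg[14:24]:
            gene2go[g] = ["T3"]
        fg = bg[:5] + [bg[6], bg[7], bg[8], bg[14], bg[15]]
        out = go_enrichment(fg, bg, gene2go).set_index("term")
        ps = out["p"]
        expect_q = {}
        ranked = ps.sort_values()
        m = len(ranked)
        raw = [p * m / (i + 1) for i, p in enumerate(ranked)]
        for i in range(m - 2, -1, -1):
            raw[i] = min(raw[i], raw[i + 1])
        for term, q in zip(ranked.index, raw):
            expect_q[term] = min(q, 1.0)
        for term in out.index:
            assert out.loc[term, "q"] == pytest.approx(expect_q[term], abs=1e-12)

    def test_matches_enumeration_on_random_small_backgrounds(self, rng):
        for _ in range(25):
            M = int(rng.integers(5, 26))
            bg = [f"g{i}" for i in range(M)]
            n_term = int(rng.integers(1, M + 1))
            term_genes = set(rng.choice(bg, size=n_term, replace=False).tolist())
            N_fg = int(rng.integers(1, M + 1))
            fg = rng.choice(bg, size=N_fg, replace=False).tolist()
            k = len(term_genes & set(fg))
            out = go_enrichment(fg, bg, {g: ["T"] for g in term_genes})
            if k == 0:
                assert out.empty
            else:
                assert out.iloc[0]["p"] == pytest.approx(
                    hypergeom_upper_tail_oracle(M, n_term, N_fg, k), abs=1e-10
                )

    def test_foreground_outside_background_rejected(self):
        with pytest.raises(MinerError):
            go_enrichment(["x"], ["a", "b"], {})


def test_gff3_reader_extracts_gene_features(tmp_path):
    from metaqtl.cg_miner import read_gff3

    gff = tmp_path / "genes.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "Chr1\ttest\tgene\t1000\t2000\t.\t+\t.\t"
        "ID=G1;Note=Phosphate transporter;Alias=OsPT99\n"
        "Chr1\ttest\tgene\t5000\t6000\t.\t-\t.\tID=G2;Note=tRNA ligase\n"
    )
    genes = read_gff3(gff)
    assert [g.gene_id for g in genes] == ["G1", "G2"]
    assert genes[0].start_bp == 1000 and genes[0].end_bp == 2000
    assert keyword_filter(genes) == [genes[0]]
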