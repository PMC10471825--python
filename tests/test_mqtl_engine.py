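"""Meta-QTL clustering: DP segmentation vs exhaustive oracle, EM mixture,
summaries and filtering."""
import itertools
import math

import numpy as np
import pytest

from metaqtl.mqtl_engine import (
    CI_TO_SD,
    EngineError,
    MQTL,
    ProjectedQTL,
    ci_reduction_report,
    cluster_em,
    cluster_chromosome,
    cluster_small,
    filter_mqtls,
    summarize,
)

from conftest import make_pqtl


def exhaustive_best_segmentation(x, sd):
    """Independent oracle: enumerate every contiguous partition of the sorted
    positions for every K, score with precision-weighted Gaussian likelihood
    and the segmentation information criterion, and return
    (K, loglik, criterion, labels)."""
    order = np.argsort(x, kind="stable")
    x = np.asarray(x)[order]
    w = 1.0 / np.asarray(sd)[order] ** 2
    n = len(x)

    def seg_ll(idx):
        mu = np.sum(w[idx] * x[idx]) / np.sum(w[idx])
        return sum(
            -0.5 * math.log(2 * math.pi / w[i]) - 0.5 * w[i] * (x[i] - mu) ** 2
            for i in idx
        )

    best = None
    for k in range(1, n + 1):
        for cuts in itertools.combinations(range(1, n), k - 1):
            bounds = [0, *cuts, n]
            ll = sum(
                seg_ll(list(range(bounds[j], bounds[j + 1])))
                for j in range(k)
            )
            aic = -2 * ll + 2 * k + 3 * (k - 1) * math.log(n)
            if best is None or aic < best[2] - 1e-9:
                labels = np.zeros(n, dtype=int)
                for j in range(k):
                    labels[bounds[j]: bounds[j + 1]] = j
                best = (k, ll, aic, labels, order)
    return best


class TestClusterSmall:
    def test_single_qtl(self):
        model = cluster_small([make_pqtl(1, 10.0)])
        assert model.K == 1 and model.means == [10.0]

    def test_two_near_one_far(self):
        qtls = [make_pqtl(1, 10.0), make_pqtl(2, 10.5), make_pqtl(3, 40.0)]
        model = cluster_small(qtls)
        assert model.K == 2
        assert model.means == pytest.approx([10.25, 40.0])
        assert model.assignment["q001"] == model.assignment["q002"] != model.assignment["q003"]

    @pytest.mark.parametrize("xs", [(10.0, 14.0), (10.0, 10.4), (0.0, 3.0, 9.0)])
    def test_matches_exhaustive_on_small_cases(self, xs):
        qtls = [make_pqtl(i, x) for i, x in enumerate(xs)]
        model = cluster_small(qtls)
        k, ll, aic, labels, order = exhaustive_best_segmentation(list(xs), [1.0] * len(xs))
        assert model.K == k
        assert model.aic == pytest.approx(aic, abs=1e-9)

    def test_matches_exhaustive_on_random_instances(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 8))
            x = rng.uniform(0, 60, size=n)
            sd = rng.uniform(0.5, 4.0, size=n)
            qtls = [make_pqtl(i, float(x[i]), float(sd[i])) for i in range(n)]
            model = cluster_small(qtls)
            k, ll, aic, labels, order = exhaustive_best_segmentation(x, sd)
            assert model.K == k
            assert model.log_likelihood == pytest.approx(ll, abs=1e-7)
            assert model.aic == pytest.approx(aic, abs=1e-7)

    def test_empty_and_bad_sd_rejected(self):
        with pytest.raises(EngineError):
            cluster_small([])
        with pytest.raises(EngineError):
            ProjectedQTL("q", 1, 1.0, 0.0, 5.0, make_pqtl(1, 1.0).trait, "S1")


class TestClusterEM:
    def test_degenerate_identical_points(self):
        qtls = [make_pqtl(i, 20.0) for i in range(12)]
        model = cluster_em(qtls, seed=0)
        assert model.K == 1
        assert model.means[0] == pytest.approx(20.0)
        assert model.weights[0] == pytest.approx(1.0)

    def test_two_well_separated_components(self, rng):
        # two tight clouds far apart relative to the stated position error
        xs = np.concatenate([rng.normal(10, 0.5, 6), rng.normal(50, 0.5, 6)])
        qtls = [make_pqtl(i, float(x)) for i, x in enumerate(xs)]
        model = cluster_em(qtls, seed=0)
        assert model.K == 2
        assert abs(model.means[0] - 10) < 1.5 and abs(model.means[1] - 50) < 1.5
        # cross-check against the exact segmentation run on the same data
        exact = cluster_small(qtls)
        assert exact.K == 2
        assert sorted(model.assignment.items()) == sorted(exact.assignment.items())

    def test_best_loglik_nondecreasing_in_k(self, rng):
        xs = np.concatenate([rng.normal(10, 1, 8), rng.normal(35, 1, 8)])
        qtls = [make_pqtl(i, float(x)) for i, x in enumerate(xs)]
        lls = []
        for k in range(1, 5):
            # force the selected K by restricting the search to one value
            model = cluster_em(qtls, k_max=k, seed=0)
            lls.append(model.log_likelihood)
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))

    def test_dispatch_threshold(self):
        small = [make_pqtl(i, float(i)) for i in range(5)]
        assert cluster_chromosome(small).method == "segmentation"
        big = [make_pqtl(i, float(i % 4) * 15) for i in range(12)]
        assert cluster_chromosome(big).method == "mixture"


class TestSummarize:
    def test_closed_form_ci(self):
        qtls = [make_pqtl(1, 10.0), make_pqtl(2, 14.0)]
        model = cluster_small(qtls)
        # force a single cluster to check the pooled summary arithmetic
        model.assignment = {"q001": 0, "q002": 0}
        (m,) = summarize(model, qtls)
        assert m.position_cM == pytest.approx(12.0)
        assert m.ci95_lo_cM == pytest.approx(12 - 1.96 / math.sqrt(2), abs=1e-3)
        assert m.ci95_hi_cM == pytest.approx(13.386, abs=1e-3)

    def test_single_member(self):
        qtls = [make_pqtl(1, 10.0, sd=2.0, pve=8.0)]
        (m,) = summarize(cluster_small(qtls), qtls)
        assert m.position_cM == pytest.approx(10.0)
        assert m.ci95_lo_cM == pytest.approx(6.08)
        assert m.ci95_hi_cM == pytest.approx(13.92)
        assert m.avg_pve_percent == pytest.approx(8.0)

    def test_avg_pve_is_member_mean_and_ids_by_position(self):
        qtls = [
            make_pqtl(1, 50.0, pve=12.0), make_pqtl(2, 50.5, pve=8.0),
            make_pqtl(3, 51.0, pve=10.0), make_pqtl(4, 5.0, pve=7.0),
        ]
        model = cluster_small(qtls)
        mqtls = summarize(model, qtls)
        assert [m.mqtl_id for m in mqtls] == ["MQTL1.1", "MQTL1.2"]
        big = next(m for m in mqtls if m.n_members == 3)
        assert big.avg_pve_percent == pytest.approx(10.0)

    def test_position_in_convex_hull_and_conservation(self, rng):
        xs = rng.uniform(0, 100, size=9)
        qtls = [make_pqtl(i, float(x), sd=float(rng.uniform(0.5, 3))) for i, x in enumerate(xs)]
        model = cluster_small(qtls)
        mqtls = summarize(model, qtls)
        assert sum(m.n_members for m in mqtls) == len(qtls)
        for m in mqtls:
            member_x = [q.x for q in qtls if q.qtl_id in m.member_qtl_ids]
            assert min(member_x) - 1e-9 <= m.position_cM <= max(member_x) + 1e-9


def _mqtl(avg_pve, studies, chrom=1):
    sids = [f"S{i}" for i in range(studies)]
    return MQTL(
        mqtl_id="MQTL1.1", chromosome=chrom, position_cM=10.0,
        ci95_lo_cM=9.0, ci95_hi_cM=11.0, member_qtl_ids=["q1"],
        member_study_ids=sids, traits=["YLD"], avg_pve_percent=avg_pve,
        start_bp=0, stop_bp=1, aic=0.0, model_K=1,
    )


@pytest.mark.parametrize(
    "avg_pve, studies, kept",
    [(4.9, 3, False), (12.0, 1, False), (5.0, 2, True), (7.5, 4, True)],
)
def test_filter_thresholds_inclusive(avg_pve, studies, kept):
    out = filter_mqtls([_mqtl(avg_pve, studies)])
    assert (len(out) == 1) is kept


def test_ci_reduction_arithmetic():
    qtls = [make_pqtl(1, 10.0, sd=14.0 / CI_TO_SD), make_pqtl(2, 12.0, sd=14.0 / CI_TO_SD)]
    mqtls = [_mqtl(10.0, 2)]
    mqtls[0].ci95_lo_cM, mqtls[0].ci95_hi_cM = 9.0, 11.8  # width 2.8
    rep = ci_reduction_report(qtls, mqtls)
    row = rep.iloc[0]
    assert row["fold_change"] == pytest.approx(5.0)
    assert row["reduction_cM"] == pytest.approx(11.2)


def test_ci_reduction_fold_one_for_identical_widths():
    qtls = [make_pqtl(1, 10.0, sd=2.0 / CI_TO_SD)]
    m = _mqtl(10.0, 2)
    m.ci95_lo_cM, m.ci95_hi_cM = 9.0, 11.0
    rep = ci_reduction_report(qtls, [m])
    assert rep.iloc[0]["fold_change"] == pytest.approx(1.0)
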