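"""Sliding-window Hotelling T^2 region calling: eligibility, windows,
the test itself against independent oracles, and the dual DMR criterion."""

import itertools

import numpy as np
import pytest

from wsmeth.array_io import ProbeAnnotation, Relation
from wsmeth.dmp import probe_anova
from wsmeth.dmr import (
    DMRParams,
    WindowResult,
    call_dmrs,
    eligible_probes,
    hotelling_t2,
    make_windows,
    window_significant,
)

from conftest import island_probes, make_matrix

GROUPS_3V3 = ["CASE"] * 3 + ["CTRL"] * 3


class TestEligibility:
    def test_open_sea_gene_probe_excluded(self):
        a = ProbeAnnotation("cgA", "chr1", 100, frozenset({"FOO"}))
        assert eligible_probes([a]) == []

    def test_island_probe_without_gene_excluded(self):
        a = ProbeAnnotation("cgA", "chr1", 100, frozenset(), "chr1:90-190", Relation.ISLAND)
        assert eligible_probes([a]) == []

    def test_gene_annotated_shore_included_and_sorted(self):
        a = ProbeAnnotation("cgA", "chr5", 158691793, frozenset({"UBLCP1"}),
                            "chr5:158690013-158690541", Relation.S_SHORE)
        b = ProbeAnnotation("cgB", "chr2", 500, frozenset({"X"}), "chr2:400-600", Relation.ISLAND)
        assert eligible_probes([a, b]) == [b, a]


class TestWindows:
    def test_five_probes_three_windows(self):
        probes = island_probes("chr1:100-600", "chr1", 100, 5)
        assert len(make_windows(probes)) == 5 - 3 + 1

    def test_two_probes_no_window(self):
        probes = island_probes("chr1:100-300", "chr1", 100, 2)
        assert make_windows(probes) == []

    def test_windows_never_span_island_boundaries(self):
        first = island_probes("chr1:100-400", "chr1", 100, 3)
        second = island_probes("chr1:500-800", "chr1", 500, 3)
        windows = make_windows(eligible_probes(first + second))
        assert len(windows) == 2
        for w in windows:
            assert len({a.island_name for a in w}) == 1


class TestHotelling:
    def test_equal_means_t2_zero_p_one(self, rng):
        base = rng.random((3, 3))
        betas = np.hstack([base, base])  # identical group means, nonzero variance
        res = hotelling_t2(betas + rng.normal(0, 0, betas.shape), GROUPS_3V3)
        assert res.T2 == pytest.approx(0, abs=1e-12)
        assert res.p_value == 1

    def test_univariate_reduction_equals_anova(self, rng):
        betas = rng.random((1, 8))
        groups = ["CASE"] * 4 + ["CTRL"] * 4
        res = hotelling_t2(betas, groups)
        _, p_anova = probe_anova(betas[0, :4], betas[0, 4:])
        assert res.p_value == pytest.approx(p_anova, rel=1e-10)

    def test_matches_balanced_permutation_distribution(self):
        betas = np.array(
            [
                [0.62, 0.55, 0.70, 0.45, 0.52, 0.40],
                [0.58, 0.49, 0.66, 0.43, 0.50, 0.38],
                [0.33, 0.28, 0.38, 0.22, 0.27, 0.18],
            ]
        )
        obs = hotelling_t2(betas, GROUPS_3V3)
        perm = []
        for case_idx in itertools.combinations(range(6), 3):
            groups = ["CTRL"] * 6
            for i in case_idx:
                groups[i] = "CASE"
            perm.append(hotelling_t2(betas, groups).T2)
        p_perm = np.mean(np.asarray(perm) >= obs.T2 - 1e-12)
        mc_err = 2.6 * np.sqrt(p_perm * (1 - p_perm) / 20) + 0.05
        assert abs(obs.p_value - p_perm) <= mc_err

    def test_affine_invariance_and_label_swap(self, rng):
        betas = rng.random((3, 6)) * 0.5 + 0.2
        res = hotelling_t2(betas, GROUPS_3V3)
        scaled = hotelling_t2(np.clip(0.1 + 0.8 * betas, 0, 1), GROUPS_3V3)
        assert scaled.T2 == pytest.approx(res.T2, rel=1e-9)
        swapped = hotelling_t2(betas, ["CTRL"] * 3 + ["CASE"] * 3)
        assert swapped.p_value == pytest.approx(res.p_value, rel=1e-12)
        assert np.allclose(swapped.deltas, -np.asarray(res.deltas))

    def test_agrees_with_statsmodels_manova(self, rng):
        # two-group MANOVA: Wilks lambda F/p must coincide with the T2 transform
        from statsmodels.multivariate.manova import MANOVA
        import pandas as pd

        for _ in range(20):
            betas = rng.random((3, 8))
            groups = ["CASE"] * 4 + ["CTRL"] * 4
            res = hotelling_t2(betas, groups)
            df = pd.DataFrame(betas.T, columns=["y1", "y2", "y3"])
            df["g"] = groups
            mv = MANOVA.from_formula("y1 + y2 + y3 ~ g", data=df)
            wilks = mv.mv_test().results["g"]["stat"].loc["Wilks' lambda"]
            assert res.F_stat == pytest.approx(float(wilks["F Value"]), rel=1e-8)
            assert res.p_value == pytest.approx(float(wilks["Pr > F"]), rel=1e-8, abs=1e-12)

    def test_insufficient_samples_error_names_minimum(self):
        with pytest.raises(ValueError, match="5 samples"):
            hotelling_t2(np.random.default_rng(0).random((3, 4)), ["CASE"] * 2 + ["CTRL"] * 2)

    def test_singular_covariance_flagged(self):
        row = np.array([0.1, 0.2, 0.3, 0.6, 0.7, 0.8])
        betas = np.vstack([row, row, row])  # rank-1 pooled covariance
        res = hotelling_t2(betas, GROUPS_3V3)
        assert res.singular


def _window(p, deltas):
    return WindowResult(
        probe_ids=("a", "b", "c"), island_name="isl", chrom="chr1",
        positions=(100, 200, 300), T2=1.0, F_stat=1.0, p_value=p, deltas=deltas,
    )


class TestDualCriterion:
    @pytest.mark.parametrize(
        "p, deltas, expected",
        [
            (5e-4, (+0.35, +0.31, +0.05), True),   # two adjacent probes >= 0.3
            (5e-4, (+0.35, +0.05, +0.31), False),  # exceeding probes not adjacent
            (0.01, (+0.40, +0.40, +0.40), False),  # p fails
            (5e-4, (+0.30, +0.30, +0.05), True),   # delta criterion is inclusive
            (0.001, (+0.35, +0.35, +0.35), False), # p criterion is strict
            (5e-4, (-0.35, -0.31, +0.05), True),   # sign does not matter
        ],
    )
    def test_rule(self, p, deltas, expected):
        assert window_significant(_window(p, deltas), DMRParams()) is expected


class TestCallDmrs:
    def _scene(self, effects, sd=0.005, seed=0):
        """One 6-probe island; ``effects`` added to the case group."""
        rng = np.random.default_rng(seed)
        probes = island_probes("chr1:100-700", "chr1", 100, len(effects))
        base = rng.uniform(0.3, 0.5, len(effects))[:, None]
        values = base + rng.normal(0, sd, (len(effects), 6))
        values[:, :3] += np.asarray(effects)[:, None]
        m = make_matrix(np.clip(values, 0, 1), probe_ids=[a.probe_id for a in probes])
        return m, probes

    def test_spiked_run_called_and_merged_into_one_dmr(self):
        m, probes = self._scene([0.35, 0.35, 0.35, 0.0, 0.0, 0.0], sd=0.004)
        windows, dmrs = call_dmrs(m, probes)
        assert len(windows) == 4
        assert len(dmrs) == 1
        d = dmrs[0]
        assert d.direction == "HYPER"
        assert d.start == probes[0].position and d.end <= probes[-1].position
        assert d.p_value == min(w.p_value for w in windows if window_significant(w, DMRParams()))

    def test_flat_island_yields_no_dmr(self):
        m, probes = self._scene([0.0] * 6)
        _, dmrs = call_dmrs(m, probes)
        assert dmrs == []

    def test_direction_mixed_when_signs_conflict(self):
        m, probes = self._scene([0.35, -0.35, 0.35, 0.35, 0.0, 0.0], sd=0.003)
        _, dmrs = call_dmrs(m, probes)
        for d in dmrs:
            assert d.direction in ("HYPER", "MIXED")

    def test_dmr_p_below_threshold_and_min_probe_count(self):
        m, probes = self._scene([0.4, 0.4, 0.4, 0.4, 0.0, 0.0], sd=0.004)
        _, dmrs = call_dmrs(m, probes)
        params = DMRParams()
        for d in dmrs:
            assert d.p_value < params.p_threshold
            assert len(d.probe_ids) >= params.window_size
            assert d.start <= d.end


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DMRParams(window_size=1)
        with pytest.raises(ValueError):
            DMRParams(min_adjacent_exceeding=4)
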