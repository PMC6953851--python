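"""ANOVA, Scott-Knott means clustering and Pearson correlation."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from pgpbscreen.model import BiomassObservation, Species
from pgpbscreen.stats import AnovaResult, one_way_anova, pearson, scott_knott


def obs_from_groups(groups: dict, species=Species.TOMATO, offset=100.0):
    """Observations from raw group values; the constant offset keeps dry
    weights positive and changes no sum of squares."""
    out = []
    for trt, vals in groups.items():
        for i, v in enumerate(vals):
            out.append(BiomassObservation(species, trt, i + 1, v + offset, v + offset))
    return out


class TestAnova:
    def test_hand_computed_two_group_example(self):
        a = one_way_anova(obs_from_groups({"g1": [1, 2, 3], "g2": [4, 5, 6]}),
                          "tomato", "rdw")
        assert a.f == pytest.approx(13.5)
        assert a.mse == pytest.approx(1.0)
        assert a.df_error == 4

    def test_all_equal_observations_give_zero_f(self):
        a = one_way_anova(obs_from_groups({"g1": [2, 2], "g2": [2, 2]}), "tomato", "rdw")
        assert a.f == 0.0

    def test_agrees_with_scipy_f_oneway(self):
        rng = np.random.default_rng(0)
        groups = {f"g{i}": list(rng.normal(i * 0.1, 1.0, size=5)) for i in range(4)}
        a = one_way_anova(obs_from_groups(groups), "tomato", "rdw")
        f_ref, p_ref = sps.f_oneway(*groups.values())
        assert a.f == pytest.approx(float(f_ref))
        assert a.p_value == pytest.approx(float(p_ref))

    def test_permuting_labels_preserves_total_sum_of_squares(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=12)
        g1 = {"a": list(vals[:6]), "b": list(vals[6:])}
        g2 = {"a": list(vals[::2]), "b": list(vals[1::2])}
        def ss_total(a):
            # SSB + SSW recomposed from the decomposition
            ssb = a.f * a.mse * (a.k - 1)
            return ssb + a.mse * a.df_error
        a1 = one_way_anova(obs_from_groups(g1), "tomato", "rdw")
        a2 = one_way_anova(obs_from_groups(g2), "tomato", "rdw")
        assert ss_total(a1) == pytest.approx(ss_total(a2))

    def test_single_replicate_group_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            one_way_anova(obs_from_groups({"g1": [1.0], "g2": [1, 2]}), "tomato", "rdw")

    def test_unbalanced_design_uses_harmonic_mean_and_is_flagged(self):
        a = one_way_anova(obs_from_groups({"g1": [1, 2, 3, 4], "g2": [4, 5]}),
                          "tomato", "rdw")
        assert not a.balanced
        assert a.r == pytest.approx(2 / (1 / 4 + 1 / 2))


def brute_force_scott_knott(means: dict, mse: float, r: float, nu: int, alpha: float):
    """Independent oracle: iterative exhaustive split search on sorted means."""
    order = sorted(means, key=lambda t: (-means[t], t))
    out = []

    def split(treats):
        k = len(treats)
        if k == 1:
            out.append(treats)
            return
        m = [means[t] for t in treats]
        total = sum(m)
        candidates = []
        for cut in range(1, k):
            t1, t2 = sum(m[:cut]), sum(m[cut:])
            b0 = t1 ** 2 / cut + t2 ** 2 / (k - cut) - total ** 2 / k
            candidates.append((b0, cut))
        b0, cut = max(candidates)
        ybar = total / k
        sigma0 = (sum((x - ybar) ** 2 for x in m) + nu * mse / r) / (k + nu)
        lam = math.pi / (2 * (math.pi - 2)) * b0 / sigma0
        crit = sps.chi2.ppf(1 - alpha, k / (math.pi - 2))
        if lam > crit:
            split(treats[:cut])
            split(treats[cut:])
        else:
            out.append(treats)

    split(order)
    return out


class TestScottKnott:
    def make_anova(self, means, mse=0.05, r=5, nu=16):
        return AnovaResult(k=len(means), r=r, f=1.0, mse=mse, df_error=nu,
                           means=dict(means))

    def test_all_means_equal_yield_one_group(self):
        g = scott_knott(self.make_anova({"a": 1.0, "b": 1.0, "c": 1.0}))
        assert g.clusters == [["a", "b", "c"]]

    def test_two_well_separated_tiers_split_cleanly(self):
        g = scott_knott(self.make_anova({"a": 1.0, "b": 1.1, "c": 9.0, "d": 9.2}))
        assert [sorted(c) for c in g.clusters] == [["c", "d"], ["a", "b"]]
        assert g.labels["c"] == "a" and g.labels["a"] == "b"

    def test_tiny_alpha_never_splits(self):
        g = scott_knott(self.make_anova({"a": 1.0, "b": 5.0, "c": 9.0}), alpha=1e-12)
        assert len(g.clusters) == 1

    def test_clusters_are_contiguous_in_mean_order(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            means = {f"t{i}": float(rng.normal(0, 2)) for i in range(7)}
            g = scott_knott(self.make_anova(means, mse=0.5, r=4, nu=21))
            ordered = sorted(means, key=lambda t: (-means[t], t))
            flat = [t for c in g.clusters for t in c]
            assert flat == ordered  # interval clusters in sorted order

    def test_decreasing_alpha_never_increases_group_count(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            means = {f"t{i}": float(rng.normal(0, 1.5)) for i in range(6)}
            an = self.make_anova(means, mse=0.4, r=5, nu=24)
            counts = [len(scott_knott(an, a).clusters) for a in (0.20, 0.05, 0.01, 0.001)]
            assert counts == sorted(counts, reverse=True)

    @pytest.mark.parametrize("k", [3, 4, 5, 6])
    def test_matches_brute_force_oracle(self, k):
        rng = np.random.default_rng(k * 17)
        for _ in range(25):
            means = {f"t{i}": float(rng.normal(0, 1)) for i in range(k)}
            mse, r, nu = float(rng.uniform(0.05, 1.0)), 5, 4 * k
            ours = scott_knott(AnovaResult(k, r, 1.0, mse, nu, dict(means))).clusters
            oracle = brute_force_scott_knott(means, mse, r, nu, 0.05)
            assert ours == oracle

    def test_null_split_rate_is_near_alpha(self):
        """With all true means equal, the fraction of datasets split at all
        should track the nominal level."""
        rng = np.random.default_rng(8)
        alpha, n_sim, k, r = 0.05, 800, 5, 5
        splits = 0
        for _ in range(n_sim):
            data = {f"t{i}": list(rng.normal(0.0, 1.0, size=r)) for i in range(k)}
            an = one_way_anova(obs_from_groups(data), "tomato", "rdw")
            splits += len(scott_knott(an, alpha).clusters) > 1
        rate = splits / n_sim
        assert abs(rate - alpha) < 0.025  # ~3 MC sigma


class TestPearson:
    def test_perfect_linear_relation(self):
        r, p = pearson([1, 2, 3, 4], [3, 5, 7, 9])
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_orthogonal_residual_gives_zero(self):
        r, _ = pearson([1, 2, 3], [1, 0, 1])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        r, _ = pearson([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])
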