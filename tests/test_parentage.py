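"""Parentage assignment: LOD likelihoods against a brute-force enumeration
oracle, maternal verification, the simulated delta criterion, sibship
clustering, contamination flags, and the equal-contribution test."""

import numpy as np
import pandas as pd
import pytest

from polygs import kinship, parentage, simpop
from polygs.datatypes import MISSING, GenotypeMatrix, RelationshipMatrix


def brute_force_lod(off, dam, sire, error_rate, freqs):
    """Independent oracle: enumerate transmitted-allele combinations."""
    total = 0.0
    for go, gd, gs, p in zip(off, dam, sire, freqs):
        # P(offspring genotype | parents) by explicit gamete enumeration
        t = 0.0
        pd_ = [1 - gd / 2, gd / 2] if gd != 1 else [0.5, 0.5]
        ps_ = [1 - gs / 2, gs / 2] if gs != 1 else [0.5, 0.5]
        pd_ = [[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]][gd]
        ps_ = [[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]][gs]
        for ad in (0, 1):
            for as_ in (0, 1):
                if ad + as_ == go:
                    t += pd_[ad] * ps_[as_]
        hw = [(1 - p) ** 2, 2 * p * (1 - p), p**2][go]
        num = (1 - error_rate) * t + error_rate * hw
        total += np.log(num) - np.log(hw)
    return total


class TestPairLikelihood:
    def test_exclusion_is_minus_infinity(self):
        lod = parentage.pair_likelihood(
            np.array([2]), np.array([0]), np.array([0]), 0.0, np.array([0.4])
        )
        assert lod == -np.inf

    def test_matches_enumeration_oracle_on_toy(self):
        freqs = np.array([0.3, 0.45, 0.12])
        off = np.array([1, 2, 0])
        dam = np.array([1, 1, 0])
        sire = np.array([2, 1, 1])
        for e in (0.0, 0.02, 0.1):
            got = parentage.pair_likelihood(off, dam, sire, e, freqs)
            want = brute_force_lod(off, dam, sire, e, freqs)
            assert got == pytest.approx(want, rel=1e-12)

    def test_exact_match_dominates(self):
        rng = np.random.default_rng(2)
        freqs = rng.uniform(0.2, 0.5, size=120)
        truth = rng.binomial(2, freqs).astype(np.int8)
        # offspring identical to a selfed parent: beats any competing pair
        competitors = rng.binomial(2, freqs, size=(6, 120)).astype(np.int8)
        lod_self = parentage.pair_likelihood(truth, truth, truth, 0.02, freqs)
        for comp in competitors:
            assert lod_self > parentage.pair_likelihood(truth, comp, comp, 0.02, freqs)

    def test_missing_loci_skipped(self):
        freqs = np.array([0.3, 0.4])
        off = np.array([1, MISSING])
        lod = parentage.pair_likelihood(off, np.array([1, 0]), np.array([1, 0]), 0.0, freqs)
        one = parentage.pair_likelihood(np.array([1]), np.array([1]), np.array([1]), 0.0, freqs[:1])
        assert np.isfinite(lod)

    def test_true_parent_never_excluded_at_zero_error(self, small_polycross):
        parents, offspring, ped = small_polycross
        freqs = parentage.floor_freqs(offspring.allele_freqs(), offspring.n_individuals)
        prow = {i: parents.calls[k] for k, i in enumerate(parents.ids)}
        for k in range(0, offspring.n_individuals, 9):
            oid = offspring.ids[k]
            lod = parentage.pair_likelihood(
                offspring.calls[k], prow[ped.dam[oid]], prow[ped.sire[oid]], 0.0, freqs
            )
            assert np.isfinite(lod)


class TestVerifyMothers:
    def test_zero_error_all_confirmed(self, small_polycross):
        parents, offspring, ped = small_polycross
        mothers = parents.subset(ids=[f"M{k + 1:03d}" for k in range(12)])
        expected = {o: ped.dam[o] for o in offspring.ids}
        res = parentage.verify_mothers(offspring, mothers, expected, error_rate=0.0)
        assert (res.table["status"] == "confirmed").all()
        assert (res.table["assigned_dam"] == [ped.dam[o] for o in offspring.ids]).all()

    def test_high_mismatch_not_confirmed(self):
        rng = np.random.default_rng(3)
        freqs = np.full(200, 0.5)
        mother = rng.binomial(2, freqs).astype(np.int8)
        off = mother.copy()
        hom = np.where(mother != 1)[0][:6]  # 3% opposite homozygotes
        off[hom] = 2 - off[hom]
        mg = GenotypeMatrix(["mom"], [f"s{j}" for j in range(200)], mother[None, :])
        og = GenotypeMatrix(["kid"], [f"s{j}" for j in range(200)], off[None, :])
        res = parentage.verify_mothers(og, mg, {"kid": "mom"}, error_rate=0.02,
                                       mismatch_cut=0.025)
        assert res.table["status"].iloc[0] != "confirmed"

    def test_foreign_mother_unassigned(self, small_polycross):
        parents, offspring, ped = small_polycross
        mothers = parents.subset(ids=[f"M{k + 1:03d}" for k in range(12)])
        rng = np.random.default_rng(4)
        foreign = rng.binomial(2, 0.4, size=(1, offspring.n_snps)).astype(np.int8)
        kid = np.array([rng.binomial(1, f / 2) + rng.binomial(1, 0.4) for f in foreign[0]],
                       dtype=np.int8)
        og = GenotypeMatrix(["alien"], list(offspring.snp_ids), kid[None, :])
        res = parentage.verify_mothers(og, mothers, {}, error_rate=0.0)
        assert res.table["status"].iloc[0] == "unassigned"


class TestDeltaThreshold:
    def test_zero_error_fully_genotyped_limit(self, small_polycross):
        parents, offspring, _ = small_polycross
        fathers = parents.subset(ids=parents.ids[-6:])
        freqs = offspring.allele_freqs()
        thr = parentage.estimate_delta_threshold(
            fathers, freqs, n_simulated=800, error_rate=0.0,
            sampled_fraction=1.0, seed=0,
        )
        assert thr.critical_delta == 0.0

    def test_reproducible_across_seeds(self, small_polycross):
        parents, offspring, _ = small_polycross
        # few markers + error so the threshold is non-trivial
        fathers = parents.subset(ids=parents.ids[-6:], snp_ids=parents.snp_ids[:40])
        freqs = offspring.allele_freqs()[:40]
        thrs = [
            parentage.estimate_delta_threshold(
                fathers, freqs, n_simulated=6000, error_rate=0.05,
                sampled_fraction=0.5, seed=s,
            ).critical_delta
            for s in (1, 2, 3)
        ]
        centre = np.mean(thrs)
        assert centre > 0
        assert np.all(np.abs(np.array(thrs) - centre) <= 0.10 * centre + 0.3)

    def test_needs_two_candidates(self):
        g = GenotypeMatrix(["f1"], ["s0"], np.array([[1]], dtype=np.int8))
        with pytest.raises(ValueError, match="two candidate"):
            parentage.estimate_delta_threshold(g, np.array([0.5]))


class TestAssignPaternity:
    def test_identical_twin_fathers_tie_never_assigned(self):
        rng = np.random.default_rng(5)
        m = 150
        freqs = np.full(m, 0.4)
        dam = rng.binomial(2, freqs).astype(np.int8)
        twin = rng.binomial(2, freqs).astype(np.int8)
        kid = (
            np.array([rng.integers(0, 2) if g == 1 else g // 2 for g in dam])
            + np.array([rng.integers(0, 2) if g == 1 else g // 2 for g in twin])
        ).astype(np.int8)
        snps = [f"s{j}" for j in range(m)]
        fathers = GenotypeMatrix(["fa", "fb"], snps, np.vstack([twin, twin]))
        dams = GenotypeMatrix(["mom"], snps, dam[None, :])
        off = GenotypeMatrix(["kid"], snps, kid[None, :])
        thr = parentage.DeltaThreshold(0.0, 0.95, 0, 0.0, 1.0)
        res = parentage.assign_paternity(off, fathers, {"kid": "mom"}, dams, thr,
                                         allele_freqs=freqs)
        assert res.table["assigned_sire"].iloc[0] is None
        assert res.table["delta"].iloc[0] == 0.0

    def test_order_invariance(self, small_polycross):
        parents, offspring, ped = small_polycross
        fathers = parents.subset(ids=parents.ids[-6:])
        mothers = parents.subset(ids=[f"M{k + 1:03d}" for k in range(12)])
        dams = {o: ped.dam[o] for o in offspring.ids}
        freqs = offspring.allele_freqs()
        thr = parentage.DeltaThreshold(0.0, 0.95, 0, 0.0, 1.0)
        fwd = parentage.assign_paternity(offspring, fathers, dams, mothers, thr,
                                         allele_freqs=freqs)
        rev_ids = list(reversed(offspring.ids))
        rev = parentage.assign_paternity(offspring.subset(ids=rev_ids), fathers,
                                         dams, mothers, thr, allele_freqs=freqs)
        merged = fwd.table.set_index("id").join(rev.table.set_index("id"),
                                                lsuffix="_f", rsuffix="_r")
        assert (merged["assigned_sire_f"].fillna("-") == merged["assigned_sire_r"].fillna("-")).all()


class TestClustering:
    def _relatedness(self, offspring):
        return kinship.build_G(offspring)

    def test_recovers_ungenotyped_father_families(self):
        cfg = simpop.SimConfig(
            n_mothers=10, n_polymix_fathers=8, n_shared_parents=0,
            offspring_per_mother=16, n_snp=700, seed=41,
            contamination_rate=0.0, genotyping_error_rate=0.0, missing_rate=0.0,
            male_skew=np.inf,
        )
        parents = simpop.simulate_parents(cfg)
        off, ped = simpop.simulate_polycross(parents, cfg)
        clusters = parentage.cluster_unassigned_sires(
            off.ids, self._relatedness(off), mother_of=ped.dam
        )
        big = {k: v for k, v in clusters.items() if len(v) >= 10}
        assert len(big) == cfg.n_polymix_fathers
        # each recovered cluster is sire-pure
        for members in big.values():
            assert len({ped.sire[o] for o in members}) == 1

    def test_singleton(self):
        K = RelationshipMatrix(["a"], np.array([[1.0]]), "G")
        clusters = parentage.cluster_unassigned_sires(["a"], K)
        assert clusters == {"c_1": ["a"]}

    def test_all_full_sibs_one_cluster(self):
        n = 8
        vals = np.full((n, n), 0.5)
        np.fill_diagonal(vals, 1.0)
        K = RelationshipMatrix([f"i{k}" for k in range(n)], vals, "G")
        clusters = parentage.cluster_unassigned_sires([f"i{k}" for k in range(n)], K)
        assert len(clusters) == 1


class TestFlagContaminants:
    def test_boundary_size(self):
        clusters = {"c_1": [f"o{k}" for k in range(6)], "c_2": [f"p{k}" for k in range(20)]}
        res = parentage.flag_contaminants(clusters, min_family_size=7)
        by_id = res.table.set_index("id")
        assert (by_id.loc[[f"o{k}" for k in range(6)], "status"] == "contaminant").all()
        assert (by_id.loc[[f"p{k}" for k in range(20)], "status"] == "clustered_unknown_sire").all()

    def test_zero_contamination_simulation_clean(self, small_polycross):
        _, offspring, ped = small_polycross
        g = kinship.build_G(offspring)
        clusters = parentage.cluster_unassigned_sires(offspring.ids, g, mother_of=ped.dam)
        smallest_true = min(
            np.bincount(pd.factorize(pd.Series([ped.sire[o] for o in offspring.ids]))[0])
        )
        res = parentage.flag_contaminants(clusters, min_family_size=min(smallest_true, 7))
        assert not (res.table["status"] == "contaminant").any()


class TestEqualContribution:
    def test_equal_counts(self):
        chi2, p = parentage.test_equal_contribution([20, 20, 20])
        assert chi2 == 0.0 and p == 1.0

    def test_hand_arithmetic(self):
        chi2, p = parentage.test_equal_contribution({"a": 10, "b": 30})
        assert chi2 == pytest.approx(10.0)  # (10-20)^2/20 + (30-20)^2/20

    def test_requires_two_fathers(self):
        with pytest.raises(ValueError):
            parentage.test_equal_contribution([5])
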