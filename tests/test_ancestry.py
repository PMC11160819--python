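"""Reference PCA, OADP projection, and most-similar-population assignment."""

import numpy as np
import pytest

from oracles import full_pca_projection_oracle
from pgskit.ancestry import (
    AncestryError,
    ReferencePanel,
    aligned_target_dosages,
    assign_population,
    assign_populations,
    fit_reference_pca,
    overlap_variants,
    project_naive,
    project_oadp,
    project_samples,
    prune_ld,
    standardize_sample,
)
from pgskit.genotypes import GenotypeBlock, TargetVariant
from pgskit.simulate import SimulationConfig, simulate_panel


def _panel(variants, dosages):
    n = dosages.shape[0]
    ids = [f"r{i}" for i in range(n)]
    labels = {sid: ("A" if i < n // 2 else "B") for i, sid in enumerate(ids)}
    return ReferencePanel(
        block=GenotypeBlock(ids, variants, dosages), labels=labels
    )


class TestOverlap:
    def _variants(self):
        return [
            TargetVariant("1", 10, "A", ("G",)),
            TargetVariant("1", 20, "C", ("T",)),
            TargetVariant("1", 30, "A", ("T",)),  # palindromic
            TargetVariant("1", 40, "G", ("C",)),  # palindromic
            TargetVariant("2", 10, "T", ("C",)),
        ]

    def test_identical_lists_full_overlap_minus_palindromes(self):
        variants = self._variants()
        panel = _panel(variants, np.ones((6, 5)))
        target = GenotypeBlock(["t1"], variants, np.zeros((1, 5)))
        ov = overlap_variants(panel, target, min_count=1)
        assert len(ov) == 3
        assert not ov.flip_target.any()

    def test_disjoint_lists_error(self):
        panel = _panel(self._variants(), np.ones((6, 5)))
        target = GenotypeBlock(
            ["t1"], [TargetVariant("9", 99, "A", ("G",))], np.zeros((1, 1))
        )
        with pytest.raises(AncestryError, match="overlap"):
            overlap_variants(panel, target, min_count=1)

    def test_allele_swap_reflects_target_dosage(self):
        variants = self._variants()
        panel = _panel(variants, np.ones((6, 5)))
        swapped = [
            TargetVariant("1", 10, "G", ("A",)),  # ref/alt exchanged
            TargetVariant("1", 20, "C", ("T",)),
        ]
        target = GenotypeBlock(["t1"], swapped, np.array([[0.5, 1.5]]))
        ov = overlap_variants(panel, target, min_count=1)
        assert len(ov) == 2
        assert ov.flip_target.tolist() == [True, False]
        aligned = aligned_target_dosages(target, ov)
        assert aligned.tolist() == [[1.5, 1.5]]

    def test_strand_flipped_pair_reconciled(self):
        panel = _panel(self._variants(), np.ones((6, 5)))
        # revcomp of A/G is T/C: same variant read off the other strand
        flipped = [TargetVariant("1", 10, "T", ("C",))]
        target = GenotypeBlock(["t1"], flipped, np.array([[2.0]]))
        ov = overlap_variants(panel, target, min_count=1)
        assert len(ov) == 1 and not ov.flip_target[0]


class TestPruneLd:
    def test_perfectly_correlated_pair_drops_later(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, size=100).astype(float)
        dosages = np.column_stack([x, x, rng.integers(0, 3, size=100)])
        kept = prune_ld(dosages)
        assert kept.tolist() == [0, 2]

    def test_independent_variants_mostly_kept(self):
        """Balding-Nichols draws have no LD, so with weak structure almost
        nothing prunes (strong structure induces real between-variant
        correlation, which pruning is supposed to remove)."""
        sim = simulate_panel(
            SimulationConfig(
                n_pops=2, fst=1e-3, n_ref_per_pop=150, n_target_per_pop=2,
                m_variants=500, seed=13,
            )
        )
        dosages = sim.panel.block.dosages
        kept = prune_ld(dosages)
        assert len(kept) > 0.95 * dosages.shape[1]

    def test_vacuous_threshold_drops_nothing(self):
        rng = np.random.default_rng(2)
        dosages = rng.integers(0, 3, size=(50, 20)).astype(float)
        assert len(prune_ld(dosages, r2_threshold=1.0)) == 20


def _fit(sim, K):
    block = sim.panel.block
    keys = [(v.chrom, v.pos, v.ref, v.alt) for v in block.variants]
    return fit_reference_pca(block, keys, K=K)


class TestReferencePca:
    def test_pc1_separates_two_populations(self, two_pop_sim):
        from sklearn.metrics import silhouette_score

        model = _fit(two_pop_sim, K=2)
        labels = [two_pop_sim.panel.labels[s] for s in model.sample_ids]
        score = silhouette_score(model.ref_coords[:, :1], labels)
        assert score > 0.5

    def test_loadings_orthonormal_and_coords_uncorrelated(self, two_pop_sim):
        model = _fit(two_pop_sim, K=4)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)
        cov = model.ref_coords.T @ model.ref_coords
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(cov)).max()

    def test_refit_is_identical_no_sign_flip(self, two_pop_sim):
        a, b = _fit(two_pop_sim, K=3), _fit(two_pop_sim, K=3)
        np.testing.assert_array_equal(a.loadings, b.loadings)
        np.testing.assert_array_equal(a.ref_coords, b.ref_coords)
        for k in range(3):
            j = np.argmax(np.abs(a.loadings[:, k]))
            assert a.loadings[j, k] > 0

    def test_k_beyond_rank_errors(self):
        sim = simulate_panel(
            SimulationConfig(
                n_pops=2, n_ref_per_pop=3, n_target_per_pop=2, m_variants=50, seed=9
            )
        )
        with pytest.raises(AncestryError, match="rank"):
            _fit(sim, K=30)

    def test_save_load_round_trip(self, two_pop_sim, tmp_path):
        model = _fit(two_pop_sim, K=3)
        model.save(tmp_path / "model.npz")
        from pgskit.ancestry import PCAModel

        back = PCAModel.load(tmp_path / "model.npz")
        np.testing.assert_array_equal(back.loadings, model.loadings)
        np.testing.assert_array_equal(back.ref_coords, model.ref_coords)
        assert back.variant_keys == model.variant_keys
        assert back.sample_ids == model.sample_ids


class TestProjection:
    def test_naive_zero_vector_projects_to_origin(self, two_pop_sim):
        model = _fit(two_pop_sim, K=3)
        proj = project_naive(model, np.zeros(model.loadings.shape[0]))
        np.testing.assert_array_equal(proj.coords, np.zeros(3))

    def test_naive_reference_sample_at_full_rank_reproduces_coords(self):
        # variants < samples: the loadings span the full variant space
        sim = simulate_panel(
            SimulationConfig(
                n_pops=2, n_ref_per_pop=50, n_target_per_pop=5, m_variants=30, seed=31
            )
        )
        block = sim.panel.block
        keys = [(v.chrom, v.pos, v.ref, v.alt) for v in block.variants]
        full = fit_reference_pca(block, keys, K=int(np.linalg.matrix_rank(
            fit_reference_pca(block, keys, K=2).ref_std
        )))
        for i in (0, 17, 63):
            proj = project_naive(full, full.ref_std[i])
            np.testing.assert_allclose(proj.coords, full.ref_coords[i], atol=1e-8)

    def test_oadp_duplicate_of_reference_sample(self, small_sim):
        """A sample identical to a reference sample matches the full-refit
        oracle to numerical precision and lands close to that sample's own
        reference coordinates (exact only at full rank, since the extra row
        perturbs a truncated subspace)."""
        model = _fit(small_sim, K=2)
        for i in (0, 45, 100):
            z = model.ref_std[i]
            proj = project_oadp(model, z)
            oracle = full_pca_projection_oracle(model, z)
            np.testing.assert_allclose(proj.coords, oracle, atol=1e-6)
            rel = np.linalg.norm(proj.coords - model.ref_coords[i]) / np.linalg.norm(
                model.ref_coords[i]
            )
            assert rel < 0.15

    def test_oadp_beats_naive_against_full_refit_oracle(self, two_pop_sim):
        """Held-out samples: OADP coordinates are closer to the full-PCA
        refit oracle than shrinkage-biased naive coordinates."""
        model = _fit(two_pop_sim, K=2)
        target = two_pop_sim.target
        ov_cols = target.dosages  # same variants, same orientation
        d_oadp, d_naive = [], []
        for i in range(20):
            raw = ov_cols[i][model.kept_mask]
            z = standardize_sample(model, raw)
            oracle = full_pca_projection_oracle(model, z)
            d_oadp.append(np.linalg.norm(project_oadp(model, z).coords - oracle))
            d_naive.append(np.linalg.norm(project_naive(model, z).coords - oracle))
        assert np.mean(d_oadp) < np.mean(d_naive)
        # naive projections shrink toward the origin relative to OADP
        norms_naive = [
            np.linalg.norm(project_naive(model, standardize_sample(model, ov_cols[i][model.kept_mask])).coords)
            for i in range(20)
        ]
        norms_oadp = [
            np.linalg.norm(project_oadp(model, standardize_sample(model, ov_cols[i][model.kept_mask])).coords)
            for i in range(20)
        ]
        assert np.mean(norms_naive) < np.mean(norms_oadp)

    def test_full_rank_oadp_naive_oracle_agree(self):
        sim = simulate_panel(
            SimulationConfig(
                n_pops=2, n_ref_per_pop=50, n_target_per_pop=10, m_variants=30, seed=41
            )
        )
        block = sim.panel.block
        keys = [(v.chrom, v.pos, v.ref, v.alt) for v in block.variants]
        probe = fit_reference_pca(block, keys, K=2)
        rank = int(np.linalg.matrix_rank(probe.ref_std))
        model = fit_reference_pca(block, keys, K=rank)
        for i in range(5):
            raw = sim.target.dosages[i][model.kept_mask]
            z = standardize_sample(model, raw)
            oracle = full_pca_projection_oracle(model, z)
            np.testing.assert_allclose(project_oadp(model, z).coords, oracle, atol=1e-6)
            np.testing.assert_allclose(project_naive(model, z).coords, oracle, atol=1e-6)


class TestAssignment:
    def test_centroid_has_zero_distance(self, two_pop_sim):
        model = _fit(two_pop_sim, K=2)
        labels = two_pop_sim.panel.labels
        idx = [i for i, s in enumerate(model.sample_ids) if labels[s] == "POP1"]
        centroid = model.ref_coords[idx].mean(axis=0)
        from pgskit.ancestry import Projection

        assign = assign_population(
            Projection("x", centroid, "naive"), model, labels
        )
        assert assign.most_similar_pop == "POP1"
        assert assign.distances["POP1"] == pytest.approx(0.0, abs=1e-9)

    def test_exact_tie_breaks_lexicographically(self):
        rng = np.random.default_rng(3)
        coords2 = rng.normal(size=(12, 2))
        from pgskit.ancestry import PCAModel, Projection

        # two mirror-image populations around the origin
        ref = np.vstack([coords2, -coords2])
        ids = [f"r{i}" for i in range(24)]
        labels = {sid: ("ZPOP" if i < 12 else "APOP") for i, sid in enumerate(ids)}
        model = PCAModel(
            variant_keys=[("1", i + 1, "A", "G") for i in range(2)],
            mu=np.zeros(2),
            sigma=np.ones(2),
            loadings=np.eye(2),
            ref_coords=ref,
            singular_values=np.ones(2),
            K=2,
            sample_ids=ids,
            ref_std=ref,
            kept_mask=np.ones(2, dtype=bool),
        )
        assign = assign_population(
            Projection("x", np.zeros(2), "naive"), model, labels
        )
        assert assign.most_similar_pop == "APOP"

    def test_mahalanobis_invariant_under_rotation(self, two_pop_sim):
        model = _fit(two_pop_sim, K=3)
        labels = two_pop_sim.panel.labels
        rng = np.random.default_rng(8)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = _fit(two_pop_sim, K=3)
        rotated.ref_coords = model.ref_coords @ Q
        from pgskit.ancestry import Projection

        x = np.array([1.0, -2.0, 0.5])
        a = assign_population(Projection("x", x, "naive"), model, labels)
        b = assign_population(Projection("x", x @ Q, "naive"), rotated, labels)
        for pop in a.distances:
            assert a.distances[pop] == pytest.approx(b.distances[pop], rel=1e-6)

    def test_synthetic_targets_assigned_true_population(self, small_sim):
        model = _fit(small_sim, K=4)
        projs = project_samples(
            model,
            small_sim.target.dosages[:, model.kept_mask],
            small_sim.target.sample_ids,
            method="oadp",
        )
        assigns = assign_populations(projs, model, small_sim.panel.labels)
        correct = sum(
            a.most_similar_pop == small_sim.target_labels[a.sample_id]
            for a in assigns
        )
        assert correct / len(assigns) >= 0.95
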