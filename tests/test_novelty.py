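import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from heterofrag.chem_core import invert_stereocenters, parse_structure
from heterofrag.novelty import (
    BitFingerprint,
    QueryError,
    ScaffoldQuerySet,
    PARENT_SCAFFOLD_SMILES,
    embed_2d,
    fingerprint_matrix,
    morgan_fingerprint,
    nearest_neighbor_report,
    scaffold_filter,
    separation_score,
    tanimoto,
)


def _fp(bit_indices, n_bits=16):
    bits = np.zeros(n_bits, dtype=bool)
    bits[list(bit_indices)] = True
    return BitFingerprint(bits=bits, radius=2)


class TestScaffoldQuerySet:
    def test_diagonal_match_matrix_on_parent_scaffolds(self):
        queries = ScaffoldQuerySet()
        for parent, smiles in PARENT_SCAFFOLD_SMILES.items():
            hits = queries.match(parse_structure(smiles))
            assert hits == {parent}, (parent, hits)

    def test_invalid_smarts_fails_at_load_time(self):
        with pytest.raises(QueryError, match="SMARTS"):
            ScaffoldQuerySet(smarts={"broken": "C1CC("}, validate_parents=False)

    def test_pattern_missing_its_parent_rejected(self):
        bad = dict(ScaffoldQuerySet().smarts)
        bad["piperidine"] = "[#7X3]1[CX4][CX4][CX4][CX4]1"  # pyrrolidine-sized
        with pytest.raises(QueryError):
            ScaffoldQuerySet(smarts=bad)


class TestScaffoldFilter:
    def test_piperidine_matches_piperidine_only(self):
        [(mol, hits)] = scaffold_filter([parse_structure("C1CCNCC1")])
        assert hits == {"piperidine"}

    def test_benzene_excluded(self):
        assert scaffold_filter([parse_structure("c1ccccc1")]) == []

    def test_synthesized_n_heterocycles_match_their_design_scaffold(self, design_library):
        """Brute-force check over the 38 synthesized N-heterocycle fragments:
        each matches the ring motif its design declares."""
        synth = design_library.subset(
            status="synthesized", scaffolds=("pyrrolidine", "piperidine")
        )
        assert len(synth) == 38
        for design in synth.designs:
            [(_, hits)] = scaffold_filter([synth.molecules[design.frag_id]])
            assert design.scaffold in hits, design.frag_id

    def test_order_preserved(self):
        mols = [
            parse_structure("C1CCNCC1", id="a"),
            parse_structure("c1ccccc1", id="b"),
            parse_structure("C1CCNC1", id="c"),
        ]
        kept = [m.id for m, _ in scaffold_filter(mols)]
        assert kept == ["a", "c"]


class TestMorganFingerprint:
    def test_deterministic_for_same_structure(self):
        a = morgan_fingerprint(parse_structure("OC(=O)C1CCNCC1"))
        b = morgan_fingerprint(parse_structure("C1CC(C(O)=O)CCN1"))  # same molecule
        assert np.array_equal(a.bits, b.bits)

    def test_methane_radius_zero_single_environment(self):
        fp = morgan_fingerprint(parse_structure("C"), radius=0)
        assert fp.n_set == 1

    def test_enantiomers_hash_identically(self, chiral_pool):
        for mol in chiral_pool[:25]:
            a = morgan_fingerprint(mol)
            b = morgan_fingerprint(invert_stereocenters(mol))
            assert np.array_equal(a.bits, b.bits)

    def test_chirality_flag_can_distinguish_enantiomers(self):
        mol = parse_structure("N[C@@H](C)C(=O)O")
        ent = invert_stereocenters(mol)
        a = morgan_fingerprint(mol, chirality=True)
        b = morgan_fingerprint(ent, chirality=True)
        assert not np.array_equal(a.bits, b.bits)

    @pytest.mark.parametrize("n_bits", [0, -5])
    def test_invalid_width_rejected(self, n_bits):
        with pytest.raises(ValueError):
            morgan_fingerprint(parse_structure("C"), n_bits=n_bits)


class TestTanimoto:
    def test_worked_example(self):
        assert tanimoto(_fp({0, 1, 2}), _fp({1, 2, 3})) == 0.5  # 2 / 4

    def test_identical_nonempty_is_one(self):
        assert tanimoto(_fp({3, 7}), _fp({3, 7})) == 1.0

    def test_disjoint_is_zero(self):
        assert tanimoto(_fp({0}), _fp({1})) == 0.0

    def test_empty_pair_convention(self):
        assert tanimoto(_fp(set()), _fp(set())) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            tanimoto(_fp({0}, n_bits=16), _fp({0}, n_bits=32))

    @given(
        a=st.sets(st.integers(0, 63), max_size=40),
        b=st.sets(st.integers(0, 63), max_size=40),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetry_bounds_identity(self, a, b):
        fa, fb = _fp(a, 64), _fp(b, 64)
        s = tanimoto(fa, fb)
        assert 0.0 <= s <= 1.0
        assert s == tanimoto(fb, fa)
        assert (s == 1.0) == (a == b)


class TestNearestNeighborReport:
    def test_query_present_in_references_has_zero_novelty(self):
        fp = _fp({1, 2, 3})
        [report] = nearest_neighbor_report([fp], [_fp({5}), fp])
        assert report.max_tanimoto == 1.0 and report.novelty == 0.0

    def test_single_disjoint_reference_full_novelty(self):
        [report] = nearest_neighbor_report([_fp({0, 1})], [_fp({8, 9})])
        assert report.novelty == 1.0

    def test_matches_pairwise_tanimoto(self):
        rng = np.random.default_rng(3)
        queries = [_fp(set(rng.choice(64, 10)), 64) for _ in range(5)]
        refs = [_fp(set(rng.choice(64, 10)), 64) for _ in range(9)]
        reports = nearest_neighbor_report(queries, refs)
        for q, rep in zip(queries, reports):
            assert rep.max_tanimoto == pytest.approx(
                max(tanimoto(q, r) for r in refs)
            )

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            nearest_neighbor_report([_fp({0})], [])

    def test_synthesized_more_novel_than_held_out_decoys(
        self, synthesized_molecules, decoy_benchmark
    ):
        """The collection's mean novelty vs motif-matched decoys exceeds the
        decoy-vs-decoy held-out baseline."""
        _, decoys = decoy_benchmark
        matched = [m for m, _ in scaffold_filter(decoys)]
        rfp = [morgan_fingerprint(m) for m in matched]
        qfp = [morgan_fingerprint(m) for m in synthesized_molecules]
        half = len(rfp) // 2
        synth_novelty = np.mean(
            [r.novelty for r in nearest_neighbor_report(qfp, rfp[half:])]
        )
        decoy_novelty = np.mean(
            [r.novelty for r in nearest_neighbor_report(rfp[:half], rfp[half:])]
        )
        assert synth_novelty > decoy_novelty


class TestEmbed2D:
    def test_pca_equidistant_triple_stays_equilateral(self):
        fps = [_fp({0}, 8), _fp({1}, 8), _fp({2}, 8)]
        emb = embed_2d(fps, method="pca")
        d = [
            np.linalg.norm(emb.coords[i] - emb.coords[j])
            for i, j in ((0, 1), (0, 2), (1, 2))
        ]
        assert max(d) - min(d) < 1e-9

    def test_pca_duplicates_get_identical_coordinates(self):
        fps = [_fp({0, 1}, 8), _fp({0, 1}, 8), _fp({2}, 8), _fp({3, 4}, 8)]
        emb = embed_2d(fps, method="pca")
        assert np.allclose(emb.coords[0], emb.coords[1])

    def test_pca_deterministic(self, synthesized_molecules):
        fps = [morgan_fingerprint(m) for m in synthesized_molecules]
        a = embed_2d(fps, method="pca")
        b = embed_2d(fps, method="pca")
        assert np.array_equal(a.coords, b.coords)

    def test_too_few_points_error_names_minimum(self):
        with pytest.raises(ValueError, match="3"):
            embed_2d([_fp({0}), _fp({1})], method="pca")
        with pytest.raises(ValueError, match="n_neighbors"):
            embed_2d([_fp({i}) for i in range(5)], method="umap", n_neighbors=15)

    def test_umap_reproducible_for_fixed_seed(self, synthesized_molecules, decoy_benchmark):
        """Same inputs and seed reproduce UMAP coordinates within 1e-6 after
        Procrustes alignment (rotation/reflection freedom allowed)."""
        from scipy.spatial import procrustes

        _, decoys = decoy_benchmark
        fps = [morgan_fingerprint(m) for m in synthesized_molecules + decoys[:80]]
        a = embed_2d(fps, method="umap", seed=42)
        b = embed_2d(fps, method="umap", seed=42)
        assert a.metric == "jaccard" and a.seed == 42
        _, _, disparity = procrustes(a.coords, b.coords)
        assert disparity < 1e-6


class TestSeparationScore:
    def test_two_tight_groups_score_near_one(self):
        coords = np.array([[0.0, 0.0], [0.01, 0.0], [10.0, 10.0], [10.01, 10.0]])
        emb = _embedding(coords)
        assert separation_score(emb, ["a", "a", "b", "b"]) > 0.95

    def test_coincident_groups_score_nonpositive(self):
        coords = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 0.0], [1.0, 1.0]])
        emb = _embedding(coords)
        assert separation_score(emb, ["a", "a", "b", "b"]) <= 0.0

    def test_random_label_permutation_baseline_near_zero(self):
        """Mean silhouette over 100 label shuffles is ~0: the score detects
        structure, not label bookkeeping."""
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(60, 2))
        emb = _embedding(coords)
        labels = np.array(["a"] * 30 + ["b"] * 30)
        scores = []
        for _ in range(100):
            scores.append(separation_score(emb, rng.permutation(labels)))
        assert abs(np.mean(scores)) < 0.05

    def test_degenerate_labeling_rejected(self):
        emb = _embedding(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            separation_score(emb, ["a", "a", "a"])
        with pytest.raises(ValueError):
            separation_score(emb, ["a", "a", "b"])


def _embedding(coords):
    from heterofrag.novelty import Embedding2D

    return Embedding2D(
        coords=np.asarray(coords, float), method="pca", metric="euclidean",
        seed=0, params={},
    )
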