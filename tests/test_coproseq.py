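"""Community profiling: informative sizes, read assignment, quantification,
PoMA, ordination — each against an independent oracle where one exists."""

import numpy as np
import pandas as pd
import pytest

from defcom import coproseq as cp
from defcom import synthetic as syn
from defcom.synthetic import CommunityGenomeSet, SpeciesGenome, revcomp


def _gset(seqs: dict[str, str]) -> CommunityGenomeSet:
    return CommunityGenomeSet(
        species={sid: SpeciesGenome(sid, seq, []) for sid, seq in seqs.items()}
    )


def brute_force_informative_sizes(seqs: dict[str, str], k: int) -> dict[str, int]:
    """Dictionary-count oracle: canonical k-mer occurrence counting."""
    counts: dict[str, int] = {}
    for seq in seqs.values():
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            km = min(km, revcomp(km))
            counts[km] = counts.get(km, 0) + 1
    out = {}
    for sid, seq in seqs.items():
        out[sid] = sum(
            1
            for i in range(len(seq) - k + 1)
            if counts[min(seq[i : i + k], revcomp(seq[i : i + k]))] == 1
        )
    return out


def brute_force_assign(reads, seqs: dict[str, str]):
    """Exhaustive substring-scan oracle for read assignment."""
    unique = {sid: 0 for sid in seqs}
    ambiguous = unassigned = 0
    for r in reads.reads:
        hits = [
            sid for sid, s in seqs.items() if r in s or revcomp(r) in s
        ]
        if len(hits) == 0:
            unassigned += 1
        elif len(hits) == 1:
            unique[hits[0]] += 1
        else:
            ambiguous += 1
    return unique, ambiguous, unassigned


class TestInformativeSizes:
    def test_identical_genomes_have_zero_informative_size(self):
        seq = "ACGTACGGTTACGATCGATCGGATC"
        g = _gset({"a": seq, "b": seq})
        sizes = cp.compute_informative_sizes(g, 5)
        assert sizes.to_dict() == {"a": 0, "b": 0}

    def test_all_distinct_kmers_give_full_length(self):
        # de Bruijn-ish fragment with all distinct canonical 5-mers
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 60))
        g = _gset({"solo": seq})
        sizes = cp.compute_informative_sizes(g, 5)
        expected = brute_force_informative_sizes({"solo": seq}, 5)["solo"]
        assert sizes["solo"] == expected
        if expected == len(seq) - 4:  # the all-distinct case
            assert sizes["solo"] == len(seq) - 5 + 1

    def test_three_genome_set_matches_hash_map_oracle(self, toy_genomes):
        seqs = {sid: sp.sequence for sid, sp in toy_genomes.species.items()}
        sizes = cp.compute_informative_sizes(toy_genomes, 5)
        assert sizes.to_dict() == brute_force_informative_sizes(seqs, 5)

    def test_k_larger_than_genome_rejected(self):
        g = _gset({"a": "ACGTACGT"})
        with pytest.raises(ValueError, match="exceeds"):
            cp.compute_informative_sizes(g, 9)

    def test_size_bounded_by_positions(self, toy_genomes):
        k = 25
        sizes = cp.compute_informative_sizes(toy_genomes, k)
        for sid, sp in toy_genomes.species.items():
            assert 0 <= sizes[sid] <= len(sp.sequence) - k + 1


class TestAssignReads:
    def test_mixed_reads_match_substring_scan_oracle(self, shared_block_genomes):
        reads = syn.simulate_shotgun_reads(
            shared_block_genomes,
            {"sp01": 0.5, "sp02": 0.3, "sp03": 0.2},
            1000,
            read_length=25,
            seed=21,
        )
        res = cp.assign_reads(reads, shared_block_genomes)
        seqs = {sid: sp.sequence for sid, sp in shared_block_genomes.species.items()}
        o_unique, o_amb, o_un = brute_force_assign(reads, seqs)
        assert res.unique_counts.to_dict() == o_unique
        assert res.ambiguous == o_amb
        assert res.unassigned == o_un

    def test_conservation_of_read_count(self, shared_block_genomes):
        reads = syn.simulate_shotgun_reads(
            shared_block_genomes,
            {"sp01": 0.4, "sp02": 0.4, "sp03": 0.2},
            500,
            seed=22,
        )
        res = cp.assign_reads(reads, shared_block_genomes)
        assert res.total == 500

    def test_reads_from_shared_block_are_ambiguous(self, shared_block_genomes):
        block = shared_block_genomes.species["sp01"].sequence[:600]
        reads = syn.ReadSet(
            reads=[block[i : i + 25] for i in range(0, 400, 10)],
            read_ids=[f"r{i}" for i in range(40)],
            true_species=["sp01"] * 40,
            read_length=25,
        )
        res = cp.assign_reads(reads, shared_block_genomes)
        assert res.ambiguous == 40
        assert res.unique_counts.sum() == 0

    def test_empty_read_set_is_empty_result(self, toy_genomes):
        reads = syn.ReadSet([], [], [], 25)
        res = cp.assign_reads(reads, toy_genomes)
        assert res.total == 0


class TestQuantify:
    def test_hand_arithmetic(self):
        counts = pd.Series({"a": 100, "b": 100})
        sizes = pd.Series({"a": 1000, "b": 500})
        out = cp.quantify(counts, sizes).set_index("species")
        assert out.at["a", "proportion"] == pytest.approx(100 / 3)
        assert out.at["b", "proportion"] == pytest.approx(200 / 3)

    def test_scale_invariance(self):
        sizes = pd.Series({"a": 800, "b": 800})
        p1 = cp.quantify(pd.Series({"a": 30, "b": 70}), sizes)["proportion"]
        p2 = cp.quantify(pd.Series({"a": 300, "b": 700}), sizes)["proportion"]
        assert np.allclose(p1, p2)

    def test_proportions_sum_to_100(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 1000, size=(4, 5)),
            columns=list("abcde"),
            index=[f"s{i}" for i in range(4)],
        )
        sizes = pd.Series(rng.integers(500, 2000, size=5), index=list("abcde"))
        out = cp.quantify(counts, sizes)
        sums = out.groupby("sample")["proportion"].sum()
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_zero_informative_size_with_reads_flagged(self):
        with pytest.raises(ValueError, match="zero informative size.*'b'"):
            cp.quantify(pd.Series({"a": 10, "b": 5}), pd.Series({"a": 100, "b": 0}))

    def test_recovery_of_design_proportions(self, shared_block_genomes):
        """50/30/20 design recovered within 1% absolute at 1e5 error-free
        reads, despite a fully shared block between sp01 and sp02."""
        true = {"sp01": 0.5, "sp02": 0.3, "sp03": 0.2}
        reads = syn.simulate_shotgun_reads(
            shared_block_genomes, true, 100_000, read_length=25, seed=23
        )
        sizes = cp.compute_informative_sizes(shared_block_genomes, 25)
        res = cp.assign_reads(reads, shared_block_genomes)
        out = cp.quantify(res.unique_counts, sizes).set_index("species")
        for sid, p in true.items():
            assert out.at[sid, "proportion"] == pytest.approx(100 * p, abs=1.0)


class TestPresenceAndPoma:
    @pytest.mark.parametrize(
        "proportion,present",
        [(0.002, False), (0.003, True), (0.0, False), (55.0, True)],
    )
    def test_presence_threshold_boundaries(self, proportion, present):
        table = pd.DataFrame({"proportion": [proportion]})
        assert cp.presence_filter(table)["present"].iloc[0] == present

    def test_poma_hand_arithmetic(self):
        table = pd.DataFrame(
            {
                "animal": ["m1"] * 3,
                "species": ["a"] * 3,
                "day": [1, 2, 3],
                "proportion": [10.0, 40.0, 20.0],
            }
        )
        out = cp.poma(table)
        assert list(out["poma"]) == [25.0, 100.0, 50.0]

    def test_poma_constant_series_all_100(self):
        table = pd.DataFrame(
            {"animal": ["m"] * 3, "species": ["a"] * 3, "day": [1, 2, 3],
             "proportion": [5.0] * 3}
        )
        assert (cp.poma(table)["poma"] == 100.0).all()

    def test_poma_ties_both_100(self):
        table = pd.DataFrame(
            {"animal": ["m"] * 3, "species": ["a"] * 3, "day": [1, 2, 3],
             "proportion": [8.0, 2.0, 8.0]}
        )
        out = cp.poma(table)
        assert list(out["poma"]) == [100.0, 25.0, 100.0]

    def test_poma_rescaling_invariance(self):
        base = pd.DataFrame(
            {"animal": ["m"] * 4, "species": ["a"] * 4, "day": [1, 2, 3, 4],
             "proportion": [1.0, 3.0, 2.0, 4.0]}
        )
        scaled = base.assign(proportion=base["proportion"] * 7.5)
        assert np.allclose(cp.poma(base)["poma"], cp.poma(scaled)["poma"])

    def test_all_zero_series_warns_and_is_nan(self):
        table = pd.DataFrame(
            {"animal": ["m"] * 2, "species": ["a"] * 2, "day": [1, 2],
             "proportion": [0.0, 0.0]}
        )
        with pytest.warns(RuntimeWarning, match="all-zero"):
            out = cp.poma(table)
        assert out["poma"].isna().all()


class TestOrdination:
    def test_orthogonal_samples_distance_sqrt2(self):
        props = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["p", "q"])
        d = cp.hellinger_distances(props)
        assert d.at["p", "q"] == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_identical_samples_coincide(self):
        props = pd.DataFrame(
            [[30, 50, 20], [30, 50, 20], [10, 10, 80]], index=["a", "b", "c"]
        )
        coords, _, _ = cp.hellinger_pcoa(props)
        assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-9)

    def test_gower_property_distances_reproduced(self, rng):
        props = pd.DataFrame(
            rng.dirichlet(np.ones(6), size=8) * 100,
            index=[f"s{i}" for i in range(8)],
        )
        d = cp.hellinger_distances(props).to_numpy()
        coords, _, eigval = cp.hellinger_pcoa(props)
        if (eigval >= -1e-10).all():
            c = coords.to_numpy()
            dc = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(axis=2))
            assert np.allclose(d, dc, atol=1e-8)

    def test_matches_scikit_bio_pcoa(self, rng):
        """Independent oracle: classical PCoA from scikit-bio."""
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.ordination import pcoa

        props = pd.DataFrame(
            rng.dirichlet(np.ones(5), size=7) * 100,
            index=[f"s{i}" for i in range(7)],
        )
        d = cp.hellinger_distances(props)
        ours, pct, _ = cp.hellinger_pcoa(props)
        ref = pcoa(DistanceMatrix(d.to_numpy(), ids=list(props.index)))
        n = min(ours.shape[1], 4)
        for i in range(n):
            a = ours.iloc[:, i].to_numpy()
            b = ref.samples.iloc[:, i].to_numpy()
            # axes are sign-indeterminate
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_too_few_samples_rejected(self):
        props = pd.DataFrame([[1.0, 0.0], [0.5, 0.5]])
        with pytest.raises(ValueError, match="3 samples"):
            cp.hellinger_pcoa(props)


class TestPredictivenessR2:
    def test_identical_vectors_r2_one(self):
        assert cp.predictiveness_r2([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_reversed_vector_perfect_negative(self):
        assert cp.predictiveness_r2([1, 2, 3], [3, 2, 1]) == pytest.approx(1.0)

    def test_null_expectation_one_over_n_minus_one(self, rng):
        n_species, reps = 12, 2000
        vals = [
            cp.predictiveness_r2(rng.random(n_species), rng.random(n_species))
            for _ in range(reps)
        ]
        assert np.mean(vals) == pytest.approx(1 / (n_species - 1), abs=0.02)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            cp.predictiveness_r2([1, 1, 1], [1, 2, 3])
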