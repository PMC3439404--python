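"""Generator correctness: determinism, planted truth, meiosis calibration."""

import numpy as np
import pandas as pd
import pytest

from dartmap import synthetic_data as sd


class TestSimulateGenome:
    def test_deterministic_given_seed(self):
        spec = sd.SyntheticGenomeSpec(
            n_chromosomes=2, chromosome_lengths=[50_000, 60_000],
            n_unanchored_scaffolds=2, gene_density=20.0, seed=5,
        )
        a, b = sd.simulate_genome(spec), sd.simulate_genome(spec)
        assert a.sequences == b.sequences
        pd.testing.assert_frame_equal(a.genes, b.genes)

    def test_zero_gene_density_gives_no_genes(self):
        spec = sd.SyntheticGenomeSpec(
            n_chromosomes=1, chromosome_lengths=[100_000], gene_density=0.0, seed=1
        )
        assert len(sd.simulate_genome(spec).genes) == 0

    def test_gene_count_matches_truth_and_poisson_scale(self):
        spec = sd.SyntheticGenomeSpec(
            n_chromosomes=2, chromosome_lengths=[1_000_000, 1_000_000],
            gene_density=10.0, gene_length_range=(500, 1_500), seed=7,
        )
        genome = sd.simulate_genome(spec)
        n = len(genome.genes)
        # Poisson(20): 4 sd band
        assert abs(n - 20) <= 4 * np.sqrt(20)
        # the annotation is the truth record: declared intervals must be
        # in range and non-overlapping per chromosome
        for chrom, sub in genome.genes.groupby("scaffold"):
            s = sub.sort_values("start")
            assert (s["end"].to_numpy()[:-1] <= s["start"].to_numpy()[1:]).all()

    def test_scaffold_lengths_match_declared(self):
        spec = sd.SyntheticGenomeSpec(
            n_chromosomes=2, chromosome_lengths=[30_000, 40_000],
            n_unanchored_scaffolds=3, unanchored_length_range=(5_000, 9_000), seed=3,
        )
        genome = sd.simulate_genome(spec)
        assert len(genome.sequences["Chr01"]) == 30_000
        assert len(genome.sequences["Chr02"]) == 40_000
        for name in genome.unanchored:
            assert 5_000 <= len(genome.sequences[name]) <= 9_000

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_chromosomes=0),
            dict(chromosome_lengths=[-5], n_chromosomes=1),
            dict(gene_density=-1.0),
            dict(unanchored_length_range=(0, 10)),
        ],
    )
    def test_parameter_errors(self, bad):
        with pytest.raises(sd.ParameterError):
            sd.simulate_genome(sd.SyntheticGenomeSpec(**bad))


class TestPlantProbes:
    def test_zero_redundancy_is_all_singletons(self, small_genome):
        probes = sd.plant_probes(small_genome, n_probes=40, redundancy_rate=0.0, seed=1)
        labels = list(probes.truth_labels().values())
        assert len(set(labels)) == 40

    def test_exact_copy_counts(self, small_genome):
        probes = sd.plant_probes(
            small_genome, n_probes=100, redundancy_rate=0.3, mutation_rate=0.0, seed=2
        )
        truth = probes.truth
        assert int(truth.is_copy.sum()) == 30
        assert len(set(truth.cluster)) == 70
        # byte-identical to the source probe up to orientation
        by_cluster = truth.groupby("cluster")
        for _, members in by_cluster:
            src = members[~members.is_copy].iloc[0]
            for _, copy in members[members.is_copy].iterrows():
                seq = probes.sequences[copy.probe_id]
                if copy.strand == "-":
                    seq = sd.revcomp(seq)
                assert seq == probes.sequences[src.probe_id]

    def test_mutation_rate_hamming_expectation(self, small_genome):
        probes = sd.plant_probes(
            small_genome, n_probes=220, redundancy_rate=0.5, mutation_rate=0.01,
            length_range=(500, 500), seed=3,
        )
        truth = probes.truth.set_index("probe_id")
        by_cluster = probes.truth.groupby("cluster")
        dists = []
        for _, members in by_cluster:
            if len(members) < 2:
                continue
            src_seq = probes.sequences[members[~members.is_copy].iloc[0].probe_id]
            for _, copy in members[members.is_copy].iterrows():
                seq = probes.sequences[copy.probe_id]
                if copy.strand == "-":
                    seq = sd.revcomp(seq)
                dists.append(sum(a != b for a, b in zip(seq, src_seq)))
        assert len(dists) >= 100
        mean = np.mean(dists)
        sd_mean = np.sqrt(500 * 0.01 * 0.99 / len(dists))
        assert abs(mean - 5.0) <= 4 * sd_mean

    def test_length_range_exceeding_scaffold_raises(self, small_genome):
        with pytest.raises(sd.ParameterError):
            sd.plant_probes(small_genome, n_probes=5, length_range=(50_000, 60_000))

    def test_psti_motif_stamped_at_ends(self, small_genome):
        probes = sd.plant_probes(
            small_genome, n_probes=10, redundancy_rate=0.0, seed=9,
            require_psti_motif=True,
        )
        for seq in probes.sequences.values():
            assert seq.startswith("CTGCAG") and seq.endswith("CTGCAG")

    def test_deterministic(self, small_genome):
        a = sd.plant_probes(small_genome, n_probes=30, redundancy_rate=0.2, seed=4)
        b = sd.plant_probes(small_genome, n_probes=30, redundancy_rate=0.2, seed=4)
        assert a.sequences == b.sequences


class TestSimulateCross:
    def test_deterministic(self):
        spec = sd.CrossSimSpec(n_progeny=50, markers_per_chromosome=10, seed=8)
        a = sd.simulate_cross({"Chr01": 5_000_000}, spec)
        b = sd.simulate_cross({"Chr01": 5_000_000}, spec)
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_colocated_markers_identical_vectors(self):
        spec = sd.CrossSimSpec(
            n_progeny=60, markers_per_chromosome=2, fraction_3to1=0.0,
            fraction_codominant=0.0, missing_rate=0.0, error_rate=0.0, seed=13,
        )
        cross = sd.simulate_cross({"Chr01": 1}, spec)  # both markers at bp 0
        assert (cross.truth["cm"] == 0.0).all()
        g = cross.genotypes
        same_parent = (g.iloc[0]["P1"], g.iloc[0]["P2"]) == (g.iloc[1]["P1"], g.iloc[1]["P2"])
        v0, v1 = g.iloc[0, 2:].to_numpy(), g.iloc[1, 2:].to_numpy()
        if same_parent:
            # phases may still differ; vectors are identical or complementary
            assert (v0 == v1).all() or (v0 != v1).all()

    def test_haldane_recombination_closed_form(self):
        rng = np.random.default_rng(31)
        hom = sd.simulate_meioses(np.array([0.0, 10.0]), 5_000, rng)
        observed = float((hom[:, 0] != hom[:, 1]).mean())
        expected = (1 - np.exp(-0.2)) / 2  # 0.0906
        tol = 3 * np.sqrt(expected * (1 - expected) / 5_000)
        assert abs(observed - expected) <= tol

    def test_crossover_calibration(self):
        """Mean observed crossovers per gamete match the planted Morgan length."""
        positions = np.linspace(0.0, 100.0, 201)  # 1 Morgan, dense markers
        rng = np.random.default_rng(17)
        hom = sd.simulate_meioses(positions, 1_000, rng)
        switches = (hom[:, 1:] != hom[:, :-1]).sum(axis=1)
        theta = (1 - np.exp(-2 * np.diff(positions) / 100)) / 2
        expected = theta.sum()
        sd_mean = np.sqrt(np.sum(theta * (1 - theta)) / 1_000)
        assert abs(switches.mean() - expected) <= 4 * sd_mean
        assert abs(expected - 1.0) < 0.01  # dense markers see ~the Morgan length

    def test_missing_rate_call_rate(self):
        spec = sd.CrossSimSpec(
            n_progeny=100, markers_per_chromosome=200, missing_rate=0.25, seed=19
        )
        cross = sd.simulate_cross({"Chr01": 50_000_000}, spec)
        mean_cr = cross.quality["call_rate"].mean()
        sd_mean = np.sqrt(0.25 * 0.75 / (100 * 200))
        assert abs(mean_cr - 0.75) <= 4 * sd_mean

    def test_progeny_codes_match_declared_type(self):
        spec = sd.CrossSimSpec(
            n_progeny=40, markers_per_chromosome=50, fraction_3to1=0.3,
            fraction_codominant=0.2, missing_rate=0.1, seed=23,
        )
        cross = sd.simulate_cross({"Chr01": 20_000_000}, spec)
        for mid, row in cross.genotypes.iterrows():
            stype = cross.truth.loc[mid, "seg_type"]
            progeny = row.iloc[2:]
            valid = set(progeny) - {sd.MISSING}
            if stype == sd.FULLY_INFORMATIVE:
                assert valid <= {"ac", "ad", "bc", "bd"}
            else:
                assert valid <= {"0", "1"}

    def test_n_progeny_error(self):
        with pytest.raises(sd.ParameterError):
            sd.simulate_cross(
                {"Chr01": 1_000_000}, sd.CrossSimSpec(n_progeny=1)
            )

    def test_transmissions_are_noise_free(self, clean_cross):
        """With no noise, testcross scores equal the transmitted alleles."""
        x1 = clean_cross.transmissions["P1"]
        truth = clean_cross.truth
        cols = clean_cross.progeny_columns
        for k, mid in enumerate(truth.index):
            if truth.loc[mid, "seg_type"] != sd.TESTCROSS_P1:
                continue
            scores = clean_cross.genotypes.loc[mid, cols].to_numpy()
            assert (scores == np.where(x1[:, k] == 1, "1", "0")).all()
            break
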