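import numpy as np
import pytest

from semiperm import data_io, introgression as ig, popgen_stats as pg
from semiperm import synthetic_data as sd
from semiperm.errors import ConfigError, SimulationError


def panmictic_config(theta=5.0, length=500):
    return sd.SimulationConfig(
        splits=[], demes=[sd.DemeSpec("a", "x")], contacts=[],
        loci=[sd.LocusSpec("l", length, theta)], samples_per_deme=5, seed=1,
    )


class TestGenealogy:
    def test_pairwise_tmrca_mean(self):
        cfg = panmictic_config()
        rng = np.random.default_rng(0)
        times = []
        for _ in range(4000):
            root, _ = sd.simulate_genealogy(
                cfg, cfg.loci[0], {("a", "x"): ["t1", "t2"]}, rng
            )
            times.append(root.time)
        # E[T2] = 1, Var[T2] = 1 -> SE = 1/sqrt(reps)
        assert np.mean(times) == pytest.approx(1.0, abs=3 / np.sqrt(len(times)))

    def test_no_migration_cross_coalescence_predates_split(self):
        cfg = sd.species_pair_config(
            seed=1, split_time=10.0, contact_m=0.0, n_diploids=2, n_loci=1,
            within_species_m=0.0,
        )
        rng = np.random.default_rng(5)
        tips = {
            ("spA", "contact"): ["x1", "x2"],
            ("spB", "contact"): ["y1", "y2"],
        }
        for _ in range(50):
            root, _ = sd.simulate_genealogy(cfg, cfg.loci[0], tips, rng)

            def check(node):
                if node.tip_id is not None:
                    return {node.tip_id[0]}
                sides = [check(c) for c in node.children]
                merged = set().union(*sides)
                if len(sides) == 2 and sides[0] != sides[1] and (
                    "x" in merged and "y" in merged
                ):
                    cross = any(
                        ("x" in a and "y" in b) or ("y" in a and "x" in b)
                        for a in sides for b in sides if a is not b
                    )
                    if cross:
                        assert node.time >= 10.0
                return merged

            check(root)

    def test_fixed_seed_identical_tree(self):
        cfg = panmictic_config()
        tips = {("a", "x"): [f"t{i}" for i in range(6)]}
        r1, _ = sd.simulate_genealogy(cfg, cfg.loci[0], tips,
                                      np.random.default_rng(9))
        r2, _ = sd.simulate_genealogy(cfg, cfg.loci[0], tips,
                                      np.random.default_rng(9))

        def shape(node):
            if node.tip_id:
                return node.tip_id
            return (node.time, tuple(sorted(repr(shape(c))
                                            for c in node.children)))

        assert shape(r1) == shape(r2)

    def test_zero_size_deme_errors(self):
        cfg = sd.SimulationConfig(
            splits=[], demes=[sd.DemeSpec("a", "x", 0.0)], contacts=[],
            loci=[sd.LocusSpec("l", 100, 1.0)], samples_per_deme=2, seed=1,
        )
        with pytest.raises(ConfigError):
            sd.simulate_genealogy(
                cfg, cfg.loci[0], {("a", "x"): ["t1", "t2"]},
                np.random.default_rng(0),
            )


class TestMutations:
    def test_theta_zero_identical(self):
        cfg = panmictic_config(theta=0.0)
        rng = np.random.default_rng(2)
        root, _ = sd.simulate_genealogy(
            cfg, cfg.loci[0], {("a", "x"): [f"t{i}" for i in range(6)]}, rng
        )
        seqs = sd.drop_mutations(root, 0.0, 100, rng)
        assert len(set(seqs.values())) == 1

    def test_neutral_expectations(self):
        """E[K] = theta and E[S] = theta * a_{n-1} within 3 SE."""
        cfg = panmictic_config()
        rng = np.random.default_rng(3)
        tips = {("a", "x"): [f"t{i}" for i in range(10)]}
        Ks, Ss = [], []
        for _ in range(1000):
            root, _ = sd.simulate_genealogy(cfg, cfg.loci[0], tips, rng)
            seqs = list(sd.drop_mutations(root, 5.0, 500, rng).values())
            Ks.append(pg.mean_pairwise_differences(seqs))
            Ss.append(pg.segregating_sites(seqs))
        a9 = sum(1 / i for i in range(1, 10))
        se_k = np.std(Ks) / np.sqrt(len(Ks))
        se_s = np.std(Ss) / np.sqrt(len(Ss))
        assert np.mean(Ks) == pytest.approx(5.0, abs=3 * se_k)
        assert np.mean(Ss) == pytest.approx(5.0 * a9, abs=3 * se_s)

    def test_mutation_overflow_errors(self):
        cfg = panmictic_config(theta=50.0, length=3)
        rng = np.random.default_rng(4)
        root, _ = sd.simulate_genealogy(
            cfg, cfg.loci[0], {("a", "x"): [f"t{i}" for i in range(8)]}, rng
        )
        with pytest.raises(SimulationError):
            sd.drop_mutations(root, 50.0, 3, rng)


class TestDataset:
    def test_determinism_byte_identical(self, tmp_path):
        cfg = sd.barbel_like_config(seed=7, samples_per_deme=3)
        d1 = sd.simulate_dataset(cfg)
        d2 = sd.simulate_dataset(sd.barbel_like_config(seed=7, samples_per_deme=3))
        p1 = d1.write(tmp_path / "one")
        p2 = d2.write(tmp_path / "two")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_single_species_all_allopatric(self):
        cfg = sd.SimulationConfig(
            splits=[], demes=[sd.DemeSpec("a", "x"), sd.DemeSpec("a", "y")],
            contacts=[], loci=[sd.LocusSpec("l", 200, 2.0)],
            samples_per_deme=3, seed=2, within_species_m=1.0,
        )
        ds = sd.simulate_dataset(cfg)
        smap = data_io.build_sympatry_map(ds.samples)
        assert all(lab == data_io.ALLOPATRIC for lab in smap.labels.values())

    def test_no_migration_yields_zero_proportion(self):
        props = []
        for seed in range(7):
            cfg = sd.species_pair_config(
                seed=seed, split_time=8.0, contact_m=0.0, n_diploids=5,
                n_loci=2, theta=3.0,
            )
            ds = sd.simulate_dataset(cfg)
            smap = data_io.build_sympatry_map(ds.samples)
            tables = {
                n: data_io.collapse_alleles(a, ds.samples)
                for n, a in ds.alignments.items()
            }
            pair = ("spA", "spB")
            excl = ig.exclude_loci_for_pair(pair, tables, smap)
            calls = ig.classify_diagnostic_alleles(
                pair, "contact", tables, smap, excl
            )
            props.append(
                ig.introgression_proportion(
                    pair, "contact", calls, tables, excl
                ).proportion
            )
        assert np.median(props) == 0.0

    def test_haploid_locus_one_copy_per_sample(self):
        cfg = sd.barbel_like_config(seed=5, samples_per_deme=2)
        ds = sd.simulate_dataset(cfg)
        mt = ds.alignments["mt"]
        assert len(mt) == len(ds.samples.records)
        assert all("_" not in hid.rsplit("-", 1)[-1] for hid in mt.ids)

    def test_truth_table_written(self, tmp_path):
        cfg = sd.species_pair_config(seed=3, split_time=5.0, contact_m=1.0,
                                     n_diploids=3, n_loci=1)
        ds = sd.simulate_dataset(cfg)
        assert set(ds.truth.lineages) == {"nuc1", "divergence_ref"}
        for (locus, pair), frac in ds.truth.cross_fractions.items():
            assert 0.0 <= frac <= 1.0
        paths = ds.write(tmp_path)
        assert paths["truth"].exists()

    def test_monotone_permeability(self):
        """Realized introgression proportion is non-decreasing in the
        permeability scalar s at fixed M (medians over replicate batches)."""
        medians = []
        for s in (0.0, 0.5, 1.0):
            props = []
            for seed in range(12):
                cfg = sd.species_pair_config(
                    seed=100 * seed + int(10 * s), split_time=8.0,
                    contact_m=3.0, n_diploids=5, n_loci=2, theta=4.0,
                )
                cfg.loci = [
                    sd.LocusSpec(l.name, l.length, l.theta, l.ploidy, s)
                    for l in cfg.loci
                ]
                ds = sd.simulate_dataset(cfg)
                smap = data_io.build_sympatry_map(ds.samples)
                tables = {
                    n: data_io.collapse_alleles(a, ds.samples)
                    for n, a in ds.alignments.items()
                }
                pair = ("spA", "spB")
                excl = ig.exclude_loci_for_pair(pair, tables, smap)
                calls = ig.classify_diagnostic_alleles(
                    pair, "contact", tables, smap, excl
                )
                props.append(
                    ig.introgression_proportion(
                        pair, "contact", calls, tables, excl
                    ).proportion
                )
            medians.append(float(np.median(props)))
        assert medians[0] <= medians[1] <= medians[2]
        assert medians[2] > medians[0]


class TestConfig:
    def test_toml_roundtrip(self, tmp_path):
        toml = """
seed = 9
samples_per_deme = 3
within_species_m = 1.0

[[splits]]
species = "a"
parent = "anc"
time = 4.0

[[splits]]
species = "b"
parent = "anc"
time = 4.0

[[demes]]
species = "a"
basin = "G"

[[demes]]
species = "b"
basin = "G"

[[contacts]]
species_a = "a"
species_b = "b"
basin = "G"
start_time = 0.5
M = 1.0

[[loci]]
name = "l1"
length = 300
theta = 2.0
"""
        p = tmp_path / "sim.toml"
        p.write_text(toml)
        cfg = sd.read_simulation_config(p)
        assert cfg.seed == 9
        ds = sd.simulate_dataset(cfg)
        assert "l1" in ds.alignments

    def test_seed_mandatory(self, tmp_path):
        p = tmp_path / "sim.toml"
        p.write_text("samples_per_deme = 2\ndemes = []\nloci = []\n")
        with pytest.raises(ConfigError):
            sd.read_simulation_config(p)

    def test_contact_after_split_rejected(self):
        with pytest.raises(ConfigError):
            sd.species_pair_config(seed=1, split_time=0.4, contact_m=1.0,
                                   contact_start=0.5)

    def test_fixtures_byte_stable(self, tmp_path):
        out1 = sd.make_toy_fixtures(tmp_path / "f1")
        out2 = sd.make_toy_fixtures(tmp_path / "f2")
        for key in out1:
            for f1 in sorted(out1[key].iterdir()):
                f2 = out2[key] / f1.name
                assert f1.read_bytes() == f2.read_bytes()

    def test_fixture_zero_variation_all_zero_stats(self, tmp_path):
        from semiperm.popgen_stats import population_stats
        out = sd.make_toy_fixtures(tmp_path)
        zv = out["zero_variation"]
        samples = data_io.read_metadata_tsv(zv / "metadata.tsv")
        aln = data_io.read_locus_fasta(zv / "locus1.fasta")
        samples.bind_alignment(aln)
        st = population_stats({"locus1": aln}, samples, ("alpha", "G"))[-1]
        assert (st.S, st.Hd, st.K, st.pi, st.thetaW) == (0, 0, 0, 0, 0)

    def test_fixture_fst_third(self, tmp_path):
        out = sd.make_toy_fixtures(tmp_path)
        ft = out["fst_third"]
        samples = data_io.read_metadata_tsv(ft / "metadata.tsv")
        aln = data_io.read_locus_fasta(ft / "locus1.fasta")
        samples.bind_alignment(aln)
        from semiperm.popgen_stats import hudson_fst, population_sequences
        x = population_sequences(aln, samples, ("xpop", "G"))
        y = population_sequences(aln, samples, ("ypop", "T"))
        assert hudson_fst(x, y)[0] == pytest.approx(1 / 3)
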