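import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import xchromatin as xc
from xchromatin import synthetic_data as sd
from xchromatin.synthetic_data import ConfigError


@pytest.fixture(scope="module")
def small_annotation():
    return xc.make_toy_genome(
        {"X": 20, "2L": 20, "4": 4},
        {"X": 100_000, "2L": 100_000, "4": 5_000},
        seed=4,
    )


class TestShearReads:
    def test_read_count_and_length(self, small_annotation):
        shear = sd.ShearModel.uniform(small_annotation)
        reads = xc.simulate_shear_reads(small_annotation, shear, "female",
                                        5000, seed=1)
        assert len(reads.reads) == 5000
        assert ((reads.reads["end"] - reads.reads["start"]) == 35).all()
        assert reads.total_sequenced_bp == 5000 * 35
        # every read fits within its arm
        for arm in small_annotation.arms:
            sub = reads.on_arm(arm.name)
            assert sub.empty or (sub["end"].max() <= arm.length_bp
                                 and sub["start"].min() >= 0)

    def test_male_x_half_coverage(self, small_annotation):
        """Copy number 1 vs 2 forces X density to half autosome density."""
        shear = sd.ShearModel.uniform(small_annotation)
        reads = xc.simulate_shear_reads(small_annotation, shear, "male",
                                        120_000, seed=2)
        bp = reads.reads.groupby("arm").size() * 35
        dens = {a.name: bp.get(a.name, 0) / a.length_bp
                for a in small_annotation.arms}
        auto = (bp.get("2L", 0) + bp.get("4", 0)) / (100_000 + 5_000)
        assert dens["X"] / auto == pytest.approx(0.5, abs=0.02)

    def test_exon_boost_recovered_against_propensity_oracle(self, small_annotation):
        """Simulated exon/intron depth ratio matches the exact expectation
        from an independently built propensity vector."""
        shear = sd.ShearModel(
            arm_openness={a.name: 1.0 for a in small_annotation.arms},
            exon_boost=2.0,
        )
        reads = xc.simulate_shear_reads(small_annotation, shear, "female",
                                        400_000, read_length=35, seed=3)
        # brute-force per-base masks, independent of the generator internals
        arm = small_annotation.arm("2L")
        exonic = np.zeros(arm.length_bp, dtype=bool)
        intronic = np.zeros(arm.length_bp, dtype=bool)
        for g in small_annotation.genes_on("2L"):
            for s, e in g.exons:
                exonic[s:e] = True
            for s, e in g.introns:
                intronic[s:e] = True
        track = xc.depth_track(reads, arm)
        ratio = track.depth[exonic].mean() / track.depth[intronic].mean()
        # oracle: expected depth at base b is proportional to the summed
        # start-weights of reads covering b
        w = np.ones(arm.length_bp)
        w[exonic] = 2.0
        cover = np.convolve(w[: arm.length_bp - 34], np.ones(35))
        expected = cover[exonic].mean() / cover[intronic].mean()
        assert ratio == pytest.approx(expected, rel=0.03)

    def test_seed_reproducibility_byte_identical(self, small_annotation, tmp_path):
        shear = sd.ShearModel.default(small_annotation)
        paths = []
        for i in (1, 2):
            reads = xc.simulate_shear_reads(small_annotation, shear, "male",
                                            2000, seed=99)
            p = tmp_path / f"r{i}.bed"
            reads.to_bed(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_bed_round_trip(self, small_annotation, tmp_path):
        shear = sd.ShearModel.uniform(small_annotation)
        reads = xc.simulate_shear_reads(small_annotation, shear, "male",
                                        500, seed=7)
        p = tmp_path / "reads.bed"
        reads.to_bed(p)
        back = sd.ReadSet.from_bed(p, "male", 35,
                                   total_sequenced_bp=reads.total_sequenced_bp)
        pd.testing.assert_frame_equal(back.reads, reads.reads)

    def test_bad_config_rejected(self, small_annotation):
        with pytest.raises(ConfigError):
            sd.ShearModel(arm_openness={"X": -1.0})
        shear = sd.ShearModel.uniform(small_annotation)
        with pytest.raises(ConfigError):
            xc.simulate_shear_reads(small_annotation, shear, "male", 0)


class TestArrayBatch:
    def test_null_config_gives_exactly_zero_ratios(self, small_annotation):
        effects = sd.EffectConfig(
            gene_effect_sd=0.0, array_bias_sd=0.0, noise_sd=0.0,
            input_noise_sd=0.0, control_fraction=0.0, duplicate_fraction=0.0,
        )
        batches = xc.simulate_array_batch(small_annotation, effects, "H4K16ac",
                                          n_replicates={"male": 1, "female": 1},
                                          seed=0)
        for batch in batches.values():
            df = batch.elements
            ratios = np.log2(df["chip_intensity"] / df["input_intensity"])
            assert np.all(ratios == 0.0)

    def test_noise_free_x_shift_planted_exactly(self, small_annotation):
        shift = math.log2(1.5)
        effects = sd.EffectConfig(
            x_shift={"male": shift, "female": shift},
            gene_effect_sd=0.0, array_bias_sd=0.0, noise_sd=0.0,
            input_noise_sd=0.0, control_fraction=0.0, duplicate_fraction=0.0,
        )
        batch = xc.simulate_array_batch(small_annotation, effects, "H4K16ac",
                                        sexes=("male",),
                                        n_replicates={"male": 1}, seed=1)["male"]
        df = batch.elements
        arms = small_annotation.gene_arms().reindex(df["gene_id"]).to_numpy()
        ratios = np.log2(df["chip_intensity"] / df["input_intensity"]).to_numpy()
        on_x = arms == "X"
        assert ratios[on_x].mean() - ratios[~on_x].mean() == pytest.approx(
            shift, abs=1e-12
        )

    def test_latent_mapping_hits_spearman_target(self):
        """Monte-Carlo check of rho_latent = 2 sin(pi rho_S / 6)."""
        ann = xc.make_toy_genome(
            {"X": 2000, "2L": 1980, "2R": 1980, "3L": 1980, "3R": 1980, "4": 80},
            seed=7,
        )
        effects = sd.EffectConfig(
            shared_effect_correlation=0.9, noise_sd=0.0, array_bias_sd=0.0,
            input_noise_sd=0.0, control_fraction=0.0, duplicate_fraction=0.0,
        )
        batches = xc.simulate_array_batch(ann, effects, "H3K4me2",
                                          n_replicates={"male": 1, "female": 1},
                                          seed=10)
        ratios = {}
        for sex, batch in batches.items():
            df = batch.elements
            ratios[sex] = np.log2(
                df["chip_intensity"] / df["input_intensity"]
            ).to_numpy()
        rho, _ = stats.spearmanr(ratios["male"], ratios["female"])
        assert rho == pytest.approx(0.9, abs=0.02)

    def test_replicates_controls_and_duplicates_structured(self, small_annotation):
        effects = sd.EffectConfig(control_fraction=0.05, duplicate_fraction=0.2)
        batch = xc.simulate_array_batch(small_annotation, effects, "H4K16ac",
                                        sexes=("male",),
                                        n_replicates={"male": 3}, seed=5)["male"]
        df = batch.elements
        assert df["array_id"].nunique() == 3
        one = df[df["array_id"] == df["array_id"].iloc[0]]
        n_genes = len(small_annotation.genes)
        gene_counts = one[~one["is_control"]].groupby("gene_id").size()
        assert set(gene_counts.unique()) <= {1, 2}
        assert (gene_counts == 2).sum() > 0  # some duplicates spotted
        assert one["is_control"].sum() > 0
        assert (one.loc[one["is_control"], "gene_id"].fillna("") == "").all()
        # controls sit at low background intensity in both channels
        ctrl = one[one["is_control"]]
        genes = one[~one["is_control"]]
        assert ctrl["input_intensity"].mean() < genes["input_intensity"].mean() / 10

    def test_impossible_correlation_rejected(self):
        with pytest.raises(ConfigError):
            sd.EffectConfig(shared_effect_correlation=1.5)


@pytest.fixture(scope="module")
def ratios():
    rng = np.random.default_rng(0)
    vals = rng.normal(0.2, 0.6, 4000)
    return pd.Series(vals, index=[f"g{i}" for i in range(4000)])


class TestExpression:
    def test_null_link_gives_unit_fold(self, small_annotation, ratios):
        effects = sd.EffectConfig(expression_fold={"male": 1.0, "female": 1.0})
        expr, _ = xc.simulate_expression(small_annotation, ratios, effects,
                                         "male", seed=1)
        classes = xc.percentile_classes(ratios)
        fold = xc.expression_association(classes, expr)["fold"]
        assert fold == pytest.approx(1.0, abs=0.05)

    def test_noise_free_fold_matches_closed_form(self, small_annotation, ratios):
        effects = sd.EffectConfig(
            expression_fold={"male": 2.68, "female": 3.77},
            expression_noise_sd=0.0,
        )
        expr, _ = xc.simulate_expression(small_annotation, ratios, effects,
                                         "male", seed=2)
        classes = xc.percentile_classes(ratios)
        fold = xc.expression_association(classes, expr)["fold"]
        assert fold == pytest.approx(2.68, rel=1e-9)

    def test_labels_partition_with_configured_fraction(self, small_annotation,
                                                       ratios):
        effects = sd.EffectConfig(sex_bias_fraction={"male": 0.2, "female": 0.1})
        _, labels = xc.simulate_expression(small_annotation, ratios, effects,
                                           "male", seed=3)
        assert set(labels.unique()) == {"male_biased", "non_biased"}
        assert labels.index.equals(ratios.index)
        frac = (labels == "male_biased").mean()
        assert frac == pytest.approx(0.2, abs=1e-3)

    def test_biased_genes_have_depleted_ratios(self, small_annotation, ratios):
        effects = sd.EffectConfig(sex_bias_strength=0.8)
        _, labels = xc.simulate_expression(small_annotation, ratios, effects,
                                           "male", seed=4)
        biased = ratios[labels == "male_biased"]
        non = ratios[labels == "non_biased"]
        assert biased.mean() < non.mean() - 0.2
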