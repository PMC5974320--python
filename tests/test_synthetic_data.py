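import numpy as np
import pandas as pd
import pytest

from tomoloc.classify import (classify_protein_array, classify_rna,
                              classify_rna_array, classify_table,
                              consensus_category)
from tomoloc.normalization import to_fractions
from tomoloc.synthetic_data import (
    GroundTruth, SynthConfig, simulate_dataset, simulate_homoeologs,
    simulate_protein, simulate_rna, simulate_utrs,
)


@pytest.fixture(scope="module")
def small_config():
    return SynthConfig(seed=11, n_genes=200, n_anchors=4, pair_fraction=0.2,
                       n_proteins=80)


class TestDeterminism:
    def test_same_seed_identical_dataset(self, small_config):
        c1, q1, u1, t1 = simulate_dataset(small_config)
        c2, q2, u2, t2 = simulate_dataset(small_config)
        pd.testing.assert_frame_equal(c1.data, c2.data)
        pd.testing.assert_frame_equal(q1.data, q2.data)
        assert u1.records == u2.records
        assert t1.categories == t2.categories
        assert t1.pair_map == t2.pair_map

    def test_different_seed_differs(self, small_config):
        import dataclasses
        other = dataclasses.replace(small_config, seed=12)
        c1, *_ = simulate_dataset(small_config)
        c2, *_ = simulate_dataset(other)
        assert not c1.data.equals(c2.data)


class TestRoster:
    def test_archetypes_validated_at_construction(self):
        with pytest.raises(ValueError, match="archetype"):
            SynthConfig(archetypes={**SynthConfig().archetypes,
                                    "vegetal": (0.2, 0.2, 0.2, 0.2, 0.2)})

    def test_category_proportions_respected(self):
        cfg = SynthConfig(seed=0, n_genes=2000, pair_fraction=0.0)
        _, _, truth = simulate_rna(cfg)
        cats = pd.Series({g: c for g, c in truth.categories.items()
                          if g not in truth.anchors})
        counts = cats.value_counts()
        assert counts["animal"] == round(0.944 * 2000)
        assert counts["extremely_vegetal"] == round(0.002 * 2000)

    def test_true_fractions_classify_back(self, small_config):
        _, _, truth = simulate_rna(small_config)
        genes = [g for g in truth.categories if g not in truth.anchors]
        labels = classify_rna_array(truth.fractions.loc[genes].to_numpy())
        expected = np.array([truth.categories[g] for g in genes])
        assert (labels == expected).all()


class TestRnaCounts:
    def test_noise_free_recovery(self):
        """With noise off, classification recovers every generating category."""
        cfg = SynthConfig(seed=3, n_genes=300, pair_fraction=0.0,
                          nb_dispersion=1e9, abundance_sdlog=0.0,
                          abundance_meanlog=np.log(1e6))
        counts, _, truth = simulate_rna(cfg)
        labels = classify_table(to_fractions(counts), "rna")
        labels = labels.drop(truth.anchors)
        truthcat = pd.Series(truth.categories).loc[labels.index]
        assert (labels == truthcat).mean() == 1.0

    def test_distortion_shifts_fractions(self):
        cfg = SynthConfig(seed=3, n_genes=100, pair_fraction=0.0,
                          segment_distortion=(2, 1, 1, 1, 0.5),
                          noise_free_anchors=True)
        counts, cq, truth = simulate_rna(cfg)
        # anchor counts are distorted but anchor Cq reflects the true fractions
        from tomoloc.normalization import compute_size_factors
        f = compute_size_factors(counts, cq)
        inv = 1 / np.array([2, 1, 1, 1, 0.5])
        inv /= np.exp(np.log(inv).mean())
        np.testing.assert_allclose(f.data[1].to_numpy(), inv, atol=1e-9)


class TestProtein:
    def test_low_noise_quorum_recovery(self):
        cfg = SynthConfig(seed=5, n_proteins=120, protein_noise_sd=1e-4)
        table, cats = simulate_protein(cfg)
        prof = to_fractions(table)
        recovered = {}
        for gene in prof.consensus.index:
            labels = [
                str(classify_protein_array(
                    prof.replicates[r].loc[[gene]].to_numpy())[0])
                for r in prof.replicates if gene in prof.replicates[r].index
            ]
            recovered[gene] = consensus_category(labels)
        acc = np.mean([recovered[g] == cats[g] for g in recovered])
        assert acc >= 0.99

    def test_seed_determinism(self):
        cfg = SynthConfig(seed=6, n_proteins=40)
        t1, _ = simulate_protein(cfg)
        t2, _ = simulate_protein(cfg)
        pd.testing.assert_frame_equal(t1.data, t2.data)


class TestUtrs:
    def test_planted_positions_recorded_and_present(self, small_config):
        _, _, utrs, truth = simulate_dataset(small_config)
        n_checked = 0
        for gene, plants in truth.motif_positions.items():
            for motif, positions in plants.items():
                for pos in positions:
                    assert utrs.records[gene][pos:pos + len(motif)] == motif
                    n_checked += 1
        assert n_checked > 0

    def test_plant_rate_zero_background_presence(self):
        """Without planting, motif presence matches the background model."""
        cfg = SynthConfig(seed=9, motif_plant={})
        cats = {f"g{i}": "vegetal" for i in range(300)}
        truth = GroundTruth(categories=cats, fractions=pd.DataFrame())
        utrs = simulate_utrs(cfg, truth, np.random.default_rng(9))
        from tomoloc.motif_scan import Motif, scan_iupac
        m = Motif(id="m", consensus="TTCAC")
        with_hit = sum(bool(scan_iupac(s, m)) for s in utrs.records.values())
        # P(no hit) ~ (1 - 4^-5)^(L-4); mean L ~ e^(6.8 + 0.45^2/2) ~ 995
        lengths = np.array([len(s) for s in utrs.records.values()])
        expected = np.mean(1 - (1 - 4.0 ** -5) ** (lengths - 4)) * len(lengths)
        assert abs(with_hit - expected) < 4 * np.sqrt(expected)

    def test_s_copy_shares_mutated_background(self, small_config):
        _, _, utrs, truth = simulate_dataset(small_config)
        base, (gl, gs) = next(iter(truth.pair_map.items()))
        sl, ss = utrs.records[gl], utrs.records[gs]
        n = min(len(sl), len(ss))
        ident = np.mean([a == b for a, b in zip(sl[:n], ss[:n])])
        assert ident > 0.9   # ~5% mutation rate


class TestHomoeologs:
    def test_designed_concordance_zero_q(self):
        cfg = SynthConfig(seed=2, n_genes=100, pair_fraction=0.5,
                          discordant_fraction=0.0)
        truth = GroundTruth(
            categories={f"g{i}": "animal" for i in range(100)},
            fractions=pd.DataFrame(
                np.tile(SynthConfig().archetypes["animal"], (100, 1)),
                index=[f"g{i}" for i in range(100)],
                columns=list("ABCDE")))
        out = simulate_homoeologs(cfg, truth, np.random.default_rng(2))
        assert len(out.pair_map) == 50
        assert out.designed_concordance == 1.0
        for gl, gs in out.pair_map.values():
            assert out.categories[gl] == out.categories[gs]

    def test_designed_discordant_count_exact(self):
        cfg = SynthConfig(seed=4, n_genes=400, pair_fraction=0.5,
                          discordant_fraction=0.03)
        _, _, _, truth = simulate_dataset(cfg)
        n_pairs = len(truth.pair_map)
        assert n_pairs == 200
        assert len(truth.designed_discordant) == round(0.03 * n_pairs)
        for base in truth.designed_discordant:
            gl, gs = truth.pair_map[base]
            assert truth.categories[gl] != truth.categories[gs]

    def test_discordant_s_profile_reclassifies(self):
        cfg = SynthConfig(seed=4, n_genes=400, pair_fraction=0.5,
                          discordant_fraction=0.05)
        _, _, _, truth = simulate_dataset(cfg)
        for base in truth.designed_discordant:
            gl, gs = truth.pair_map[base]
            assert classify_rna(truth.fractions.loc[gs].to_numpy()) == \
                truth.categories[gs]
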