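import numpy as np
import pytest

from desatnet import synth
from desatnet.align import smith_waterman
from desatnet.synth import SynthConfig, expected_identity, generate

from _oracles import expected_identity_mc


def frac_identity(a, b):
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestGenerate:
    def test_zero_rates_reproduce_root(self):
        config = SynthConfig(
            seed=1, n_families=2, subfamilies_per_family=2,
            seqs_per_subfamily=3, seq_len=60, p_family=0.0, p_subfamily=0.0,
            p_tip=0.0, frac_fused=0.0, n_background=0,
        )
        records, _ = generate(config)
        assert len({r.sequence for r in records}) == 1

    def test_single_branch_identity_within_binomial_interval(self):
        # one family, one subfamily: tip vs subfamily ancestor differs only
        # by the tip branch. Identity to another tip of the same subfamily
        # follows the two-step chain; here test the one-step rate via
        # p_family = p_subfamily = 0.
        config = SynthConfig(
            seed=2, n_families=1, subfamilies_per_family=1,
            seqs_per_subfamily=30, seq_len=400, p_family=0.0,
            p_subfamily=0.0, p_tip=0.2, frac_fused=0.0, n_background=0,
        )
        records, _ = generate(config)
        # ancestor == root == what a p_tip=0 run produces
        root = generate(
            SynthConfig(**{**config.__dict__, "p_tip": 0.0})
        )[0][0].sequence
        ident = np.mean([frac_identity(r.sequence, root) for r in records])
        # central 99% interval for mean of 30*400 Bernoulli(0.8) sites
        half = 2.576 * np.sqrt(0.8 * 0.2 / (30 * 400))
        assert abs(ident - 0.8) < half * 1.5

    def test_same_seed_is_byte_identical(self, tmp_path):
        config = SynthConfig(seed=5, n_families=2, subfamilies_per_family=2,
                             seqs_per_subfamily=4, seq_len=80, n_background=5)
        a_dir, b_dir = tmp_path / "a", tmp_path / "b"
        for d in (a_dir, b_dir):
            records, truth = generate(config)
            synth.write_corpus(records, truth, d)
        for name in ("corpus.fasta", "annotations.tsv", "truth.tsv"):
            assert (a_dir / name).read_bytes() == (b_dir / name).read_bytes()

    def test_identity_tiers_ordered(self, small_corpus):
        config, records, truth = small_corpus
        by_id = {r.id: r for r in records}
        tips = [r for r in records if not r.id.startswith("BG")]

        def mean_identity(pairs):
            vals = []
            for a, b in pairs:
                sa = by_id[a].sequence[: config.seq_len]
                sb = by_id[b].sequence[: config.seq_len]
                vals.append(frac_identity(sa, sb))
            return np.mean(vals)

        within_sub, within_fam, between_fam = [], [], []
        for i, a in enumerate(tips):
            for b in tips[i + 1 :]:
                if truth.subfamily[a.id] == truth.subfamily[b.id]:
                    within_sub.append((a.id, b.id))
                elif truth.family[a.id] == truth.family[b.id]:
                    within_fam.append((a.id, b.id))
                else:
                    between_fam.append((a.id, b.id))
        assert (
            mean_identity(within_sub)
            > mean_identity(within_fam)
            > mean_identity(between_fam)
        )

    def test_fused_tips_and_only_fused_tips_carry_cytb5(self, small_corpus):
        _, records, truth = small_corpus
        for r in records:
            assert r.has_cytb5 == (r.id in truth.fused)

    def test_fused_fraction_concentrated_in_family_one(self, small_corpus):
        _, records, truth = small_corpus
        assert truth.fused
        assert all(truth.family[t] == "fam1" for t in truth.fused)

    def test_characterized_labels_match_subfamily_substrate(self, small_corpus):
        _, records, truth = small_corpus
        for r in records:
            if r.characterized:
                sub = truth.subfamily[r.id]
                assert r.substrate == truth.substrate_by_subfamily[sub]

    def test_every_subfamily_has_a_characterized_tip(self, small_corpus):
        _, records, truth = small_corpus
        chars = {
            truth.subfamily[r.id] for r in records if r.characterized
        }
        assert chars == set(truth.substrate_by_subfamily)

    def test_background_is_singleton_truth(self, small_corpus):
        _, records, truth = small_corpus
        bg = [r.id for r in records if r.id.startswith("BG")]
        assert len({truth.family[b] for b in bg}) == len(bg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SynthConfig(p_tip=1.0)
        with pytest.raises(ValueError):
            SynthConfig(seq_len=10)
        with pytest.raises(ValueError):
            SynthConfig(n_families=0)


class TestExpectedIdentity:
    def test_empty_path_is_one(self):
        assert expected_identity([]) == 1.0

    def test_single_step_has_no_back_substitution(self):
        assert expected_identity([0.3]) == pytest.approx(0.7)

    def test_two_half_steps_closed_form(self):
        # 0.5*0.5 + 0.5*(0.5/19)
        assert expected_identity([0.5, 0.5]) == pytest.approx(
            0.25 + 0.5 * 0.5 / 19, abs=1e-12
        )

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(3)
        path = [0.35, 0.1, 0.1, 0.35]
        mc = expected_identity_mc(path, length=400, n_rep=50, rng=rng)
        assert expected_identity(path) == pytest.approx(mc, abs=0.01)

    def test_long_path_approaches_random_floor(self):
        assert expected_identity([0.5] * 200) == pytest.approx(0.05, abs=1e-3)

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            expected_identity([1.0])


@pytest.fixture(scope="module")
def report(small_corpus):
    config, _, _ = small_corpus
    return synth.recovery_experiment(
        config, thresholds=(-5.0, -13.0, -57.0), holdout_frac=0.2,
        classify_threshold=-57.0,
    )


class TestSmallRecovery:
    """Pipeline recovery on the fast small corpus; the full-scale study
    conditions are exercised by the acceptance suite."""

    def test_single_family_config_trivially_recovers(self):
        config = SynthConfig(
            seed=9, n_families=1, subfamilies_per_family=2,
            seqs_per_subfamily=5, seq_len=150, n_background=0,
            frac_fused=0.0,
        )
        rep = synth.recovery_experiment(
            config, thresholds=(-5.0,), holdout_frac=0.0,
            classify_threshold=-5.0,
        )
        assert rep.family_ari[0] == pytest.approx(1.0)

    def test_background_only_config_mostly_singletons(self):
        config = SynthConfig(
            seed=10, n_families=1, subfamilies_per_family=1,
            seqs_per_subfamily=1, seq_len=300, n_background=30,
            frac_fused=0.0,
        )
        records, _ = generate(config)
        build = synth.build_pipeline(records)
        part = synth.network.connected_components(build.ssn)
        singleton = sum(
            1 for info in part.clusters.values() if info.node_count == 1
        )
        # unrelated sequences almost never share an edge at logE <= -5
        assert singleton >= len(build.repnodes) - 2

    def test_family_ari_at_loose_threshold(self, report):
        fam_ari, _ = report.ari_at(-13.0)
        assert fam_ari > 0.9

    def test_subfamily_ari_at_strict_threshold(self, report):
        _, sub_ari = report.ari_at(-57.0)
        assert sub_ari > 0.9

    def test_holdout_classified_to_planted_subfamily(self, report):
        assert report.holdout_total > 0
        assert report.holdout_correct >= 0.8 * report.holdout_total

    def test_report_frame_and_text(self, report):
        df = report.to_frame()
        assert list(df.columns) == [
            "threshold", "family_ari", "subfamily_ari", "n_clusters"
        ]
        assert "hold-out" in report.summary_text()
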