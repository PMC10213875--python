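"""Synthetic study generator: determinism, constructed reference
properties, noise model and count conservation."""

import numpy as np
import pandas as pd
import pytest

from sncpipe.refdb import reverse_complement
from sncpipe.synthetic import (
    SimConfig,
    TOTAL_RPM,
    build_feature_panel,
    generate_references,
    nb_counts,
    simulate_counts,
    simulate_human_study,
    synthesize_reads,
    write_reference_fastas,
)


def small_cfg(seed=1, depth=3000):
    return SimConfig(seed=seed, depth=depth)


class TestReferences:
    def test_18s_embedded_in_45s(self, toy_refset):
        by_id = {r.ref_id: r for r in toy_refset.records}
        assert by_id["rRNA-18S"].sequence in by_id["rRNA-45S"].sequence

    def test_required_database_composition(self, toy_refset):
        biotypes = pd.Series([r.biotype for r in toy_refset.records]).value_counts()
        assert biotypes["miRNA"] >= 5
        assert biotypes["tRNA"] >= 3
        assert biotypes["piRNA"] >= 10
        assert biotypes["other_ncRNA"] >= 2
        trnas = [r for r in toy_refset.records if r.biotype == "tRNA"]
        assert any(r.is_histidine for r in trnas)
        assert any(r.splice_junctions for r in trnas)

    def test_rescue_decoy_off_genome_but_hamming1_from_rrna(self, toy_refset):
        decoy = next(r for r in toy_refset.records if r.ref_id == "piR-m-offgenome")
        assert decoy.sequence not in toy_refset.genome
        assert reverse_complement(decoy.sequence) not in toy_refset.genome
        r18 = next(r for r in toy_refset.records if r.ref_id == "rRNA-18S")
        best = min(
            sum(a != b for a, b in zip(decoy.sequence, r18.sequence[i:]))
            for i in range(len(r18.sequence) - len(decoy.sequence) + 1)
        )
        assert best == 1

    def test_same_seed_identical_fasta_bytes(self, tmp_path):
        cfg = small_cfg()
        outs = []
        for run in ("a", "b"):
            rng = np.random.default_rng(cfg.seed)
            refset = generate_references(cfg, rng)
            paths = write_reference_fastas(refset, tmp_path / run)
            outs.append(b"".join(p.read_bytes() for p in sorted(paths.values())))
        assert outs[0] == outs[1]


class TestNoiseModel:
    def test_poisson_limit_variance_equals_mean(self):
        rng = np.random.default_rng(1)
        mean = np.full(500, 80.0)
        draws = np.array([nb_counts(rng, mean, 0.0) for _ in range(50)]).ravel()
        assert draws.var() / draws.mean() == pytest.approx(1.0, abs=0.1)

    def test_nb_variance_mu_plus_phi_mu_squared(self):
        rng = np.random.default_rng(2)
        mu, phi = 60.0, 0.2
        draws = nb_counts(rng, np.full(20000, mu), phi)
        expected = mu + phi * mu * mu
        assert draws.var() == pytest.approx(expected, rel=0.05)

    def test_planted_fold_change_shifts_group_means(self, toy_refset):
        cfg = small_cfg(depth=50000)
        rng = np.random.default_rng(5)
        panel = build_feature_panel(cfg, toy_refset, rng)
        truth = simulate_counts(cfg, panel, rng)
        effect = next(e for e in truth.effects
                      if e.direction == "up" and len(e.generations) == 3)
        sp = truth.panel.index[truth.panel["feature_id"] == effect.feature_id][0]
        treated = truth.samples.index[truth.samples["lineage"] == effect.lineage]
        control = truth.samples.index[truth.samples["lineage"] == "control"]
        ratio = (
            truth.counts.loc[sp, treated].mean()
            / truth.counts.loc[sp, control].mean()
        )
        assert ratio == pytest.approx(8.0, rel=0.35)

    def test_baselines_fill_rpm_budget(self, toy_refset):
        cfg = small_cfg()
        rng = np.random.default_rng(9)
        panel = build_feature_panel(cfg, toy_refset, rng)
        truth = simulate_counts(cfg, panel, rng)
        assert truth.panel["baseline_rpm"].sum() == pytest.approx(TOTAL_RPM)


class TestTruthTables:
    def test_transgenerational_truth_requires_all_three_generations(self, toy_refset):
        cfg = small_cfg()
        rng = np.random.default_rng(3)
        panel = build_feature_panel(cfg, toy_refset, rng)
        truth = simulate_counts(cfg, panel, rng)
        for e in truth.effects:
            sets = truth.transgen_truth.get(e.lineage, {"up": set(), "down": set()})
            in_tg = e.feature_id in sets["up"] | sets["down"]
            assert in_tg == (set(cfg.generations) <= set(e.generations))

    def test_combined_lineage_inherits_obese_plants(self, toy_refset):
        cfg = small_cfg()
        rng = np.random.default_rng(4)
        panel = build_feature_panel(cfg, toy_refset, rng)
        truth = simulate_counts(cfg, panel, rng)
        obese_only = {
            e.feature_id for e in truth.effects
            if e.lineage == "obese" and len(e.generations) == 3
        }
        combined = truth.transgen_truth["obese_androgenized"]
        assert not obese_only & (combined["up"] | combined["down"])

    def test_unknown_planted_feature_rejected(self, toy_refset):
        from sncpipe.synthetic import PlantedEffect

        cfg = small_cfg()
        rng = np.random.default_rng(5)
        panel = build_feature_panel(cfg, toy_refset, rng)
        with pytest.raises(ValueError, match="ghost"):
            simulate_counts(cfg, panel, rng, effects=[PlantedEffect("ghost", "obese", "up")])


class TestReads:
    def test_count_conservation_with_decoys(self, tmp_path, toy_refset):
        cfg = SimConfig(seed=1, depth=2000, n_decoy_reads=25)
        rng = np.random.default_rng(cfg.seed)
        panel = build_feature_panel(cfg, toy_refset, rng)
        truth = simulate_counts(cfg, panel, rng)
        paths = synthesize_reads(truth, cfg, tmp_path, rng)
        sample = truth.samples.index[0]
        n_lines = sum(1 for _ in open(paths[sample]))
        assert n_lines // 4 == int(truth.counts[sample].sum()) + 25

    def test_fastq_deterministic_under_seed(self, tmp_path, toy_refset):
        outs = []
        for run in ("a", "b"):
            cfg = SimConfig(seed=2, depth=1500)
            rng = np.random.default_rng(cfg.seed)
            refset = generate_references(cfg, rng)
            panel = build_feature_panel(cfg, refset, rng)
            truth = simulate_counts(cfg, panel, rng)
            paths = synthesize_reads(truth, cfg, tmp_path / run, rng)
            outs.append(b"".join(p.read_bytes() for p in sorted(paths.values())))
        assert outs[0] == outs[1]

    def test_5p_fragments_start_at_parent_position_one(self, toy_refset):
        cfg = small_cfg()
        rng = np.random.default_rng(6)
        panel = build_feature_panel(cfg, toy_refset, rng)
        by_id = {r.ref_id: r for r in toy_refset.records}
        five_p = panel[panel["subtype"] == "tsRNA_5p"]
        assert len(five_p) > 0
        for _, row in five_p.iterrows():
            assert by_id[row["parent"]].sequence.startswith(row["sequence"])

    def test_composition_matches_configured_proportions(self, tmp_path, toy_refset):
        """Realised read counts track expected means within multinomial error."""
        cfg = SimConfig(seed=3, depth=30000, phi=0.0)
        rng = np.random.default_rng(cfg.seed)
        panel = build_feature_panel(cfg, toy_refset, rng)
        truth = simulate_counts(cfg, panel, rng)
        sample = truth.samples.index[0]
        lib = truth.library_sizes[sample]
        expected = truth.panel["baseline_rpm"] * lib / 1e6
        observed = truth.counts[sample]
        big = expected[expected > 50]
        z = (observed[big.index] - big) / np.sqrt(big)
        assert np.abs(z).max() < 5


class TestHumanStudy:
    def test_homolog_per_transgen_feature_and_pair_truth(self, toy_refset):
        cfg = small_cfg()
        rng = np.random.default_rng(8)
        panel = build_feature_panel(cfg, toy_refset, rng)
        truth = simulate_counts(cfg, panel, rng)
        human = simulate_human_study(cfg, truth, rng)
        n_tg = sum(
            len(s["up"] | s["down"]) for s in truth.transgen_truth.values()
        )
        assert len(human.planted_pairs) == n_tg
        assert human.samples["group"].value_counts()["pcos"] == 9
        # every planted pair's sequences accept under the seed-anchored rule
        from sncpipe.homology import seed_anchored_match

        info = truth.panel.drop_duplicates("feature_id").set_index("feature_id")
        for _, row in human.planted_pairs.iterrows():
            q = human.features.loc[row["query_id"], "sequence"]
            s = info.loc[row["subject_id"], "sequence"]
            assert seed_anchored_match(q, s) is not None
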