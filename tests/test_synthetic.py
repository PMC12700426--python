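"""Tests of the synthetic-data generator against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from sostempo.lexabox import Pwm, extract_promoters
from sostempo.synthetic_data import (
    SimConfig,
    assign_sos_truth,
    default_box_pwm,
    generate_dataset,
    make_null_truth,
    plant_lexa_boxes,
    simulate_annotation,
    simulate_counts,
    simulate_coverage,
    simulate_traces,
)


def test_single_gene_genome_is_degenerate_but_valid():
    cfg = SimConfig(genome_length=10_000, n_genes=1, n_sos_genes=0,
                    operon_fraction=0.0)
    genome, ann = simulate_annotation(cfg, np.random.default_rng(0))
    assert len(genome) == 10_000
    assert len(ann) == 1
    assert len(ann.tus()) == 1


def test_annotation_determinism_and_seed_sensitivity(small_config):
    g1, a1 = simulate_annotation(small_config, np.random.default_rng(7))
    g2, a2 = simulate_annotation(small_config, np.random.default_rng(7))
    g3, _ = simulate_annotation(small_config, np.random.default_rng(8))
    assert g1 == g2
    assert [(g.gene_id, g.start, g.strand) for g in a1] == [
        (g.gene_id, g.start, g.strand) for g in a2
    ]
    assert g1 != g3


def test_operon_fraction_reduces_tu_count_recount_oracle():
    cfg = SimConfig(genome_length=80_000, n_genes=50, n_sos_genes=10,
                    operon_fraction=0.2)
    _, ann = simulate_annotation(cfg, np.random.default_rng(3))
    tu_ids = {g.tu_id for g in ann}
    assert len(tu_ids) < len(ann)
    # independent recount: grouping genes by tu_id reproduces the TU map
    recount = pd.Series([g.tu_id for g in ann]).nunique()
    assert recount == len(ann.tus())


def test_infeasible_packing_raises():
    cfg = SimConfig()
    cfg.genome_length = 30_000
    cfg.n_genes = 40
    with pytest.raises(ValueError, match="genome|fit"):
        simulate_annotation(cfg, np.random.default_rng(0))


def test_genes_do_not_overlap(small_config):
    _, ann = simulate_annotation(small_config, np.random.default_rng(5))
    spans = sorted((g.start, g.end) for g in ann)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 <= s2


class TestPlantedBoxes:
    def test_point_mass_pwm_plants_the_exact_string(self, small_config):
        target = "GTTCTTGTTATGTTC"
        probs = np.full((4, 15), 1e-12)
        for j, base in enumerate(target):
            probs["ACGT".index(base), j] = 1.0
        probs /= probs.sum(axis=0)
        pwm = Pwm(probs, np.full(4, 0.25))
        rng = np.random.default_rng(0)
        genome, ann = simulate_annotation(small_config, rng)
        truth = assign_sos_truth(ann, small_config, rng)
        genome2, truth2 = plant_lexa_boxes(ann, genome, truth, pwm, rng)
        boxes = truth2.genes.loc[truth2.genes["is_sos"], "box_seq"]
        assert len(boxes) == small_config.n_sos_genes
        assert (boxes == target).all()

    def test_zero_sos_genes_leaves_genome_unchanged(self):
        cfg = SimConfig(genome_length=50_000, n_genes=20, n_sos_genes=0)
        rng = np.random.default_rng(1)
        genome, ann = simulate_annotation(cfg, rng)
        truth = assign_sos_truth(ann, cfg, rng)
        genome2, _ = plant_lexa_boxes(ann, genome, truth, default_box_pwm(cfg), rng)
        assert genome2 == genome

    def test_scan_recovers_planted_offsets_exhaustively(self, small_config):
        """Relocating each box by exhaustive PWM scan finds the planted offset."""
        rng = np.random.default_rng(2)
        genome, ann = simulate_annotation(small_config, rng)
        truth = assign_sos_truth(ann, small_config, rng)
        pwm = default_box_pwm(small_config)
        genome, truth = plant_lexa_boxes(ann, genome, truth, pwm, rng)
        proms = extract_promoters(ann, genome, genes=truth.sos_genes)
        for gid, seq in proms.items():
            scores = pwm.scan(seq)
            planted = int(truth.genes.loc[gid, "box_offset"]) + 200
            # the planted box attains the window maximum (a neighbouring
            # gene's box inside the same window can tie at consensus score)
            assert scores[planted] == pytest.approx(scores.max(), abs=1e-9)

    def test_box_inside_promoter_window(self, small_config):
        rng = np.random.default_rng(3)
        genome, ann = simulate_annotation(small_config, rng)
        truth = assign_sos_truth(ann, small_config, rng)
        _, truth = plant_lexa_boxes(ann, genome, truth, default_box_pwm(small_config), rng)
        off = truth.genes.loc[truth.genes["is_sos"], "box_offset"].astype(int)
        assert (off >= -200).all() and (off + 15 <= 75).all()

    def test_overlong_box_rejected(self, small_config):
        rng = np.random.default_rng(4)
        genome, ann = simulate_annotation(small_config, rng)
        truth = assign_sos_truth(ann, small_config, rng)
        big = Pwm(np.full((4, 300), 0.25), np.full(4, 0.25))
        with pytest.raises(ValueError, match="longer than promoter"):
            plant_lexa_boxes(ann, genome, truth, big, rng)


class TestCounts:
    def test_poisson_limit_mean_within_3se(self):
        cfg = SimConfig(n_genes=2000, n_sos_genes=0, genome_length=4_000_000,
                        dispersion=0.0, library_factor_sd=0.0)
        truth = make_null_truth(cfg)
        cm = simulate_counts(cfg, truth, np.random.default_rng(0))
        for sid in cm.counts.columns:
            m = cm.counts[sid].mean()
            se = np.sqrt(cfg.basal_mu / len(cm.counts))
            assert abs(m - cfg.basal_mu) < 3 * se

    def test_derepressed_mean_follows_2_to_beta(self):
        """Law of large numbers: dlexa-condition mean ~ basal * 2^beta."""
        cfg = SimConfig(n_genes=1, n_sos_genes=0, genome_length=20_000,
                        n_replicates=1000, library_factor_sd=0.0)
        truth = make_null_truth(cfg)
        truth.genes.loc["g0001", ["is_sos", "beta", "temporal_class"]] = [True, 3.0, "early"]
        cm = simulate_counts(cfg, truth, np.random.default_rng(5))
        dlexa = cm.select("dlexAdsidA", "none", 0)
        m = cm.counts.loc["g0001", dlexa].mean()
        expect = cfg.basal_mu * 8
        sd = np.sqrt(expect + cfg.dispersion * expect**2)
        assert abs(m - expect) < 3 * sd / np.sqrt(len(dlexa))

    def test_byte_identical_across_runs(self, small_config):
        truth = make_null_truth(small_config)
        c1 = simulate_counts(small_config, truth, np.random.default_rng(9))
        c2 = simulate_counts(small_config, truth, np.random.default_rng(9))
        assert c1.counts.equals(c2.counts)

    def test_negative_dispersion_rejected(self, small_config):
        truth = make_null_truth(small_config)
        cfg = SimConfig(**{**small_config.__dict__, "dispersion": -0.1})
        with pytest.raises(ValueError, match="non-negative"):
            simulate_counts(cfg, truth, np.random.default_rng(0))


class TestCoverage:
    def test_single_peak_mass_conservation(self, small_config):
        rng = np.random.default_rng(0)
        genome, ann = simulate_annotation(small_config, rng)
        truth = assign_sos_truth(ann, small_config, rng)
        _, truth = plant_lexa_boxes(ann, genome, truth, default_box_pwm(small_config), rng)
        keep = truth.sos_genes[0]
        genes = truth.genes.copy()
        genes.loc[genes.index != keep, "is_sos"] = False
        truth_one = type(truth)(genes)
        cfg = SimConfig(**{**small_config.__dict__, "coverage_background": 0.0,
                           "peak_area": 1000.0})
        track = simulate_coverage(ann, truth_one, cfg, np.random.default_rng(1))
        total = track.sum()
        assert abs(total - 1000) < 4 * np.sqrt(1000)  # Poisson-total tolerance

    def test_background_only_is_poisson(self, small_config):
        cfg = SimConfig(**{**small_config.__dict__, "n_sos_genes": 0})
        rng = np.random.default_rng(2)
        genome, ann = simulate_annotation(cfg, rng)
        truth = assign_sos_truth(ann, cfg, rng)
        track = simulate_coverage(ann, truth, cfg, np.random.default_rng(3))
        lam = cfg.coverage_background
        se = np.sqrt(lam / track.size)
        assert abs(track.mean() - lam) < 3 * se

    def test_peak_argmax_near_planted_center(self, small_config):
        rng = np.random.default_rng(4)
        genome, ann = simulate_annotation(small_config, rng)
        truth = assign_sos_truth(ann, small_config, rng)
        _, truth = plant_lexa_boxes(ann, genome, truth, default_box_pwm(small_config), rng)
        cfg = SimConfig(**{**small_config.__dict__, "coverage_background": 0.0})
        track = simulate_coverage(ann, truth, cfg, np.random.default_rng(5))
        from sostempo.chipcov import smooth_gaussian

        sm = smooth_gaussian(track, 20.0)
        centers = truth.genes["box_center"].dropna().astype(int).to_numpy()
        for center in centers:
            others = centers[centers != center]
            if others.size and np.min(np.abs(others - center)) < 500:
                continue  # overlapping piles shift the joint maximum
            idx = np.arange(center - 200, center + 200) % len(track)
            local_max = idx[np.argmax(sm.values[idx])]
            d = abs(local_max - center) % len(track)
            assert min(d, len(track) - d) <= small_config.peak_sd / 2


class TestTraces:
    def test_no_damage_control_is_flat(self):
        cfg = SimConfig(k_c=0.0, trace_noise_cv=0.0)
        traces = simulate_traces(cfg, np.random.default_rng(0), n_cells=3)
        for tr in traces:
            norm = tr.normalized
            assert np.allclose(norm, norm[0], rtol=1e-6)

    def test_closed_form_after_derepression(self):
        """Sharp-switch limit: once L crosses K_d the reporter follows
        F(t) = (beta/delta)(1 - exp(-delta (t - t*))) from zero."""
        cfg = SimConfig(h=400.0, trace_noise_cv=0.0, cell_cv_beta=0.0,
                        dt=0.01, L0=100.0, K_d=10.0, k_c=0.05, delta=0.02,
                        background_au=0.0, obs_interval=5.0)
        traces = simulate_traces(cfg, np.random.default_rng(0), n_cells=1)
        tr = traces[0]
        t_star = np.log(cfg.L0 / cfg.K_d) / cfg.k_c
        beta = cfg.trace_beta_max
        mask = tr.t > t_star + 5
        expected = (beta / cfg.delta) * (1 - np.exp(-cfg.delta * (tr.t[mask] - t_star)))
        observed = tr.normalized[mask]
        assert np.max(np.abs(observed - expected) / expected) < 0.01

    def test_stronger_promoter_dominates_pointwise(self):
        cfg = SimConfig()
        hi = simulate_traces(cfg, np.random.default_rng(1), 200, beta_max=50.0)
        lo = simulate_traces(cfg, np.random.default_rng(2), 200, beta_max=25.0)
        mh = np.mean([t.normalized for t in hi], axis=0)
        ml = np.mean([t.normalized for t in lo], axis=0)
        assert (mh[1:] > ml[1:]).all()

    def test_preconditions(self):
        with pytest.raises(ValueError, match="dt"):
            simulate_traces(SimConfig(dt=2.0), np.random.default_rng(0), 1)
        with pytest.raises(ValueError, match="t_max"):
            simulate_traces(SimConfig(t_max=30.0), np.random.default_rng(0), 1)


def test_truth_labels_cover_every_gene(default_dataset):
    truth = default_dataset.truth.genes
    assert truth["is_sos"].notna().all()
    sos = truth[truth["is_sos"]]
    assert sos["temporal_class"].isin(["early", "late"]).all()
    assert (sos["beta"] > 0).all()
    assert sos["box_seq"].notna().all()


def test_dataset_generation_deterministic(small_config):
    d1 = generate_dataset(small_config, seed=3, n_cells=5)
    d2 = generate_dataset(small_config, seed=3, n_cells=5)
    assert d1.genome == d2.genome
    assert d1.counts.counts.equals(d2.counts.counts)
    assert np.array_equal(d1.coverage, d2.coverage)
    assert np.array_equal(d1.traces_strong[0].intensity, d2.traces_strong[0].intensity)
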