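"""Generator determinism, planted-truth recovery and file round-trips."""

import json
import os

import numpy as np
import pytest

from tfhot.annotation import map_to_gene
from tfhot.enrichment import scan_motif
from tfhot.intervals import read_genes, read_peaks
from tfhot.occupancy import classify_regions, merge_peaks, occupancy_spectrum
from tfhot.signal import average_profile, classify_modality, compare_heights, height_table
from tfhot.synthetic import (
    LandscapeConfig,
    TierSpec,
    default_tiers,
    generate_landscape,
    generate_sequences_and_annotations,
    generate_signal,
    generate_tags,
    locus_windows,
    write_landscape,
)


class TestConfigValidation:
    def test_default_config_matches_study_structure(self):
        cfg = LandscapeConfig()
        assert len(cfg.cell_types) == 10
        assert sum(cfg.cell_types.values()) == 108
        assert min(cfg.cell_types.values()) == 6
        assert max(cfg.cell_types.values()) == 21

    def test_singleton_tier_occupancy_enforced(self):
        with pytest.raises(ValueError):
            LandscapeConfig(tiers=[TierSpec("singleton", 10, (1, 2))])

    def test_jitter_bounded_by_peak_width(self):
        with pytest.raises(ValueError):
            LandscapeConfig(jitter_sd=150, peak_width=(200, 400))

    def test_hotspot_occupancy_must_reach_threshold(self):
        with pytest.raises(ValueError):
            LandscapeConfig(
                tiers=[TierSpec("hotspot", 5, (4, 8))], hotspot_min=6
            )


class TestLandscape:
    def test_planted_tiers_recovered_exactly_without_jitter(self, small_config):
        peak_sets, manifest = generate_landscape(small_config)
        _regions, counts = classify_regions(merge_peaks(peak_sets["ES"]))
        assert counts == {"singleton": 50, "combinatorial": 30, "hotspot": 20}

    def test_spectrum_matches_manifest(self, small_config):
        peak_sets, manifest = generate_landscape(small_config)
        regions, _ = classify_regions(merge_peaks(peak_sets["ES"]))
        spectrum = occupancy_spectrum(regions)
        planted = {}
        for locus in manifest["cell_types"]["ES"]["loci"]:
            planted[locus["occupancy"]] = planted.get(locus["occupancy"], 0) + 1
        for occ, n in planted.items():
            assert spectrum.loc[occ, "count"] == n

    def test_determinism_same_seed(self, small_config):
        a = generate_landscape(small_config)
        b = generate_landscape(small_config)
        assert json.dumps(a[1], sort_keys=True) == json.dumps(b[1], sort_keys=True)
        for ps_a, ps_b in zip(a[0]["ES"], b[0]["ES"]):
            assert ps_a == ps_b

    def test_different_seed_differs(self, small_config):
        a = generate_landscape(small_config)
        small_config.seed = 99
        b = generate_landscape(small_config)
        assert json.dumps(a[1]) != json.dumps(b[1])

    def test_jittered_recovery_rate(self):
        """With 20 bp jitter and >=200 bp peaks, classification still
        recovers >= 99% of planted tier labels across seeds."""
        agree = total = 0
        for seed in range(20):
            cfg = LandscapeConfig(
                seed=seed, chrom_length=2_000_000, cell_types={"ES": 8},
                jitter_sd=20.0,
                tiers=[TierSpec("singleton", 50, (1, 1)),
                       TierSpec("combinatorial", 30, (2, 5)),
                       TierSpec("hotspot", 20, (6, 8))],
            )
            peak_sets, manifest = generate_landscape(cfg)
            regions, _ = classify_regions(merge_peaks(peak_sets["ES"]))
            truth = {l["center"]: l["tier"]
                     for l in manifest["cell_types"]["ES"]["loci"]}
            centers = sorted(truth)
            for r in regions:
                mid = r.interval.midpoint
                c = min(centers, key=lambda x: abs(x - mid))
                total += 1
                agree += r.group == truth[c]
        assert total >= 20 * 100  # no spurious splits/merges beyond planted loci
        assert agree / total >= 0.99

    def test_shared_loci_reuse_coordinates(self):
        cfg = LandscapeConfig(
            seed=4, chrom_length=3_000_000, cell_types={"A": 8, "B": 8},
            shared_fraction=0.5,
            tiers=[TierSpec("singleton", 60, (1, 1)),
                   TierSpec("combinatorial", 30, (2, 5)),
                   TierSpec("hotspot", 10, (6, 8))],
        )
        _ps, manifest = generate_landscape(cfg)
        centers_a = {l["center"] for l in manifest["cell_types"]["A"]["loci"]}
        centers_b = {l["center"] for l in manifest["cell_types"]["B"]["loci"]}
        assert len(centers_a & centers_b) == 50


class TestTags:
    def test_height_ordering_detected(self, small_config):
        peak_sets, manifest = generate_landscape(small_config)
        regions, _ = classify_regions(merge_peaks(peak_sets["ES"]))
        tags = generate_tags(manifest, "ES",
                             mean_heights={"singleton": 10, "combinatorial": 30,
                                           "hotspot": 80})
        table = height_table(regions, tags)
        groups = {g: s.height.to_numpy() for g, s in table.groupby("group")}
        res = compare_heights(groups).set_index(["group_a", "group_b"])
        row = res.loc[("hotspot", "singleton")]
        assert row.median_a > row.median_b
        assert row.p_value < 0.01

    def test_zero_mean_tier_produces_no_tags(self, small_config):
        _ps, manifest = generate_landscape(small_config)
        tags = generate_tags(manifest, "ES",
                             mean_heights={"singleton": 0, "combinatorial": 0,
                                           "hotspot": 0})
        assert tags.total() == 0

    def test_doubling_means_doubles_heights(self, small_config):
        _ps, manifest = generate_landscape(small_config)
        totals = []
        for scale in (1, 2):
            means = {"singleton": 20 * scale, "combinatorial": 20 * scale,
                     "hotspot": 20 * scale}
            reps = [generate_tags(dict(manifest, seed=manifest["seed"] + r),
                                  "ES", mean_heights=means).total()
                    for r in range(20)]
            totals.append(np.mean(reps))
        assert totals[1] / totals[0] == pytest.approx(2.0, rel=0.1)


class TestSignal:
    def test_tier_shapes_classified_as_planted(self, small_config):
        peak_sets, manifest = generate_landscape(small_config)
        regions, _ = classify_regions(merge_peaks(peak_sets["ES"]))
        signal = generate_signal(manifest, "ES")
        for tier, expected in (("singleton", "monomodal"), ("hotspot", "bimodal")):
            rs = [r for r in regions if r.group == tier]
            pm = average_profile([(r.interval.chrom, r.summit) for r in rs], signal)
            assert classify_modality(pm.aggregate).call == expected

    def test_zero_amplitude_is_ambiguous(self, small_config):
        _ps, manifest = generate_landscape(small_config)
        for t in manifest["tiers"].values():
            t["signal_amplitude"] = 0.0
        signal = generate_signal(manifest, "ES")
        centers = [(manifest["chrom"], l["center"])
                   for l in manifest["cell_types"]["ES"]["loci"]]
        pm = average_profile(centers, signal)
        assert classify_modality(pm.aggregate).call == "ambiguous"

    def test_oversized_bimodal_offset_rejected(self, small_config):
        _ps, manifest = generate_landscape(small_config)
        manifest["tiers"]["hotspot"]["profile"] = "bimodal"
        manifest["tiers"]["hotspot"]["profile_offset"] = 6000
        with pytest.raises(ValueError):
            generate_signal(manifest, "ES", window=10_000)


class TestSequences:
    @pytest.fixture()
    def pack(self):
        cfg = LandscapeConfig(
            seed=5, chrom_length=3_000_000, cell_types={"ES": 8},
            tiers=[TierSpec("singleton", 200, (1, 1), motif_rate=0.05,
                            annotation_rate=0.02, de_rate=0.05),
                   TierSpec("combinatorial", 100, (2, 5), motif_rate=0.2,
                            annotation_rate=0.1, de_rate=0.1),
                   TierSpec("hotspot", 100, (6, 8), motif_rate=0.6,
                            annotation_rate=0.3, de_rate=0.5)],
        )
        peak_sets, manifest = generate_landscape(cfg)
        return generate_sequences_and_annotations(manifest, "ES"), cfg

    def test_planted_motifs_are_found_in_windows(self, pack):
        sp, _cfg = pack
        manifest = sp.manifest
        seq = sp.genome[manifest["chrom"]]
        for locus in manifest["cell_types"]["ES"]["loci"]:
            if locus["motif_planted"]:
                c = locus["center"]
                window = seq[c - 200 : c + 200]
                assert scan_motif(window, sp.motif) >= 1

    def test_gene_targets_are_nearest_genes(self, pack):
        sp, _cfg = pack
        manifest = sp.manifest
        for locus in manifest["cell_types"]["ES"]["loci"]:
            c = locus["center"]
            from tfhot.intervals import GenomicInterval

            a = map_to_gene(GenomicInterval(manifest["chrom"], c - 100, c + 100),
                            sp.genes)
            assert a.gene_id == locus["gene_target"]

    def test_de_rates_respect_tier_bias(self, pack):
        sp, _cfg = pack
        manifest = sp.manifest
        loci = manifest["cell_types"]["ES"]["loci"]
        de = set(sp.de_genes)
        hot = [l for l in loci if l["tier"] == "hotspot"]
        single = [l for l in loci if l["tier"] == "singleton"]
        hot_rate = np.mean([l["gene_target"] in de for l in hot])
        single_rate = np.mean([l["gene_target"] in de for l in single])
        assert hot_rate > single_rate

    def test_annotation_rate_recovery(self, pack):
        sp, _cfg = pack
        loci = sp.manifest["cell_types"]["ES"]["loci"]
        hot = [l for l in loci if l["tier"] == "hotspot"]
        rate = np.mean([l["annotation_member"] for l in hot])
        assert rate == pytest.approx(0.3, abs=0.1)


class TestWriteLandscape:
    def test_files_readable_and_truth_consistent(self, tmp_path, small_config):
        outdir = tmp_path / "land"
        manifest = write_landscape(small_config, str(outdir),
                                   with_sequences=True)
        # narrowPeak round-trip through the reader
        sets = []
        for factor in manifest["cell_types"]["ES"]["factors"]:
            path = outdir / f"ES.{factor}.narrowPeak"
            sets.append(read_peaks(str(path), "narrowPeak",
                                   factor=factor, cell_type="ES"))
        _regions, counts = classify_regions(merge_peaks([s for s in sets if s.peaks]))
        assert counts == {"singleton": 50, "combinatorial": 30, "hotspot": 20}
        genes = read_genes(str(outdir / "genes.bed12"))
        assert len(genes) == 100
        truth = json.loads((outdir / "truth.json").read_text())
        assert truth["seed"] == small_config.seed

    def test_byte_identical_across_runs(self, tmp_path, small_config):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_landscape(small_config, str(d1))
        write_landscape(small_config, str(d2))
        for name in sorted(os.listdir(d1)):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name
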