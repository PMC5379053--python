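"""Synthetic-data generator: determinism, planted truth, statistical oracles."""

import numpy as np
import pandas as pd
import pytest

from tecrm import simulate
from tecrm.motifs import scan
from tecrm.simulate import (
    CapacityError,
    CoverageSpec,
    ModuleSpec,
    ReporterSpec,
    SimConfig,
    SubfamilySpec,
    best_site,
    default_pwms,
    genome_to_strings,
    simulate_coverage,
    simulate_genome,
    simulate_peaks,
    simulate_reporter,
)


def consensus(length, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def config(**kw):
    defaults = dict(
        genome_length=500_000,
        subfamily_specs=(
            SubfamilySpec("SubA", consensus(300, 1), 50, 0.05),
            SubfamilySpec("SubB", consensus(300, 2), 50, 0.05),
        ),
        seed=0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSimulateGenome:
    def test_zero_rate_copies_identical_to_consensus(self):
        cfg = config(
            subfamily_specs=(SubfamilySpec("SubA", consensus(300, 1), 20, 0.0),)
        )
        genome, annotation, truth = simulate_genome(cfg)
        assert (truth.te_truth["divergence_p"] == 0.0).all()
        assert (annotation["milliDiv"] == 0.0).all()
        strings = genome_to_strings(genome)
        row = truth.te_truth.iloc[0]
        inserted = strings[row.chrom][row.start : row.end]
        from tecrm.motifs import revcomp

        expect = consensus(300, 1)
        assert inserted == (expect if row.strand == "+" else revcomp(expect))

    def test_realized_divergence_matches_binomial_mean(self):
        """rate 0.1 over 200 copies of 300 bp: mean p within 3 SE of 0.1."""
        cfg = config(
            genome_length=1_000_000,
            subfamily_specs=(SubfamilySpec("SubA", consensus(300, 3), 200, 0.1),),
        )
        _, _, truth = simulate_genome(cfg)
        mean_p = truth.te_truth["divergence_p"].mean()
        se = np.sqrt(0.1 * 0.9 / (200 * 300))
        assert abs(mean_p - 0.1) <= 3 * se

    def test_determinism_bit_identical(self):
        cfg = config(seed=5)
        g1, a1, t1 = simulate_genome(cfg)
        g2, a2, t2 = simulate_genome(cfg)
        assert genome_to_strings(g1) == genome_to_strings(g2)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(t1.te_truth, t2.te_truth)

    def test_different_seeds_differ(self):
        g1, _, _ = simulate_genome(config(seed=1))
        g2, _, _ = simulate_genome(config(seed=2))
        assert genome_to_strings(g1) != genome_to_strings(g2)

    def test_placement_no_overlap(self):
        _, annotation, _ = simulate_genome(config())
        for chrom, grp in annotation.groupby("chrom"):
            srt = grp.sort_values("genoStart")
            assert (srt["genoStart"].to_numpy()[1:] >= srt["genoEnd"].to_numpy()[:-1]).all()

    def test_capacity_error_when_genome_too_small(self):
        cfg = config(
            genome_length=10_000,
            subfamily_specs=(SubfamilySpec("SubA", consensus(300, 1), 200, 0.05),),
        )
        with pytest.raises(CapacityError):
            simulate_genome(cfg)

    def test_module_carriers_contain_exact_best_sites_in_order(self):
        cfg = config(
            planted_module_spec=ModuleSpec(
                subfamily="SubA",
                pwm_names=("Esrrb", "Klf4", "Sox2"),
                carrier_fraction=0.5,
            )
        )
        genome, _, truth = simulate_genome(cfg)
        strings = genome_to_strings(genome)
        pwms = default_pwms()
        carriers = truth.te_truth[truth.te_truth["carrier"]]
        assert len(carriers) == 25
        motifs_by_te = dict(tuple(truth.motif_truth.groupby("te_index")))
        for te in carriers.itertuples():
            planted = motifs_by_te[te.te_index]
            assert list(planted["tf"]) == ["Esrrb", "Klf4", "Sox2"]
            for m in planted.itertuples():
                seg = strings[m.chrom][m.start : m.end]
                expect = best_site(pwms[m.tf])
                from tecrm.motifs import revcomp

                assert seg == (expect if m.strand == "+" else revcomp(expect))
                # planted site is in the upstream (5') half of the element
                if m.strand == "+":
                    assert m.end - te.start <= (te.end - te.start) / 2 + 25
                else:
                    assert te.end - m.start <= (te.end - te.start) / 2 + 25

    def test_planted_sites_recovered_by_scanner(self):
        cfg = config(
            planted_module_spec=ModuleSpec(
                subfamily="SubA", pwm_names=("Esrrb",), carrier_fraction=0.2
            )
        )
        genome, _, truth = simulate_genome(cfg)
        strings = genome_to_strings(genome)
        pwm = default_pwms()["Esrrb"]
        for m in truth.motif_truth.itertuples():
            window = strings[m.chrom][m.start - 5 : m.end + 5]
            hits = scan(window, pwm, 1e-3)
            assert any(h.offset == 5 for h in hits)

    def test_conservation_annotation_rows(self):
        cfg = config(
            ltr_pair_spec=simulate.LTRPairSpec(
                n_pairs=10, insertion_time_myr=13.0, rate_per_myr=5e-4
            )
        )
        _, annotation, truth = simulate_genome(cfg)
        assert len(annotation) == 100 + 2 * 10
        assert len(truth.ltr_truth) == 10

    def test_subfamily_divergence_unbiased(self):
        """Realized divergence is an unbiased estimate of the spec'd rate
        (binomial test at alpha = 0.01 across >= 100 copies)."""
        from scipy import stats

        cfg = config(
            genome_length=1_000_000,
            subfamily_specs=(SubfamilySpec("SubA", consensus(300, 9), 120, 0.05),),
            seed=11,
        )
        _, _, truth = simulate_genome(cfg)
        n_sites = 120 * 300
        n_subs = int(round(truth.te_truth["divergence_p"].sum() * 300))
        p = stats.binomtest(n_subs, n_sites, 0.05).pvalue
        assert p > 0.01


@pytest.fixture(scope="module")
def planted():
    cfg = config(
        planted_module_spec=ModuleSpec(
            subfamily="SubA",
            pwm_names=("Esrrb", "Klf4", "Sox2"),
            carrier_fraction=0.5,
        )
    )
    return simulate_genome(cfg)


@pytest.fixture(scope="module")
def truth(planted):
    return planted[2]


class TestSimulatePeaks:
    def test_zero_background_peak_count_equals_planted(self, planted):
        _, _, truth = planted
        peaks = simulate_peaks(truth, background_rate=0.0, seed=0)
        assert len(peaks) == len(truth.motif_truth)
        assert (peaks["origin"] == "planted").all()

    def test_carriers_overlap_three_distinct_tf_peaks(self, planted):
        _, _, truth = planted
        peaks = simulate_peaks(truth, background_rate=0.0, seed=0)
        for te_idx, group in truth.motif_truth.groupby("te_index"):
            te = truth.te_truth.loc[truth.te_truth["te_index"] == te_idx].iloc[0]
            over = peaks[
                (peaks["chrom"] == te.chrom)
                & (peaks["start"] < te.end)
                & (peaks["end"] > te.start)
            ]
            assert len(set(over["tf"])) >= 3

    def test_background_varies_with_seed_planted_does_not(self, planted):
        _, _, truth = planted
        p1 = simulate_peaks(truth, background_rate=20.0, seed=1)
        p2 = simulate_peaks(truth, background_rate=20.0, seed=2)
        pl1 = p1[p1["origin"] == "planted"].reset_index(drop=True)
        pl2 = p2[p2["origin"] == "planted"].reset_index(drop=True)
        pd.testing.assert_frame_equal(pl1, pl2)
        assert not p1[p1["origin"] == "background"].equals(
            p2[p2["origin"] == "background"]
        )

    def test_peaks_within_chromosome_bounds(self, planted):
        _, _, truth = planted
        peaks = simulate_peaks(truth, background_rate=50.0, seed=3)
        for r in peaks.itertuples():
            assert 0 <= r.start < r.end <= truth.chrom_sizes[r.chrom]


class TestSimulateCoverage:
    def test_null_track_is_poisson_background(self, truth):
        tracks = simulate_coverage(
            truth, CoverageSpec(background_depth=20.0, enrichment=1.0), seed=0
        )
        arr = tracks["H3K27ac"].depth["chr1"]
        window = arr[10_000:13_000]
        se = np.sqrt(20.0 / window.size)
        assert abs(window.mean() - 20.0) <= 4 * se

    def test_planted_enrichment_over_carrier(self, truth):
        tracks = simulate_coverage(
            truth, CoverageSpec(background_depth=20.0, enrichment=5.0), seed=0
        )
        arr = tracks["H3K27ac"].depth["chr1"]
        carriers = truth.te_truth[truth.te_truth["carrier"]]
        te = carriers.iloc[0]
        ratio = arr[te.start : te.end].mean() / 20.0
        assert 4.0 <= ratio <= 6.0

    def test_zero_background_all_zero(self, truth):
        tracks = simulate_coverage(
            truth, CoverageSpec(background_depth=0.0, enrichment=1.0), seed=0
        )
        assert all((a == 0).all() for a in tracks["H3K27ac"].depth.values())
        assert tracks["H3K27ac"].library_size == 0.0

    def test_library_size_is_total_counts(self, truth):
        tracks = simulate_coverage(
            truth, CoverageSpec(background_depth=5.0, enrichment=2.0), seed=0
        )
        t = tracks["H3K27ac"]
        assert t.library_size == sum(a.sum() for a in t.depth.values())


class TestSimulateReporter:
    def test_table_shapes(self):
        constructs = pd.DataFrame(
            {"construct": [f"c{i}" for i in range(5)], "variant_class": ["wt"] * 5}
        )
        spec = ReporterSpec()
        luc, barcodes, truth = simulate_reporter(spec, constructs, 0)
        assert len(barcodes) == 5 * 8 * 3
        assert len(luc) == 5 * 3 * 3
        assert len(truth) == 5

    def test_all_unit_folds_cluster_at_one(self):
        constructs = pd.DataFrame(
            {"construct": ["basal", "a", "b", "c"],
             "variant_class": ["basal", "u", "u", "u"]}
        )
        spec = ReporterSpec(fold_changes={"u": 1.0}, depth=1000.0)
        from tecrm.reporter import cre_expression

        meds = []
        for seed in range(10):
            _, barcodes, _ = simulate_reporter(spec, constructs, seed)
            meds.extend(
                p.fold_change for p in cre_expression(barcodes, ["basal"])
            )
        assert 0.9 <= np.median(meds) <= 1.1

    def test_infinite_depth_limit(self):
        """depth 1e5, dispersion 0: per-barcode ratio ~ basal x fold within 1%."""
        constructs = pd.DataFrame(
            {"construct": ["x"], "variant_class": ["wt"]}
        )
        spec = ReporterSpec(fold_changes={"wt": 4.0}, depth=1e5, dispersion=0.0,
                            basal_mean_ratio=0.5)
        _, barcodes, _ = simulate_reporter(spec, constructs, 1)
        ratio = barcodes["cdna"] / barcodes["dna"]
        assert np.allclose(ratio, 0.5 * 4.0, rtol=0.01)

    def test_unknown_variant_class_raises(self):
        constructs = pd.DataFrame({"construct": ["x"], "variant_class": ["nope"]})
        with pytest.raises(KeyError):
            simulate_reporter(ReporterSpec(), constructs, 0)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ReporterSpec(barcodes_per_construct=4)
        with pytest.raises(ValueError):
            ReporterSpec(depth=0)
        with pytest.raises(ValueError):
            ReporterSpec(fold_changes={"bad": -1.0})


class TestSpecValidation:
    def test_bad_consensus(self):
        with pytest.raises(ValueError):
            SubfamilySpec("S", "ACGX", 10, 0.05)

    def test_bad_rate(self):
        with pytest.raises(ValueError):
            SubfamilySpec("S", "ACGT" * 10, 10, 1.5)

    def test_module_subfamily_must_exist(self):
        with pytest.raises(ValueError):
            config(
                planted_module_spec=ModuleSpec(
                    subfamily="Ghost", pwm_names=("Esrrb",), carrier_fraction=0.5
                )
            )
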