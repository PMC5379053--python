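"""End-to-end pipeline orchestration over the synthetic-data generator.

A single YAML config (key: value) drives simulation and every analysis stage
in order — cluster, enrich, scan, age, profile, reporter — with all tunables
defaulting to the study's stated values. Each run writes stage TSVs, plus a
machine-readable manifest (seed, config hash, package version) sufficient to
reproduce the run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, enrichment, evolution, io, profiles, reporter, simulate
from .intervals import TFSite, assign_clusters_to_tes, cluster_sites, GenomicInterval

#: every tunable with its default (the study's stated value) and valid range
DEFAULTS: dict[str, tuple[float, float, float]] = {
    # name: (default, min, max)
    "peak_extension": (200, 2, 10_000),
    "cluster_gap": (100, 0, 100_000),
    "motif_pvalue": (1e-3, 1e-12, 1.0),
    "min_elements": (10, 1, 10_000),
    "lor_threshold": (4.5, 0.0, 64.0),
    "lor_strong": (6.0, 0.0, 64.0),
    "enrich_pvalue": (1e-3, 1e-12, 1.0),
    "max_ltr_span": (7_000, 1, 1_000_000),
    "rate_fast": (0.012, 1e-6, 1.0),
    "rate_slow": (0.0005, 1e-6, 1.0),
    "gene_window": (50_000, 0, 10_000_000),
    "profile_bin": (50, 1, 10_000),
    "profile_flank": (1_500, 50, 1_000_000),
    "enhancer_fold": (2.0, 0.0, 1e6),
    "strong_enhancer_fold": (10.0, 0.0, 1e6),
    # simulation knobs
    "genome_length": (5_000_000, 10_000, 100_000_000),
    "n_chromosomes": (1, 1, 100),
    "n_subfamilies": (6, 1, 100),
    "copies_per_subfamily": (100, 1, 100_000),
    "consensus_length": (300, 50, 100_000),
    "sub_rate": (0.05, 0.0, 1.0),
    "carrier_fraction": (0.5, 0.0, 1.0),
    "background_peak_rate": (10.0, 0.0, 10_000.0),
    "n_ltr_pairs": (100, 0, 100_000),
    "ltr_true_time": (13.0, 0.0, 1_000.0),
    "ltr_rate": (5e-4, 1e-6, 1.0),
    "ltr_internal_span": (6_500, 1, 1_000_000),
    "coverage_background": (20.0, 0.0, 1e6),
    "coverage_enrichment": (5.0, 1.0, 1e6),
    "reporter_depth": (1_000.0, 1.0, 1e9),
    "reporter_dispersion": (0.1, 0.0, 5.0),
    "seed": (0, 0, 2**31 - 1),
}


class PipelineError(RuntimeError):
    """A stage-named pipeline failure."""


def validate_config(cfg: dict | None) -> dict:
    """Fill defaults, reject unknown keys and out-of-range values."""
    cfg = dict(cfg or {})
    unknown = set(cfg) - set(DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    out = {}
    for key, (default, lo, hi) in DEFAULTS.items():
        val = cfg.get(key, default)
        if not (lo <= float(val) <= hi):
            raise ValueError(f"config key {key}={val} outside valid range [{lo}, {hi}]")
        out[key] = type(default)(val)
    return out


def _sim_config(cfg: dict, rng: np.random.Generator) -> simulate.SimConfig:
    n_sub = int(cfg["n_subfamilies"])
    length = int(cfg["consensus_length"])
    specs = []
    for i in range(n_sub):
        consensus = "".join(
            simulate.BASES[int(b)] for b in rng.integers(0, 4, length)
        )
        specs.append(
            simulate.SubfamilySpec(
                name=f"SimLTR{i + 1}",
                consensus=consensus,
                n_copies=int(cfg["copies_per_subfamily"]),
                sub_rate=float(cfg["sub_rate"]),
            )
        )
    module = simulate.ModuleSpec(
        subfamily="SimLTR1",
        pwm_names=("Esrrb", "Klf4", "Sox2"),
        carrier_fraction=float(cfg["carrier_fraction"]),
    )
    ltr = (
        simulate.LTRPairSpec(
            n_pairs=int(cfg["n_ltr_pairs"]),
            insertion_time_myr=float(cfg["ltr_true_time"]),
            rate_per_myr=float(cfg["ltr_rate"]),
            internal_span=int(cfg["ltr_internal_span"]),
        )
        if int(cfg["n_ltr_pairs"]) > 0
        else None
    )
    return simulate.SimConfig(
        genome_length=int(cfg["genome_length"]),
        n_chromosomes=int(cfg["n_chromosomes"]),
        subfamily_specs=tuple(specs),
        planted_module_spec=module,
        ltr_pair_spec=ltr,
        coverage_spec=simulate.CoverageSpec(
            background_depth=float(cfg["coverage_background"]),
            enrichment=float(cfg["coverage_enrichment"]),
        ),
        reporter_spec=simulate.ReporterSpec(
            depth=float(cfg["reporter_depth"]),
            dispersion=float(cfg["reporter_dispersion"]),
        ),
        seed=int(cfg["seed"]),
    )


def peaks_to_sites(peaks: pd.DataFrame) -> list[TFSite]:
    return [
        TFSite(
            interval=GenomicInterval(r.chrom, int(r.start), int(r.end)),
            tf=str(r.tf),
            kind="peak",
        )
        for r in peaks.itertuples()
    ]


def run_pipeline(cfg: dict | None, outdir: str | Path, log=print) -> Path:
    """Simulate the study conditions and run every analysis stage in order.

    Writes all stage TSVs plus ``manifest.json`` under ``outdir``; any stage
    failure aborts the run with a stage-named error.
    """
    cfg = validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:  # re-raise with the stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return result

        return deco

    @stage("simulate")
    def _sim():
        sim_cfg = _sim_config(cfg, np.random.default_rng(seed))
        genome, annotation, truth = simulate.simulate_genome(sim_cfg)
        io.write_fasta(simulate.genome_to_strings(genome), outdir / "genome.fa")
        io.write_rmsk(annotation, outdir / "te_annotation.tsv")
        io.write_chrom_sizes(truth.chrom_sizes, outdir / "chrom.sizes")
        truth.te_truth.to_csv(outdir / "truth_te.tsv", sep="\t", index=False)
        truth.motif_truth.to_csv(outdir / "truth_motifs.tsv", sep="\t", index=False)
        truth.ltr_truth.to_csv(outdir / "truth_ltr.tsv", sep="\t", index=False)
        return genome, annotation, truth

    genome, annotation, truth = _sim
    log(f"simulate: {len(annotation)} annotation rows")

    @stage("cluster")
    def _cluster():
        peaks = simulate.simulate_peaks(
            truth, background_rate=float(cfg["background_peak_rate"]), seed=seed + 1
        )
        io.write_peaks_bed(peaks, outdir / "peaks.bed")
        sites = peaks_to_sites(peaks)
        clusters = cluster_sites(sites, gap=int(cfg["cluster_gap"]))
        tes = io.read_rmsk(outdir / "te_annotation.tsv")
        n_tfs = assign_clusters_to_tes(tes, clusters)
        per_te = pd.DataFrame(
            {
                "chrom": [t.interval.chrom for t in tes],
                "start": [t.interval.start for t in tes],
                "end": [t.interval.end for t in tes],
                "subfamily": [t.subfamily for t in tes],
                "n_tfs": n_tfs,
            }
        )
        per_te.to_csv(outdir / "per_te_binding.tsv", sep="\t", index=False)
        return tes, per_te

    tes, per_te = _cluster
    log(f"cluster: {int((per_te['n_tfs'] > 0).sum())} of {len(per_te)} TEs bound")

    @stage("enrich")
    def _enrich():
        table = enrichment.enrichment_scan(
            per_te["n_tfs"],
            per_te["subfamily"],
            min_elements=int(cfg["min_elements"]),
            lor_threshold=float(cfg["lor_threshold"]),
            p_threshold=float(cfg["enrich_pvalue"]),
        )
        table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        return table

    enrich_table = _enrich
    log(f"enrich: {int(enrich_table['flagged'].sum())} flagged rows")

    @stage("age")
    def _age():
        if truth.ltr_truth.empty:
            return pd.DataFrame()
        strings = simulate.genome_to_strings(genome)
        rows = []
        L = int(
            truth.ltr_truth["start3"].iloc[0] - truth.ltr_truth["start5"].iloc[0]
            - int(cfg["ltr_internal_span"])
        )
        for r in truth.ltr_truth.itertuples():
            seq = strings[r.chrom]
            a = seq[r.start5 : r.start5 + L]
            b = seq[r.start3 : r.start3 + L]
            d = float(np.mean([x != y for x, y in zip(a, b)]))
            rows.append(
                {
                    "pair_id": r.pair_id,
                    "chrom": r.chrom,
                    "span": int(cfg["ltr_internal_span"]),
                    "d": d,
                    "T_fast": evolution.insertion_time(d, float(cfg["rate_fast"])),
                    "T_slow": evolution.insertion_time(d, float(cfg["rate_slow"])),
                    "T_true_rate": evolution.insertion_time(d, float(cfg["ltr_rate"])),
                }
            )
        pairs = pd.DataFrame(rows)
        pairs.to_csv(outdir / "ltr_pairs.tsv", sep="\t", index=False)
        return pairs

    pairs = _age
    if not pairs.empty:
        log(f"age: {len(pairs)} LTR pairs, median T at true rate "
            f"{pairs['T_true_rate'].median():.1f} Myr")

    @stage("profile")
    def _profile():
        tracks = simulate.simulate_coverage(
            truth,
            simulate.CoverageSpec(
                background_depth=float(cfg["coverage_background"]),
                enrichment=float(cfg["coverage_enrichment"]),
            ),
            seed=seed + 2,
        )
        te_instances = [
            t for t in tes if not t.subfamily.startswith("SimERV")
        ]
        mask = ~per_te["subfamily"].str.startswith("SimERV")
        profs = profiles.category_profiles(
            te_instances,
            per_te.loc[mask, "n_tfs"].to_numpy(),
            list(tracks.values()),
            flank=int(cfg["profile_flank"]),
            bin_size=int(cfg["profile_bin"]),
        )
        frame = profiles.profiles_to_frame(profs)
        frame.to_csv(outdir / "metaprofiles.tsv", sep="\t", index=False)
        for mark, track in tracks.items():
            io.write_bedgraph(track, outdir / f"coverage_{mark}.bedGraph")
        io.write_library_sizes(tracks, outdir / "library_sizes.tsv")
        return frame

    prof_frame = _profile
    log(f"profile: {len(prof_frame)} profile rows")

    @stage("reporter")
    def _reporter():
        constructs = pd.DataFrame(
            {
                "construct": ["empty", "wt1", "wt2", "mut1", "mut3"],
                "variant_class": ["empty", "wt", "wt", "single_mut", "triple_mut"],
            }
        )
        spec = simulate.ReporterSpec(
            depth=float(cfg["reporter_depth"]),
            dispersion=float(cfg["reporter_dispersion"]),
        )
        luc, barcodes, rep_truth = simulate.simulate_reporter(spec, constructs, seed + 3)
        luc.to_csv(outdir / "luciferase.tsv", sep="\t", index=False)
        barcodes.to_csv(outdir / "barcodes.tsv", sep="\t", index=False)
        rep_truth.to_csv(outdir / "truth_reporter.tsv", sep="\t", index=False)
        pots = reporter.cre_expression(barcodes, basal_ids=["empty"])
        pd.DataFrame(
            [
                {
                    "construct": p.construct,
                    "fold_change": p.fold_change,
                    "sd": p.sd,
                    "class": p.enhancer_class,
                }
                for p in pots
            ]
        ).to_csv(outdir / "reporter_potential.tsv", sep="\t", index=False)
        return pots

    pots = _reporter
    log(f"reporter: {len(pots)} constructs quantified")

    manifest = {
        "package": "tecrm",
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
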