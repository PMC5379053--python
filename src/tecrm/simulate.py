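"""Synthetic genome and assay-data generator with known ground truth.

Every pipeline stage can be exercised without external data: a toy genome
carries TE subfamily copies mutated i.i.d. from a consensus (Jukes-Cantor
generative model: each substituted site is replaced by one of the three
alternative bases uniformly), one subfamily carries a planted module of TF
binding motifs in a fraction of its copies, paired LTRs diverge from a known
insertion time, coverage tracks are Poisson with planted enrichment over the
module carriers, and reporter tables carry planted fold changes.

All randomness flows through one integer seed; identical (config, seed)
reproduce every output bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import BASES, PWM, revcomp
from .profiles import CoverageTrack

__all__ = [
    "CapacityError",
    "SubfamilySpec",
    "ModuleSpec",
    "LTRPairSpec",
    "CoverageSpec",
    "ReporterSpec",
    "SimConfig",
    "TruthSet",
    "default_pwms",
    "simulate_genome",
    "simulate_peaks",
    "simulate_ltr_pairs",
    "simulate_coverage",
    "simulate_reporter",
    "genome_to_strings",
]


class CapacityError(RuntimeError):
    """Raised when non-overlapping TE placement fails (genome too small)."""


_PLACEMENT_RETRIES = 1_000


def _strong_pwm(name: str, consensus: str, dominant: float = 0.85) -> PWM:
    """A synthetic PWM whose consensus is the given string (dominant base
    probability ``dominant``, remainder spread over the other bases)."""
    L = len(consensus)
    probs = np.full((4, L), (1.0 - dominant) / 3.0)
    for l, b in enumerate(consensus):
        probs[BASES.index(b), l] = dominant
    return PWM(name=name, probs=probs)


def default_pwms() -> dict[str, PWM]:
    """Synthetic stand-in motifs for the five pluripotency TFs.

    The consensus strings follow the well-known core recognition sequences
    (Esrrb TCAAGGTCA, Klf4 GGGGTGGGG, Sox2 CATTGTA, Oct4 ATGCAAAT, Nanog
    CCATTAAC); the matrices themselves are synthetic, not database entries.
    """
    return {
        "Esrrb": _strong_pwm("Esrrb", "TCAAGGTCA"),
        "Klf4": _strong_pwm("Klf4", "GGGGTGGGG"),
        "Sox2": _strong_pwm("Sox2", "CATTGTA"),
        "Oct4": _strong_pwm("Oct4", "ATGCAAAT"),
        "Nanog": _strong_pwm("Nanog", "CCATTAAC"),
    }


def best_site(pwm: PWM) -> str:
    """The single best-scoring sequence under the PWM's log-odds."""
    return "".join(BASES[int(b)] for b in np.argmax(pwm.log_odds, axis=0))


@dataclass(frozen=True)
class SubfamilySpec:
    name: str
    consensus: str
    n_copies: int
    sub_rate: float
    family: str = "ERVK"
    te_class: str = "LTR"

    def __post_init__(self) -> None:
        if not self.consensus or set(self.consensus.upper()) - set(BASES):
            raise ValueError(f"{self.name}: consensus must be non-empty A/C/G/T")
        if self.n_copies < 1:
            raise ValueError(f"{self.name}: copy number must be >= 1")
        if not (0.0 <= self.sub_rate <= 1.0):
            raise ValueError(f"{self.name}: substitution rate must lie in [0, 1]")


@dataclass(frozen=True)
class ModuleSpec:
    """A planted ordered run of TF motifs in a fraction of one subfamily."""

    subfamily: str
    pwm_names: tuple[str, ...]
    carrier_fraction: float
    gap: int = 5  # bp between consecutive planted motifs
    offset: int = 10  # bp from the element 5' end to the first motif

    def __post_init__(self) -> None:
        if not (0.0 <= self.carrier_fraction <= 1.0):
            raise ValueError("carrier_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class LTRPairSpec:
    n_pairs: int
    insertion_time_myr: float
    rate_per_myr: float
    internal_span: int = 6_500
    ltr_length: int = 300
    subfamily: str = "SimERV-LTR"

    def __post_init__(self) -> None:
        if self.insertion_time_myr < 0:
            raise ValueError("insertion time must be >= 0")
        if self.rate_per_myr <= 0:
            raise ValueError("mutation rate must be > 0")


@dataclass(frozen=True)
class CoverageSpec:
    background_depth: float
    enrichment: float
    marks: tuple[str, ...] = ("H3K27ac",)
    cell_type: str = "ESC"

    def __post_init__(self) -> None:
        if self.background_depth < 0:
            raise ValueError("background depth must be >= 0")
        if self.enrichment < 1:
            raise ValueError("enrichment factor must be >= 1")


@dataclass(frozen=True)
class ReporterSpec:
    basal_mean_ratio: float = 0.5
    fold_changes: Mapping[str, float] = field(
        default_factory=lambda: {"wt": 10.0, "single_mut": 3.0, "triple_mut": 3.0}
    )
    barcodes_per_construct: int = 8
    depth: float = 1_000.0
    dispersion: float = 0.1
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.barcodes_per_construct != 8:
            raise ValueError("the CRE-seq design uses 8 barcodes per construct")
        if self.depth <= 0:
            raise ValueError("sequencing depth must be > 0")
        if any(f <= 0 for f in self.fold_changes.values()):
            raise ValueError("planted fold changes must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    genome_length: int = 1_000_000
    n_chromosomes: int = 1
    subfamily_specs: tuple[SubfamilySpec, ...] = ()
    planted_module_spec: ModuleSpec | None = None
    ltr_pair_spec: LTRPairSpec | None = None
    coverage_spec: CoverageSpec | None = None
    reporter_spec: ReporterSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1 or self.n_chromosomes < 1:
            raise ValueError("genome_length and n_chromosomes must be >= 1")
        if self.planted_module_spec is not None:
            names = {s.name for s in self.subfamily_specs}
            if self.planted_module_spec.subfamily not in names:
                raise ValueError("planted module subfamily not among subfamily_specs")


@dataclass
class TruthSet:
    """Ground truth for every planted entity."""

    te_truth: pd.DataFrame  # chrom,start,end,strand,subfamily,carrier,divergence_p
    motif_truth: pd.DataFrame  # chrom,start,end,strand,tf,te_index
    ltr_truth: pd.DataFrame  # pair_id,chrom,true_T,rate,realized_d,coords
    reporter_truth: pd.DataFrame  # construct,variant_class,fold_change
    chrom_sizes: dict[str, int] = field(default_factory=dict)


def _encode(seq: str) -> np.ndarray:
    return np.array([BASES.index(b) for b in seq.upper()], dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return lut[codes].tobytes().decode()


def genome_to_strings(genome: Mapping[str, np.ndarray]) -> dict[str, str]:
    return {c: _decode(a) for c, a in genome.items()}


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. substitutions: each site flips with prob ``rate`` to one of the
    three alternative bases uniformly (Jukes-Cantor generative model)."""
    out = codes.copy()
    if rate <= 0:
        return out
    hit = rng.random(codes.size) < rate
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out


def _place(
    occupied: dict[str, np.ndarray],
    length: int,
    rng: np.random.Generator,
) -> tuple[str, int]:
    """Uniform non-overlapping placement by rejection sampling."""
    chroms = sorted(occupied)
    sizes = np.array([occupied[c].size for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    for _ in range(_PLACEMENT_RETRIES):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        limit = occupied[chrom].size - length
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit))
        if not occupied[chrom][start : start + length].any():
            occupied[chrom][start : start + length] = True
            return chrom, start
    raise CapacityError(
        f"could not place a {length}-bp element after {_PLACEMENT_RETRIES} retries; "
        "genome too small or too crowded"
    )


def simulate_ltr_pairs(
    spec: LTRPairSpec, seed: int | np.random.Generator
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate paired LTR sequences diverged from a known insertion time.

    Each pair starts as one ancestral sequence; both copies then accumulate
    substitutions independently with per-site probability r*T, so the
    expected pairwise difference proportion is ~2rT at low divergence.
    Returns the sequence pairs and a truth table with the realized d.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_sub = min(spec.rate_per_myr * spec.insertion_time_myr, 0.75)
    pairs: list[tuple[str, str]] = []
    rows = []
    for i in range(spec.n_pairs):
        ancestral = rng.integers(0, 4, spec.ltr_length).astype(np.uint8)
        a = _mutate(ancestral, p_sub, rng)
        b = _mutate(ancestral, p_sub, rng)
        d = float((a != b).mean())
        pairs.append((_decode(a), _decode(b)))
        rows.append(
            {
                "pair_id": f"pair{i}",
                "true_T": spec.insertion_time_myr,
                "rate": spec.rate_per_myr,
                "realized_d": d,
            }
        )
    return pairs, pd.DataFrame(rows)


def simulate_genome(
    config: SimConfig, pwms: Mapping[str, PWM] | None = None
) -> tuple[dict[str, np.ndarray], pd.DataFrame, TruthSet]:
    """Generate the toy genome, its rmsk-style annotation and the truth set.

    Each TE copy is the subfamily consensus with i.i.d. substitutions at the
    spec'd rate, placed uniformly without overlap; module-carrier copies of
    the planted subfamily additionally contain one exact best-scoring site
    per planted PWM, in order, in their 5' (upstream) half. The annotation
    records the realized divergence of every copy (milliDiv).
    """
    rng = np.random.default_rng(config.seed)
    pwms = dict(pwms or default_pwms())
    genome = {
        f"chr{i + 1}": rng.integers(0, 4, config.genome_length).astype(np.uint8)
        for i in range(config.n_chromosomes)
    }
    occupied = {c: np.zeros(a.size, dtype=bool) for c, a in genome.items()}
    chrom_sizes = {c: a.size for c, a in genome.items()}

    ann_rows, te_rows, motif_rows = [], [], []
    module = config.planted_module_spec
    te_index = 0
    for spec in config.subfamily_specs:
        consensus = _encode(spec.consensus)
        n_carriers = 0
        if module is not None and spec.name == module.subfamily:
            n_carriers = int(round(module.carrier_fraction * spec.n_copies))
        carrier_ids = set(rng.choice(spec.n_copies, n_carriers, replace=False).tolist())
        for copy_i in range(spec.n_copies):
            codes = _mutate(consensus, spec.sub_rate, rng)
            planted_here: list[tuple[int, str, int]] = []  # (offset5p, tf, length)
            if copy_i in carrier_ids:
                pos = module.offset
                for tf in module.pwm_names:
                    site = _encode(best_site(pwms[tf]))
                    if pos + site.size > codes.size:
                        raise CapacityError(
                            f"consensus of {spec.name} too short for the module"
                        )
                    codes[pos : pos + site.size] = site
                    planted_here.append((pos, tf, site.size))
                    pos += site.size + module.gap
            divergence_p = float((codes != consensus).mean())
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = codes if strand == "+" else _encode(revcomp(_decode(codes)))
            chrom, start = _place(occupied, inserted.size, rng)
            genome[chrom][start : start + inserted.size] = inserted
            end = start + inserted.size
            ann_rows.append(
                {
                    "chrom": chrom,
                    "genoStart": start,
                    "genoEnd": end,
                    "strand": strand,
                    "repName": spec.name,
                    "repClass": spec.te_class,
                    "repFamily": spec.family,
                    "milliDiv": round(divergence_p * 1000, 1),
                }
            )
            te_rows.append(
                {
                    "te_index": te_index,
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "subfamily": spec.name,
                    "carrier": copy_i in carrier_ids,
                    "divergence_p": divergence_p,
                }
            )
            for off5p, tf, length in planted_here:
                if strand == "+":
                    mstart = start + off5p
                else:
                    mstart = end - off5p - length
                motif_rows.append(
                    {
                        "chrom": chrom,
                        "start": mstart,
                        "end": mstart + length,
                        "strand": strand,
                        "tf": tf,
                        "te_index": te_index,
                    }
                )
            te_index += 1

    ltr_rows = []
    if config.ltr_pair_spec is not None:
        spec = config.ltr_pair_spec
        seqs, ltr_truth = simulate_ltr_pairs(spec, rng)
        coords = []
        for i, (sa, sb) in enumerate(seqs):
            total = 2 * spec.ltr_length + spec.internal_span
            chrom, start = _place(occupied, total, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            a, b = _encode(sa), _encode(sb)
            genome[chrom][start : start + spec.ltr_length] = a
            b_start = start + spec.ltr_length + spec.internal_span
            genome[chrom][b_start : b_start + spec.ltr_length] = b
            for s in (start, b_start):
                ann_rows.append(
                    {
                        "chrom": chrom,
                        "genoStart": s,
                        "genoEnd": s + spec.ltr_length,
                        "strand": strand,
                        "repName": spec.subfamily,
                        "repClass": "LTR",
                        "repFamily": "ERVK",
                        "milliDiv": float("nan"),
                    }
                )
            coords.append(
                {"chrom": chrom, "start5": start, "start3": b_start, "strand": strand}
            )
        ltr_rows = pd.concat([ltr_truth, pd.DataFrame(coords)], axis=1)
    ltr_truth_df = (
        ltr_rows
        if isinstance(ltr_rows, pd.DataFrame)
        else pd.DataFrame(
            columns=["pair_id", "true_T", "rate", "realized_d", "chrom",
                     "start5", "start3", "strand"]
        )
    )

    annotation = pd.DataFrame(ann_rows)
    truth = TruthSet(
        te_truth=pd.DataFrame(te_rows),
        motif_truth=pd.DataFrame(
            motif_rows, columns=["chrom", "start", "end", "strand", "tf", "te_index"]
        ),
        ltr_truth=ltr_truth_df,
        reporter_truth=pd.DataFrame(columns=["construct", "variant_class", "fold_change"]),
        chrom_sizes=chrom_sizes,
    )
    return genome, annotation, truth


def simulate_peaks(
    truth: TruthSet,
    background_rate: float,
    seed: int,
    tf_names: Sequence[str] | None = None,
    peak_width: int = 200,
) -> pd.DataFrame:
    """Per-TF peak table: one peak centered on each planted motif instance,
    plus uniform background peaks at ``background_rate`` peaks/Mb/TF.

    Planted peaks are deterministic given the truth set; only the background
    depends on the seed. Peaks are clipped at chromosome bounds.
    """
    if background_rate < 0:
        raise ValueError("background rate must be >= 0")
    rng = np.random.default_rng(seed)
    half = peak_width // 2
    rows = []
    for m in truth.motif_truth.itertuples():
        center = (m.start + m.end) // 2
        size = truth.chrom_sizes[m.chrom]
        rows.append(
            {
                "chrom": m.chrom,
                "start": max(0, center - half),
                "end": min(size, center + half),
                "tf": m.tf,
                "origin": "planted",
            }
        )
    tfs = list(tf_names) if tf_names is not None else sorted(
        set(truth.motif_truth["tf"]) | {"Oct4", "Nanog"}
    )
    total_mb = sum(truth.chrom_sizes.values()) / 1e6
    chroms = sorted(truth.chrom_sizes)
    sizes = np.array([truth.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    for tf in tfs:
        n_bg = int(rng.poisson(background_rate * total_mb))
        for _ in range(n_bg):
            chrom = chroms[int(rng.choice(len(chroms), p=probs))]
            center = int(rng.integers(0, truth.chrom_sizes[chrom]))
            rows.append(
                {
                    "chrom": chrom,
                    "start": max(0, center - half),
                    "end": min(truth.chrom_sizes[chrom], center + half),
                    "tf": tf,
                    "origin": "background",
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "tf", "origin"]
    ).sort_values(["chrom", "start", "tf"], kind="stable").reset_index(drop=True)


def simulate_coverage(
    truth: TruthSet, spec: CoverageSpec, seed: int
) -> dict[str, CoverageTrack]:
    """Poisson coverage tracks with planted enrichment over module carriers.

    Depth is Poisson at the background mean everywhere; over module-carrier
    TEs the mean is multiplied by the enrichment factor. Library size is the
    total generated read-equivalents of the track.
    """
    rng = np.random.default_rng(seed)
    carriers = truth.te_truth[truth.te_truth["carrier"]]
    tracks = {}
    for mark in spec.marks:
        depth = {
            c: rng.poisson(spec.background_depth, size).astype(np.float64)
            for c, size in sorted(truth.chrom_sizes.items())
        }
        for te in carriers.itertuples():
            seg = te.end - te.start
            depth[te.chrom][te.start : te.end] = rng.poisson(
                spec.background_depth * spec.enrichment, seg
            )
        library = float(sum(a.sum() for a in depth.values()))
        tracks[mark] = CoverageTrack(
            depth=depth,
            library_size=library,
            mark=mark,
            cell_type=spec.cell_type,
        )
    return tracks


def simulate_reporter(
    spec: ReporterSpec, constructs: pd.DataFrame, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Luciferase and CRE-seq barcode tables with planted fold changes.

    ``constructs`` columns: construct, variant_class. Fold changes come from
    ``spec.fold_changes`` (class "basal"/"empty" is fixed at 1). DNA counts
    are Poisson(depth); cDNA counts are Poisson(depth * basal * fold *
    lognormal noise at the spec'd dispersion). Luciferase firefly/renilla
    pairs are drawn so each construct's expected ratio over the empty vector
    equals its planted fold change. Returns (luciferase, barcodes, truth).
    """
    rng = np.random.default_rng(seed)
    folds = dict(spec.fold_changes)
    luc_rows, bc_rows, truth_rows = [], [], []

    def fold_of(variant: str) -> float:
        if variant in ("basal", "empty"):
            return 1.0
        if variant not in folds:
            raise KeyError(f"no planted fold change for variant class {variant!r}")
        return folds[variant]

    all_constructs = list(constructs.itertuples())
    for row in all_constructs:
        fold = fold_of(row.variant_class)
        truth_rows.append(
            {"construct": row.construct, "variant_class": row.variant_class,
             "fold_change": fold}
        )
        for exp in range(1, spec.n_replicates + 1):
            for tech in range(1, spec.n_replicates + 1):
                renilla = 100.0 * rng.lognormal(0.0, spec.dispersion)
                firefly = (
                    renilla
                    * spec.basal_mean_ratio
                    * fold
                    * rng.lognormal(0.0, spec.dispersion)
                )
                luc_rows.append(
                    {
                        "construct": row.construct,
                        "firefly": firefly,
                        "renilla": renilla,
                        "experiment": exp,
                        "technical": tech,
                    }
                )
        for rep in range(1, spec.n_replicates + 1):
            for bc in range(spec.barcodes_per_construct):
                dna = int(rng.poisson(spec.depth))
                noise = rng.lognormal(0.0, spec.dispersion)
                cdna = int(
                    rng.poisson(spec.depth * spec.basal_mean_ratio * fold * noise)
                )
                bc_rows.append(
                    {
                        "construct": row.construct,
                        "barcode": f"{row.construct}_bc{bc}",
                        "replicate": rep,
                        "dna": dna,
                        "cdna": cdna,
                    }
                )
    return pd.DataFrame(luc_rows), pd.DataFrame(bc_rows), pd.DataFrame(truth_rows)
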