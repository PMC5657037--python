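"""Synthetic paired tumor/normal data on two platforms, with emulated callers.

The generator reproduces the study design the pipeline is built for,
with no external data:

* a spike-in truth set of somatic SNVs stratified by exome coverage
  (100 variants per stratum at depths <=8x, <=14x, <=200x, <=500x,
  <=800x and >800x, plus 100 in regions covered only by the genome),
  allele fractions drawn over a configurable range;
* germline heterozygous variants (allele fraction ~0.5 in both samples)
  and background noise sites;
* tumor/normal coverage imbalance up to a configurable maximum (the
  *coverdiff* parameter) and optional cross-contamination of the normal
  sample with tumor reads;
* two emulated callers over the site-level observations: a liberal
  tumor-only multinomial caller (VCMM-style: minimum depth 5, minimum
  alt depth 2, quality threshold, never consults the normal) and a
  conservative normal-penalizing caller (MuTect-style: minimum alt
  depth 2, tumor LOD threshold, KEEP/REJECT judgement with failure
  reasons such as ``alt_allele_in_normal``).

Simulation is site-level (depths, allele counts, summary qualities),
not read-level: it produces exactly the quantities the 108 features
consume.  Everything is deterministic under ``SimConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import binom as binom_dist

from . import caller_io
from .caller_io import ExomeTargets
from .sites import Caller, CallerRecord, GenomicSite, Platform, SourceId

GENOME_ONLY = "GENOME_ONLY"

_BASES = "ACGT"


@dataclass
class SimConfig:
    """Parameters of the synthetic study design (defaults = study conditions)."""

    n_per_stratum: int = 100
    exome_depth_strata: tuple = (8, 14, 200, 500, 800, math.inf)
    n_genome_only: int = 100
    allele_fraction_range: tuple = (0.05, 1.0)
    genome_mean_depth: float = 30.0
    exome_mean_depth: float = 150.0
    coverdiff_max: float = 0.5
    contamination_fraction: float = 0.0
    n_germline: int = 500
    n_background: int = 1000
    error_rate: float = 0.001
    seed: int = 0
    # layout of the synthetic contig and its exome target tiling
    contig: str = "chr1"
    contig_length: int = 2_000_000
    target_span: int = 1000
    target_period: int = 2000
    # emulated-caller thresholds (beyond the published minima, these are
    # artifact-chosen constants recorded in the manifest)
    vcmm_min_depth: int = 5
    vcmm_min_alt: int = 2
    vcmm_quality_threshold: float = 20.0
    mutect_min_alt: int = 2
    tumor_lod_threshold: float = 6.3
    normal_lod_threshold: float = 2.2
    normal_af_threshold: float = 0.03
    # simulated database membership
    dbsnp_germline_p: float = 0.9
    dbsnp_somatic_p: float = 0.02
    dbsnp_background_p: float = 0.02
    cosmic_somatic_p: float = 0.3
    cosmic_other_p: float = 0.01

    def __post_init__(self) -> None:
        strata = tuple(self.exome_depth_strata)
        if list(strata) != sorted(strata) or len(set(strata)) != len(strata):
            raise ValueError("exome depth strata must be strictly increasing")
        if not (0.0 <= self.coverdiff_max < 1.0):
            raise ValueError("coverdiff_max must be in [0,1)")
        if not (0.0 <= self.contamination_fraction <= 0.1):
            raise ValueError("contamination_fraction must be in [0, 0.1]")
        lo, hi = self.allele_fraction_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("allele fractions must lie in (0,1]")

    @property
    def stratum_labels(self) -> list[str]:
        labels = []
        for bound in self.exome_depth_strata:
            labels.append(f"le{int(bound)}" if math.isfinite(bound) else f"gt{int(self.exome_depth_strata[-2])}")
        return labels

    def stratum_bounds(self, label: str) -> tuple[int, int]:
        """Inclusive tumor exome depth bounds for one stratum label."""
        lower = 1
        for bound, lab in zip(self.exome_depth_strata, self.stratum_labels):
            upper = int(bound) if math.isfinite(bound) else int(1.5 * self.exome_depth_strata[-2])
            if lab == label:
                return lower, upper
            lower = int(bound) + 1
        raise KeyError(label)


@dataclass(frozen=True)
class TruthVariant:
    site: GenomicSite
    allele_fraction: float
    stratum: str


@dataclass
class SiteObservation:
    """Site-level sequencing evidence for one (site, platform, sample)."""

    site: GenomicSite
    platform: Platform
    sample: str  # tumor | normal
    depth: int
    alt_count: int
    alt_fwd: int
    alt_rev: int
    mean_baseq: float
    mean_mapq: float
    indel_score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.alt_count <= self.depth):
            raise ValueError(f"alt_count {self.alt_count} outside [0, depth={self.depth}]")
        if self.alt_fwd + self.alt_rev != self.alt_count:
            raise ValueError("strand counts must sum to alt_count")


@dataclass
class SimulatedData:
    cfg: SimConfig
    truth: list[TruthVariant]
    germline: list[GenomicSite]
    background: list[GenomicSite]
    observations: dict  # (site, Platform, sample) -> SiteObservation
    annotations: dict  # site -> {"dbsnp": bool, "cosmic": bool}
    targets: ExomeTargets

    @property
    def truth_sites(self) -> set[GenomicSite]:
        return {t.site for t in self.truth}


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def build_exome_targets(cfg: SimConfig) -> ExomeTargets:
    """Regular tiling: the first ``target_span`` bases of every period are exonic."""
    intervals = []
    start = 0
    while start + cfg.target_span <= cfg.contig_length:
        intervals.append((start + 1, start + cfg.target_span))  # 1-based closed
        start += cfg.target_period
    return ExomeTargets({cfg.contig: intervals})


def _draw_positions(rng, cfg: SimConfig, n: int, region: str, used: set[int]) -> list[int]:
    """Distinct positions inside/outside/anywhere relative to the target tiling."""
    out: list[int] = []
    span, period = cfg.target_span, cfg.target_period
    n_blocks = cfg.contig_length // period
    while len(out) < n:
        block = int(rng.integers(0, n_blocks))
        if region == "inside":
            offset = int(rng.integers(0, span))
        elif region == "outside":
            offset = span + int(rng.integers(0, period - span))
        else:
            offset = int(rng.integers(0, period))
        pos = block * period + offset + 1
        if pos not in used:
            used.add(pos)
            out.append(pos)
    return out


def _random_site(rng, cfg: SimConfig, pos: int) -> GenomicSite:
    ref = _BASES[int(rng.integers(0, 4))]
    alt = rng.choice([b for b in _BASES if b != ref])
    return GenomicSite(cfg.contig, pos, ref, str(alt))


def design_truth_set(cfg: SimConfig, _used: Optional[set] = None) -> list[TruthVariant]:
    """Spike-in truth set: n_per_stratum per exome-depth stratum plus
    n_genome_only variants outside the exome targets."""
    rng = np.random.default_rng([cfg.seed, 1])
    used = _used if _used is not None else set()
    lo, hi = cfg.allele_fraction_range
    truth: list[TruthVariant] = []
    for label in cfg.stratum_labels:
        for pos in _draw_positions(rng, cfg, cfg.n_per_stratum, "inside", used):
            truth.append(TruthVariant(_random_site(rng, cfg, pos), float(rng.uniform(lo, hi)), label))
    for pos in _draw_positions(rng, cfg, cfg.n_genome_only, "outside", used):
        truth.append(TruthVariant(_random_site(rng, cfg, pos), float(rng.uniform(lo, hi)), GENOME_ONLY))
    return truth


# ---------------------------------------------------------------------------
# observations
# ---------------------------------------------------------------------------

def _qualities(rng) -> tuple[float, float, float]:
    baseq = float(np.clip(rng.normal(30.0, 2.0), 10.0, 41.0))
    mapq = float(np.clip(rng.normal(55.0, 4.0), 0.0, 60.0))
    indel = float(rng.exponential(0.2))
    return round(baseq, 2), round(mapq, 2), round(indel, 3)


def _observe(rng, site, platform, sample, depth, alt_p) -> SiteObservation:
    depth = int(depth)
    alt = int(rng.binomial(depth, alt_p)) if depth > 0 else 0
    fwd = int(rng.binomial(alt, 0.5)) if alt > 0 else 0
    baseq, mapq, indel = _qualities(rng)
    return SiteObservation(site, platform, sample, depth, alt, fwd, alt - fwd, baseq, mapq, indel)


def simulate_observations(
    truth: Sequence[TruthVariant],
    n_germline: int,
    cfg: SimConfig,
    seed: Optional[int] = None,
) -> SimulatedData:
    """Draw per-(site, platform, sample) depths and allele counts.

    Tumor exome depth is forced into each truth variant's stratum
    (genome-only variants get exome depth 0); normal depth is the tumor
    depth scaled by a factor drawn from [1 - coverdiff_max, 1]; alt
    counts are binomial at the site allele fraction (somatic: tumor
    only; germline: ~0.5 in both; elsewhere the error rate).
    """
    rng = np.random.default_rng([cfg.seed if seed is None else seed, 2])
    targets = build_exome_targets(cfg)
    used = {t.site.pos for t in truth}
    germline = [_random_site(rng, cfg, p) for p in _draw_positions(rng, cfg, n_germline, "anywhere", used)]
    background = [_random_site(rng, cfg, p) for p in _draw_positions(rng, cfg, cfg.n_background, "anywhere", used)]

    annotations: dict = {}
    for t in truth:
        annotations[t.site] = {
            "dbsnp": bool(rng.random() < cfg.dbsnp_somatic_p),
            "cosmic": bool(rng.random() < cfg.cosmic_somatic_p),
        }
    for site in germline:
        annotations[site] = {
            "dbsnp": bool(rng.random() < cfg.dbsnp_germline_p),
            "cosmic": bool(rng.random() < cfg.cosmic_other_p),
        }
    for site in background:
        annotations[site] = {
            "dbsnp": bool(rng.random() < cfg.dbsnp_background_p),
            "cosmic": bool(rng.random() < cfg.cosmic_other_p),
        }

    observations: dict = {}

    def paired(site, platform, tumor_depth, tumor_p, normal_p):
        factor = float(rng.uniform(1.0 - cfg.coverdiff_max, 1.0))
        normal_depth = int(round(tumor_depth * factor)) if tumor_depth > 0 else 0
        observations[(site, platform, "tumor")] = _observe(rng, site, platform, "tumor", tumor_depth, tumor_p)
        observations[(site, platform, "normal")] = _observe(rng, site, platform, "normal", normal_depth, normal_p)

    e = cfg.error_rate
    for t in truth:
        genome_depth = max(1, int(rng.poisson(cfg.genome_mean_depth)))
        paired(t.site, Platform.WGS, genome_depth, t.allele_fraction, e)
        if t.stratum == GENOME_ONLY:
            exome_depth = 0
        else:
            lo, hi = cfg.stratum_bounds(t.stratum)
            exome_depth = int(rng.integers(lo, hi + 1))
        paired(t.site, Platform.WXS, exome_depth, t.allele_fraction, e)
    for site in germline:
        genome_depth = max(1, int(rng.poisson(cfg.genome_mean_depth)))
        exome_depth = max(1, int(rng.poisson(cfg.exome_mean_depth))) if targets.contains(site.chrom, site.pos) else 0
        paired(site, Platform.WGS, genome_depth, 0.5, 0.5)
        paired(site, Platform.WXS, exome_depth, 0.5, 0.5)
    for site in background:
        genome_depth = max(1, int(rng.poisson(cfg.genome_mean_depth)))
        exome_depth = max(1, int(rng.poisson(cfg.exome_mean_depth))) if targets.contains(site.chrom, site.pos) else 0
        paired(site, Platform.WGS, genome_depth, e, e)
        paired(site, Platform.WXS, exome_depth, e, e)

    return SimulatedData(cfg, list(truth), germline, background, observations, annotations, targets)


def contaminate_normal(data: SimulatedData, fraction: float, seed: Optional[int] = None) -> SimulatedData:
    """Mix tumor-derived reads into the normal sample at somatic sites.

    For each somatic site the normal alt count is regenerated as a
    mixture: binomial(normal depth, fraction) reads follow the tumor
    allele distribution (alt with probability = site allele fraction),
    the rest the normal noise distribution.  Depth is preserved.
    Returns a new SimulatedData; fraction 0 returns the input unchanged.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("contamination fraction must be in [0,1]")
    if fraction == 0.0:
        return data
    cfg = data.cfg
    rng = np.random.default_rng([cfg.seed if seed is None else seed, 3, int(round(fraction * 10000))])
    observations = dict(data.observations)
    for t in data.truth:
        for platform in (Platform.WGS, Platform.WXS):
            obs = observations.get((t.site, platform, "normal"))
            if obs is None or obs.depth == 0:
                continue
            tumor_reads = int(rng.binomial(obs.depth, fraction))
            alt = int(rng.binomial(tumor_reads, t.allele_fraction))
            alt += int(rng.binomial(obs.depth - tumor_reads, cfg.error_rate))
            fwd = int(rng.binomial(alt, 0.5)) if alt > 0 else 0
            observations[(t.site, platform, "normal")] = SiteObservation(
                obs.site, obs.platform, obs.sample, obs.depth, alt, fwd, alt - fwd, obs.mean_baseq, obs.mean_mapq, obs.indel_score
            )
    return SimulatedData(cfg, data.truth, data.germline, data.background, observations, data.annotations, data.targets)


# ---------------------------------------------------------------------------
# emulated callers
# ---------------------------------------------------------------------------

def _llr10(alt: int, depth: int, error_rate: float) -> float:
    """log10 likelihood ratio: binomial at the observed AF vs at the error rate."""
    if depth <= 0 or alt <= 0:
        return 0.0
    f = alt / depth
    llr = alt * math.log10(f / error_rate)
    if f < 1.0:
        llr += (depth - alt) * math.log10((1.0 - f) / (1.0 - error_rate))
    return llr


def _sorted_sites(data: SimulatedData) -> list[GenomicSite]:
    sites = {key[0] for key in data.observations}
    return sorted(sites, key=lambda s: s.sort_key)


def emulate_vcmm(data: SimulatedData, platform: Platform) -> list[CallerRecord]:
    """Liberal tumor-only caller: depth >= 5, alt >= 2, quality over threshold.

    Never consults the normal sample, so germline heterozygous sites
    with adequate depth are called — the caller's characteristic
    false-positive mode.
    """
    cfg = data.cfg
    platform = Platform(platform)
    source = SourceId(Caller.VCMM, platform)
    records: list[CallerRecord] = []
    for site in _sorted_sites(data):
        obs = data.observations.get((site, platform, "tumor"))
        if obs is None or obs.depth < cfg.vcmm_min_depth or obs.alt_count < cfg.vcmm_min_alt:
            continue
        quality = 10.0 * _llr10(obs.alt_count, obs.depth, cfg.error_rate)
        if quality < cfg.vcmm_quality_threshold:
            continue
        ann = data.annotations.get(site, {})
        fields = {
            "depth": obs.depth,
            "alt_depth": obs.alt_count,
            "snp_quality": round(quality, 2),
            "mapping_quality": obs.mean_mapq,
            "base_quality": obs.mean_baseq,
            "indel_score": obs.indel_score,
            "alt_fwd": obs.alt_fwd,
            "alt_rev": obs.alt_rev,
            "dbsnp_site": bool(ann.get("dbsnp", False)),
        }
        if fields["dbsnp_site"]:
            fields["dbsnp_id"] = f"rs{site.pos}"
        records.append(CallerRecord(site, source, fields))
    return records


def emulate_mutect(data: SimulatedData, platform: Platform) -> list[CallerRecord]:
    """Conservative paired caller: records every candidate with tumor alt >= 2,
    judged KEEP unless a rejection reason fires.

    Rejection reasons: ``alt_allele_in_normal`` when the normal alt
    fraction exceeds the threshold or the normal alt count reaches 2;
    ``fstar_tumor_lod`` when the tumor LOD is under its threshold;
    ``normal_lod`` when the normal looks insufficiently reference-like.
    """
    cfg = data.cfg
    platform = Platform(platform)
    source = SourceId(Caller.MUTECT, platform)
    records: list[CallerRecord] = []
    for site in _sorted_sites(data):
        tumor = data.observations.get((site, platform, "tumor"))
        normal = data.observations.get((site, platform, "normal"))
        if tumor is None or tumor.depth == 0 or tumor.alt_count < cfg.mutect_min_alt:
            continue
        n_depth = normal.depth if normal else 0
        n_alt = normal.alt_count if normal else 0
        t_lod = _llr10(tumor.alt_count, tumor.depth, cfg.error_rate)
        # log10 L(normal is clean) / L(normal is het)
        normal_lod = 0.0
        if n_depth > 0:
            normal_lod = (
                n_alt * math.log10(cfg.error_rate / 0.5)
                + (n_depth - n_alt) * math.log10((1.0 - cfg.error_rate) / 0.5)
            )
        reasons: list[str] = []
        if n_depth > 0 and (n_alt / n_depth > cfg.normal_af_threshold or n_alt >= 2):
            reasons.append("alt_allele_in_normal")
        if t_lod < cfg.tumor_lod_threshold:
            reasons.append("fstar_tumor_lod")
        if n_depth > 0 and normal_lod < cfg.normal_lod_threshold:
            if "alt_allele_in_normal" not in reasons:
                reasons.append("alt_allele_in_normal")
            reasons.append("normal_lod")
        ann = data.annotations.get(site, {})
        t_ref = tumor.depth - tumor.alt_count
        n_ref = n_depth - n_alt
        tumor_power = float(1.0 - binom_dist.cdf(1, tumor.depth, 0.3)) if tumor.depth > 0 else 0.0
        normal_power = float(1.0 - binom_dist.cdf(1, n_depth, 0.5)) if n_depth > 0 else 0.0
        fields = {
            "t_ref_count": t_ref,
            "t_alt_count": tumor.alt_count,
            "n_ref_count": n_ref,
            "n_alt_count": n_alt,
            "tumor_f": round(tumor.alt_count / tumor.depth, 6),
            "normal_f": round(n_alt / n_depth, 6) if n_depth > 0 else None,
            "t_lod_fstar": round(t_lod, 4),
            "init_t_lod": round(t_lod, 4),
            "normal_lod": round(normal_lod, 4),
            "t_alt_mean_baseq": tumor.mean_baseq,
            "t_ref_mean_baseq": tumor.mean_baseq,
            "n_mean_baseq": normal.mean_baseq if normal else None,
            "t_alt_mean_mapq": tumor.mean_mapq,
            "t_ref_mean_mapq": tumor.mean_mapq,
            "n_mean_mapq": normal.mean_mapq if normal else None,
            "t_alt_fwd": tumor.alt_fwd,
            "t_alt_rev": tumor.alt_rev,
            "t_ref_fwd": t_ref - t_ref // 2,
            "t_ref_rev": t_ref // 2,
            "n_alt_fwd": n_alt - n_alt // 2,
            "n_alt_rev": n_alt // 2,
            "power": round(tumor_power * normal_power, 6),
            "tumor_power": round(tumor_power, 6),
            "normal_power": round(normal_power, 6),
            "t_ins_count": int(tumor.indel_score > 1.0),
            "t_del_count": 0,
            "dbsnp_site": bool(ann.get("dbsnp", False)),
            "cosmic_site": bool(ann.get("cosmic", False)),
            "covered": True,
            "judgement": "KEEP" if not reasons else "REJECT",
            "failure_reasons": reasons,
        }
        fields = {k: v for k, v in fields.items() if v is not None}
        records.append(CallerRecord(site, source, fields))
    return records


def called_sites(records: Iterable[CallerRecord]) -> set[GenomicSite]:
    """The emitted call set: all VCMM records, KEEP-judged MuTect records."""
    out = set()
    for rec in records:
        if rec.get("judgement", "KEEP") == "KEEP":
            out.add(rec.site)
    return out


# ---------------------------------------------------------------------------
# end-to-end dataset
# ---------------------------------------------------------------------------

def simulate(cfg: SimConfig) -> SimulatedData:
    """Design the truth set, draw observations, apply contamination."""
    truth = design_truth_set(cfg)
    data = simulate_observations(truth, cfg.n_germline, cfg)
    if cfg.contamination_fraction > 0:
        data = contaminate_normal(data, cfg.contamination_fraction)
    return data


def generate_dataset(cfg: SimConfig, out_dir) -> dict:
    """Write the full synthetic dataset to disk; returns the file map.

    Outputs: truth and germline VCFs, one call_stats table and one VCMM
    table per platform, the exome target BED and a key=value manifest.
    Byte-identical under the same config and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = simulate(cfg)
    files = {
        "truth_vcf": out_dir / "truth.vcf",
        "germline_vcf": out_dir / "germline.vcf",
        "mutect_wgs": out_dir / "mutect_wgs.call_stats.tsv",
        "mutect_wxs": out_dir / "mutect_wxs.call_stats.tsv",
        "vcmm_wgs": out_dir / "vcmm_wgs.tsv",
        "vcmm_wxs": out_dir / "vcmm_wxs.tsv",
        "targets_bed": out_dir / "targets.bed",
        "manifest": out_dir / "manifest.txt",
    }
    truth_sorted = sorted(data.truth, key=lambda t: t.site.sort_key)
    caller_io.write_sites_vcf(
        files["truth_vcf"],
        [t.site for t in truth_sorted],
        info={t.site: {"AF": f"{t.allele_fraction:.4f}", "STRATUM": t.stratum} for t in truth_sorted},
    )
    caller_io.write_sites_vcf(files["germline_vcf"], sorted(data.germline, key=lambda s: s.sort_key))
    caller_io.write_mutect_callstats(emulate_mutect(data, Platform.WGS), files["mutect_wgs"])
    caller_io.write_mutect_callstats(emulate_mutect(data, Platform.WXS), files["mutect_wxs"])
    caller_io.write_vcmm_table(emulate_vcmm(data, Platform.WGS), files["vcmm_wgs"])
    caller_io.write_vcmm_table(emulate_vcmm(data, Platform.WXS), files["vcmm_wxs"])
    caller_io.write_bed(data.targets, files["targets_bed"])
    with open(files["manifest"], "wt") as fh:
        fh.write("# snvensemble synthetic dataset manifest\n")
        for key, value in asdict(cfg).items():
            fh.write(f"{key}={value}\n")
    return files
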