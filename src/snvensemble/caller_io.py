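"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
* MuTect ``call_stats`` dialect: tab-delimited, header-first, one row per
  candidate with tumor/normal evidence, a KEEP/REJECT judgement and a
  comma-separated list of failure reasons.  MuTect versions differ in
  their exact column sets, so this module pins one documented dialect
  (:data:`CALLSTATS_COLUMNS`); unknown extra columns are ignored.
* Canonical VCMM table: tab-delimited, 13 pinned columns
  (:data:`VCMM_COLUMNS`); the dbSNP flag is true iff the ``dbsnp_id``
  cell is non-empty.
* VCF 4.2 for auxiliary call sets, truth/germline sets and the
  classified output.
* BED for exome target intervals (0-based half-open on disk, converted
  to 1-based closed on read).

All tab-delimited readers accept plain or gzip-compressed input, and
``NA``, ``.`` and the empty string all decode to a missing value.
"""

from __future__ import annotations

import gzip
import io
import logging
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from cyvcf2 import VCF

from .sites import Caller, CallerRecord, GenomicSite, Platform, SourceId

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class RowError(FormatError):
    """A single data row could not be parsed; carries the line number."""


# ---------------------------------------------------------------------------
# pinned dialects
# ---------------------------------------------------------------------------

#: MuTect failure reasons modeled as individual indicator features.
MUTECT_FAILURE_REASONS: tuple[str, ...] = (
    "fstar_tumor_lod",
    "normal_lod",
    "alt_allele_in_normal",
    "possible_contamination",
    "germline_risk",
    "clustered_read_position",
    "strand_artifact",
    "poor_mapping_region_mapq0",
    "poor_mapping_region_alternate_allele_mapq",
    "triallelic_site",
    "nearby_gap_events",
    "seen_in_panel_of_normals",
)

#: Numeric evidence columns shared by the call_stats dialect and the
#: MuTect feature block (site key, flags and judgement columns excluded).
CALLSTATS_NUMERIC_FIELDS: tuple[str, ...] = (
    "t_ref_count",
    "t_alt_count",
    "n_ref_count",
    "n_alt_count",
    "tumor_f",
    "normal_f",
    "t_lod_fstar",
    "init_t_lod",
    "normal_lod",
    "t_alt_mean_baseq",
    "t_ref_mean_baseq",
    "n_mean_baseq",
    "t_alt_mean_mapq",
    "t_ref_mean_mapq",
    "n_mean_mapq",
    "t_alt_fwd",
    "t_alt_rev",
    "t_ref_fwd",
    "t_ref_rev",
    "n_alt_fwd",
    "n_alt_rev",
    "power",
    "tumor_power",
    "normal_power",
    "t_ins_count",
    "t_del_count",
)

#: call_stats dialect, version 1.  Header order is fixed for the writer;
#: the parser only requires that the required columns are present.
CALLSTATS_COLUMNS: tuple[str, ...] = (
    "contig",
    "position",
    "ref_allele",
    "alt_allele",
    "dbsnp_site",
    "cosmic_site",
    "covered",
) + CALLSTATS_NUMERIC_FIELDS + ("judgement", "failure_reasons")

_CALLSTATS_REQUIRED = ("contig", "position", "ref_allele", "alt_allele", "judgement")

#: Canonical VCMM table, version 1.
VCMM_COLUMNS: tuple[str, ...] = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "depth",
    "alt_depth",
    "snp_quality",
    "mapping_quality",
    "base_quality",
    "indel_score",
    "alt_fwd",
    "alt_rev",
    "dbsnp_id",
)

VCMM_NUMERIC_FIELDS: tuple[str, ...] = (
    "depth",
    "alt_depth",
    "snp_quality",
    "mapping_quality",
    "base_quality",
    "indel_score",
    "alt_fwd",
    "alt_rev",
)

_MISSING_TOKENS = frozenset({"NA", ".", ""})


def _open_text(path: PathLike) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _parse_number(cell: str, column: str, lineno: int):
    if cell in _MISSING_TOKENS:
        return None
    try:
        value = float(cell)
    except ValueError:
        raise RowError(f"line {lineno}: cannot parse {column}={cell!r} as a number") from None
    return int(value) if value.is_integer() and "." not in cell and "e" not in cell.lower() else value


def _parse_flag(cell: str, true_token: str):
    if cell in _MISSING_TOKENS:
        return None
    return cell.upper() == true_token


# ---------------------------------------------------------------------------
# MuTect call_stats
# ---------------------------------------------------------------------------

def parse_mutect_callstats(path: PathLike, platform: Platform) -> list[CallerRecord]:
    """Parse a MuTect call_stats table into one record per data row.

    The judgement is normalized to KEEP/REJECT and failure reasons are
    split on commas.  Numeric cells equal to ``NA``/``.``/empty are
    recorded as missing (absent from the field map).
    """
    platform = Platform(platform)
    records: list[CallerRecord] = []
    with _open_text(path) as fh:
        header: Optional[list[str]] = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                for col in _CALLSTATS_REQUIRED:
                    if col not in header:
                        raise FormatError(f"call_stats file {path} is missing required column {col!r}")
                unknown = set(header) - set(CALLSTATS_COLUMNS)
                if unknown:
                    logger.warning("call_stats %s: ignoring unknown columns %s", path, sorted(unknown))
                continue
            row = dict(zip(header, cells))
            fields: dict = {}
            for name in CALLSTATS_NUMERIC_FIELDS:
                if name in row:
                    value = _parse_number(row[name], name, lineno)
                    if value is not None:
                        fields[name] = value
            for name, token in (("dbsnp_site", "DBSNP"), ("cosmic_site", "COSMIC"), ("covered", "COVERED")):
                if name in row:
                    flag = _parse_flag(row[name], token)
                    if flag is not None:
                        fields[name] = flag
            judgement = row["judgement"].strip().upper()
            if judgement not in ("KEEP", "REJECT"):
                raise RowError(f"line {lineno}: judgement must be KEEP or REJECT, got {row['judgement']!r}")
            fields["judgement"] = judgement
            reasons_cell = row.get("failure_reasons", "")
            fields["failure_reasons"] = (
                [] if reasons_cell in _MISSING_TOKENS else [r.strip() for r in reasons_cell.split(",") if r.strip()]
            )
            try:
                site = GenomicSite(row["contig"], int(row["position"]), row["ref_allele"], row["alt_allele"])
            except ValueError as exc:
                raise RowError(f"line {lineno}: {exc}") from None
            records.append(CallerRecord(site, SourceId(Caller.MUTECT, platform), fields))
    if header is None:
        raise FormatError(f"call_stats file {path} has no header line")
    return records


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        raise TypeError("flags are formatted by their column writer")
    if isinstance(value, float):
        return format(value, ".6g")
    return str(value)


def write_mutect_callstats(records: Iterable[CallerRecord], path: PathLike) -> None:
    """Write records in the pinned call_stats dialect (inverse of the parser)."""
    with open(path, "wt") as fh:
        fh.write("## muTector-like call_stats, snvensemble dialect v1\n")
        fh.write("\t".join(CALLSTATS_COLUMNS) + "\n")
        for rec in records:
            row = [rec.site.chrom, str(rec.site.pos), rec.site.ref, rec.site.alt]
            for name, true_token, false_token in (
                ("dbsnp_site", "DBSNP", "NOVEL"),
                ("cosmic_site", "COSMIC", "NOVEL"),
                ("covered", "COVERED", "UNCOVERED"),
            ):
                flag = rec.get(name)
                row.append("NA" if flag is None else (true_token if flag else false_token))
            for name in CALLSTATS_NUMERIC_FIELDS:
                row.append(_fmt(rec.get(name)))
            row.append(rec.fields["judgement"])
            row.append(",".join(rec.get("failure_reasons", [])))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# canonical VCMM table
# ---------------------------------------------------------------------------

def parse_vcmm_table(path: PathLike, platform: Platform) -> list[CallerRecord]:
    """Parse the canonical VCMM table; dbSNP flag true iff dbsnp_id non-empty."""
    platform = Platform(platform)
    records: list[CallerRecord] = []
    with _open_text(path) as fh:
        header: Optional[list[str]] = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                for col in ("chrom", "pos", "ref", "alt"):
                    if col not in header:
                        raise FormatError(f"VCMM table {path} is missing required column {col!r}")
                continue
            row = dict(zip(header, cells))
            fields: dict = {}
            for name in VCMM_NUMERIC_FIELDS:
                if name in row:
                    value = _parse_number(row[name], name, lineno)
                    if value is not None:
                        fields[name] = value
            dbsnp_id = row.get("dbsnp_id", "")
            fields["dbsnp_site"] = dbsnp_id not in _MISSING_TOKENS
            if fields["dbsnp_site"]:
                fields["dbsnp_id"] = dbsnp_id
            try:
                site = GenomicSite(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            except ValueError as exc:
                raise RowError(f"line {lineno}: {exc}") from None
            records.append(CallerRecord(site, SourceId(Caller.VCMM, platform), fields))
    if header is None and not records:
        # an entirely empty file is an empty call set
        return []
    return records


def write_vcmm_table(records: Iterable[CallerRecord], path: PathLike) -> None:
    with open(path, "wt") as fh:
        fh.write("# canonical VCMM table, snvensemble dialect v1\n")
        fh.write("\t".join(VCMM_COLUMNS) + "\n")
        for rec in records:
            row = [rec.site.chrom, str(rec.site.pos), rec.site.ref, rec.site.alt]
            row.extend(_fmt(rec.get(name)) for name in VCMM_NUMERIC_FIELDS)
            row.append(rec.get("dbsnp_id", ".") if rec.get("dbsnp_site") else ".")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_META = """\
##fileformat=VCFv4.2
##source=snvensemble
##INFO=<ID=SCORE,Number=1,Type=Float,Description="Ensemble somatic probability">
##INFO=<ID=AF,Number=A,Type=Float,Description="Simulated allele fraction">
##INFO=<ID=STRATUM,Number=1,Type=String,Description="Simulated exome coverage stratum">
##FILTER=<ID=not_somatic,Description="Classified as not somatic by the ensemble model">
"""
_VCF_COLUMNS = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"


def _vcf_header(sites: Iterable[GenomicSite]) -> str:
    chroms = sorted({s.chrom for s in sites}, key=_natural_key_str)
    contig_lines = "".join(f"##contig=<ID={c}>\n" for c in chroms)
    return _VCF_META + contig_lines + _VCF_COLUMNS


def _natural_key_str(chrom: str):
    from .sites import _natural_chrom_key

    return _natural_chrom_key(chrom)


def read_vcf_calls(
    path: PathLike,
    caller_name: str,
    platform: Platform,
    pass_only: bool = True,
) -> list[CallerRecord]:
    """Read SNVs from a VCF call set; multi-allelic records are split per alt.

    By default only PASS records are returned (a caller's emitted call
    set); ``pass_only=False`` also returns filtered records, with the
    FILTER string kept in the field map.
    """
    platform = Platform(platform)
    source = SourceId(Caller.AUX, platform, aux_name=caller_name)
    records: list[CallerRecord] = []
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc
    try:
        for variant in vcf:
            if pass_only and variant.FILTER is not None:  # None means PASS in cyvcf2
                continue
            ref = variant.REF
            if len(ref) != 1 or ref not in "ACGT":
                continue
            for alt in variant.ALT:
                if len(alt) != 1 or alt not in "ACGT":
                    continue
                fields: dict = {"filter": variant.FILTER or "PASS"}
                score = variant.INFO.get("SCORE")
                if score is not None:
                    fields["score"] = float(score)
                af = variant.INFO.get("AF")
                if af is not None:
                    fields["allele_fraction"] = float(af)
                records.append(CallerRecord(GenomicSite(variant.CHROM, variant.POS, ref, alt), source, fields))
    finally:
        vcf.close()
    return records


def write_sites_vcf(path: PathLike, sites: Sequence[GenomicSite], info: Optional[dict] = None) -> None:
    """Write a minimal VCF of PASS sites (truth and germline sets)."""
    info = info or {}
    with open(path, "wt") as fh:
        fh.write(_vcf_header(sites))
        for site in sites:
            tags = info.get(site)
            info_str = ";".join(f"{k}={v}" for k, v in tags.items()) if tags else "."
            fh.write(f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t{info_str}\n")


def write_classified_vcf(
    path: PathLike,
    sites: Sequence[tuple[GenomicSite, str, float]],
) -> None:
    """Write classifier output: FILTER=PASS for somatic, not_somatic otherwise.

    ``sites`` must be sorted by (chrom, pos); the ensemble score goes in
    INFO/SCORE.
    """
    keys = [s.sort_key for s, _, _ in sites]
    if keys != sorted(keys):
        raise ValueError("classified sites must be sorted by (chrom, pos)")
    with open(path, "wt") as fh:
        fh.write(_vcf_header([s for s, _, _ in sites]))
        for site, label, score in sites:
            filt = "PASS" if str(label) in ("SOMATIC", "Label.SOMATIC") else "not_somatic"
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\t{filt}\tSCORE={score:.6f}\n"
            )


# ---------------------------------------------------------------------------
# BED exome targets
# ---------------------------------------------------------------------------

@dataclass
class ExomeTargets:
    """Exome target intervals, held 1-based closed per chromosome."""

    intervals: dict[str, list[tuple[int, int]]]

    def contains(self, chrom: str, pos: int) -> bool:
        ivs = self.intervals.get(chrom)
        if not ivs:
            return False
        i = bisect_right(ivs, (pos, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= pos <= ivs[i][1]


def read_bed(path: PathLike) -> ExomeTargets:
    """Read BED intervals (0-based half-open) into 1-based closed form."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cells = line.split("\t")
            if len(cells) < 3:
                raise RowError(f"line {lineno}: BED rows need chrom, start, end")
            chrom, start, end = cells[0], int(cells[1]), int(cells[2])
            intervals.setdefault(chrom, []).append((start + 1, end))
    for ivs in intervals.values():
        ivs.sort()
    return ExomeTargets(intervals)


def write_bed(targets: ExomeTargets, path: PathLike) -> None:
    with open(path, "wt") as fh:
        for chrom in sorted(targets.intervals):
            for start1, end1 in targets.intervals[chrom]:
                fh.write(f"{chrom}\t{start1 - 1}\t{end1}\n")
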