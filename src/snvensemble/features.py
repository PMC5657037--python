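"""The 108-dimensional feature space and per-site integration.

Each candidate site is described by four evidence blocks — one per
(platform, caller) source over {genome, exome} × {MuTect, VCMM}.  Feature
names are prefixed by a platform code (G = genome, X = exome) and a
caller code (M = MuTect, V = VCMM): ``GM_t_alt_count`` is the tumor alt
read count reported by MuTect on the whole genome.

The MuTect block has 44 features (read counts and depths, allele
fractions, LOD-like scores, quality and strand statistics, power values,
indel-proximity counts, dbSNP/COSMIC/covered flags, the KEEP/REJECT
judgement, and one indicator per modeled rejection reason); the VCMM
block has 10 (depth, alt depth, allele fraction, SNP/mapping/base
quality, indel score, alt strand counts, dbSNP flag).  (44 + 10) × 2
platforms = 108, enforced as a hard invariant.

A caller that did not report a site leaves its whole block missing;
within a reported block individual cells may still be missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .caller_io import CALLSTATS_NUMERIC_FIELDS, MUTECT_FAILURE_REASONS
from .sites import Caller, CallerRecord, GenomicSite, Platform, SourceId

MISSING = None

PLATFORM_CODES = {"G": Platform.WGS, "X": Platform.WXS}
CALLER_CODES = {"M": Caller.MUTECT, "V": Caller.VCMM}

#: MuTect-derived per-platform fields: (field, kind). 44 entries.
MUTECT_FEATURE_FIELDS: tuple[tuple[str, str], ...] = (
    tuple((name, "numeric") for name in CALLSTATS_NUMERIC_FIELDS)
    + (("t_depth", "numeric"), ("n_depth", "numeric"))
    + (("dbsnp_site", "boolean"), ("cosmic_site", "boolean"), ("covered", "boolean"))
    + (("judgement", "categorical"),)
    + tuple((f"reason_{r}", "boolean") for r in MUTECT_FAILURE_REASONS)
)

#: VCMM-derived per-platform fields. 10 entries.
VCMM_FEATURE_FIELDS: tuple[tuple[str, str], ...] = (
    ("depth", "numeric"),
    ("alt_depth", "numeric"),
    ("allele_fraction", "numeric"),
    ("snp_quality", "numeric"),
    ("mapping_quality", "numeric"),
    ("base_quality", "numeric"),
    ("indel_score", "numeric"),
    ("alt_fwd", "numeric"),
    ("alt_rev", "numeric"),
    ("dbsnp_site", "boolean"),
)

JUDGEMENT_CATEGORIES: tuple[str, ...] = ("KEEP", "REJECT")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature names with per-feature kinds.

    names: e.g. ``GM_t_alt_count``; kinds maps each name to one of
    {"numeric", "boolean", "categorical"}; categorical features carry a
    fixed category vocabulary.
    """

    names: tuple[str, ...]
    kinds: dict[str, str]
    categories: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("feature names must be unique")
        for name in self.names:
            parse_feature_name(name)

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


def parse_feature_name(name: str) -> tuple[Platform, Caller, str]:
    """Split ``<platform><caller>_<field>`` into its components."""
    prefix, _, fieldname = name.partition("_")
    if len(prefix) != 2 or prefix[0] not in PLATFORM_CODES or prefix[1] not in CALLER_CODES or not fieldname:
        raise ValueError(f"feature name {name!r} does not parse as <platform><caller>_<field>")
    return PLATFORM_CODES[prefix[0]], CALLER_CODES[prefix[1]], fieldname


def build_default_schema() -> FeatureSchema:
    """The canonical 108-feature schema: (44 MuTect + 10 VCMM) × {G, X}."""
    names: list[str] = []
    kinds: dict[str, str] = {}
    categories: dict[str, tuple[str, ...]] = {}
    for pcode in ("G", "X"):
        for ccode, fields in (("M", MUTECT_FEATURE_FIELDS), ("V", VCMM_FEATURE_FIELDS)):
            for fieldname, kind in fields:
                name = f"{pcode}{ccode}_{fieldname}"
                names.append(name)
                kinds[name] = kind
                if kind == "categorical":
                    categories[name] = JUDGEMENT_CATEGORIES
    schema = FeatureSchema(tuple(names), kinds, categories)
    assert len(schema) == 108, "canonical schema must have exactly 108 features"
    return schema


@dataclass
class MergedSite:
    """All caller records observed for one site, at most one per source."""

    site: GenomicSite
    records: dict[SourceId, CallerRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("a MergedSite needs at least one record")
        for rec in self.records.values():
            if rec.site != self.site:
                raise ValueError(f"record site {rec.site} does not match merged site {self.site}")


@dataclass
class FeatureVector:
    """One site's values aligned to a schema; None marks a missing cell."""

    site: GenomicSite
    values: list

    def as_dict(self, schema: FeatureSchema) -> dict:
        return dict(zip(schema.names, self.values))


class IntegrityError(ValueError):
    pass


def merge_by_site(record_lists: Iterable[Sequence[CallerRecord]]) -> list[MergedSite]:
    """Merge per-source record lists into one MergedSite per distinct site.

    Sites are keyed by (chrom, pos, ref, alt) and returned in natural
    chromosomal order.  A source may contribute at most one record per
    site; duplicates raise :class:`IntegrityError`.
    """
    merged: dict[GenomicSite, dict[SourceId, CallerRecord]] = {}
    for records in record_lists:
        for rec in records:
            per_site = merged.setdefault(rec.site, {})
            if rec.source in per_site:
                raise IntegrityError(f"duplicate record for {rec.site} from {rec.source}")
            per_site[rec.source] = rec
    return [MergedSite(site, recs) for site, recs in sorted(merged.items(), key=lambda kv: kv[0].sort_key)]


def _mutect_value(rec: CallerRecord, fieldname: str):
    if fieldname == "t_depth":
        t_ref, t_alt = rec.get("t_ref_count"), rec.get("t_alt_count")
        return None if t_ref is None or t_alt is None else t_ref + t_alt
    if fieldname == "n_depth":
        n_ref, n_alt = rec.get("n_ref_count"), rec.get("n_alt_count")
        return None if n_ref is None or n_alt is None else n_ref + n_alt
    if fieldname == "tumor_f" and rec.get("tumor_f") is None:
        t_ref, t_alt = rec.get("t_ref_count"), rec.get("t_alt_count")
        if t_ref is not None and t_alt is not None and t_ref + t_alt > 0:
            return t_alt / (t_ref + t_alt)
        return None
    if fieldname == "normal_f" and rec.get("normal_f") is None:
        n_ref, n_alt = rec.get("n_ref_count"), rec.get("n_alt_count")
        if n_ref is not None and n_alt is not None and n_ref + n_alt > 0:
            return n_alt / (n_ref + n_alt)
        return None
    if fieldname.startswith("reason_"):
        reasons = rec.get("failure_reasons")
        return None if reasons is None else (fieldname[len("reason_"):] in reasons)
    return rec.get(fieldname)


def _vcmm_value(rec: CallerRecord, fieldname: str):
    if fieldname == "allele_fraction" and rec.get("allele_fraction") is None:
        depth, alt = rec.get("depth"), rec.get("alt_depth")
        if depth is not None and alt is not None and depth > 0:
            return alt / depth
        return None
    return rec.get(fieldname)


def vectorize_site(merged: MergedSite, schema: FeatureSchema) -> FeatureVector:
    """Project one merged site onto the schema, with explicit missingness.

    Deterministic and independent of record insertion order: each value
    is read from the single record of its (platform, caller) source.
    """
    by_source = {(rec.source.platform, rec.source.caller): rec for rec in merged.records.values()}
    values: list = []
    for name in schema.names:
        platform, caller, fieldname = parse_feature_name(name)
        rec = by_source.get((platform, caller))
        if rec is None:
            values.append(MISSING)
            continue
        value = _mutect_value(rec, fieldname) if caller is Caller.MUTECT else _vcmm_value(rec, fieldname)
        if isinstance(value, float) and not np.isfinite(value):
            value = MISSING
        values.append(value)
    return FeatureVector(merged.site, values)


def encode_matrix(vectors: Sequence[FeatureVector], schema: FeatureSchema) -> np.ndarray:
    """Encode feature vectors as a float matrix (NaN = missing).

    Booleans become 0/1; categorical values become their index in the
    schema's category vocabulary.  This is the representation the
    decision tree trains on.
    """
    X = np.full((len(vectors), len(schema)), np.nan)
    cat_codes = {name: {c: i for i, c in enumerate(cats)} for name, cats in schema.categories.items()}
    for i, vec in enumerate(vectors):
        if len(vec.values) != len(schema):
            raise ValueError(f"vector length {len(vec.values)} does not match schema length {len(schema)}")
        for j, (name, value) in enumerate(zip(schema.names, vec.values)):
            if value is MISSING:
                continue
            if schema.kinds[name] == "categorical":
                X[i, j] = cat_codes[name][value]
            else:
                X[i, j] = float(value)
    return X


def export_feature_matrix(
    vectors: Sequence[FeatureVector], schema: FeatureSchema, path, labels: Optional[Sequence] = None
) -> None:
    """Write a tab-delimited feature table, one row per site, NA = missing."""
    with open(path, "wt") as fh:
        header = ["chrom", "pos", "ref", "alt", *schema.names]
        if labels is not None:
            header.append("label")
        fh.write("\t".join(header) + "\n")
        for i, vec in enumerate(vectors):
            cells = [vec.site.chrom, str(vec.site.pos), vec.site.ref, vec.site.alt]
            for value in vec.values:
                if value is MISSING:
                    cells.append("NA")
                elif isinstance(value, bool):
                    cells.append("1" if value else "0")
                elif isinstance(value, float):
                    cells.append(format(value, ".6g"))
                else:
                    cells.append(str(value))
            if labels is not None:
                cells.append(str(getattr(labels[i], "value", labels[i])))
            fh.write("\t".join(cells) + "\n")
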