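"""Truth labeling for simulated and real modes, and training-table assembly.

Simulated mode: spiked-in truth variants are positives; germline variants
and every other site reported by either caller are negatives.

Real mode (consensus labeling): a site is positive when its supporting
(caller, platform) pairs span at least two distinct callers AND at least
two distinct platforms; negative when supported by exactly one caller on
exactly one platform while both tumor and normal are covered to at least
``min_depth`` on each of the two other platforms; everything else is
left unlabeled and excluded from training and evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .features import FeatureVector, MergedSite
from .sites import GenomicSite, Label, Platform

logger = logging.getLogger(__name__)


@dataclass
class LabeledExample:
    """A feature vector with its label and the rule that produced it."""

    vector: FeatureVector
    label: Label
    provenance: str = ""


class IntegrityError(ValueError):
    pass


def label_simulated(
    candidates: Sequence[MergedSite],
    truth: Iterable[GenomicSite],
    germline: Iterable[GenomicSite],
    vectors: Optional[Sequence[FeatureVector]] = None,
) -> list[LabeledExample]:
    """Label candidate sites against a spike-in truth set.

    Every candidate gets exactly one label: SOMATIC if in the truth set,
    otherwise NOT_SOMATIC (germline or caller artifact).  The truth and
    germline sets must be disjoint.
    """
    truth_set = set(truth)
    germline_set = set(germline)
    overlap = truth_set & germline_set
    if overlap:
        raise IntegrityError(f"{len(overlap)} sites are in both truth and germline sets")
    if vectors is None:
        from .features import build_default_schema, vectorize_site

        schema = build_default_schema()
        vectors = [vectorize_site(m, schema) for m in candidates]
    examples: list[LabeledExample] = []
    for merged, vec in zip(candidates, vectors):
        if merged.site in truth_set:
            examples.append(LabeledExample(vec, Label.SOMATIC, "spike_in_truth"))
        elif merged.site in germline_set:
            examples.append(LabeledExample(vec, Label.NOT_SOMATIC, "germline"))
        else:
            examples.append(LabeledExample(vec, Label.NOT_SOMATIC, "caller_artifact"))
    return examples


#: coverage lookup: (platform, sample in {"normal","tumor"}, site) -> depth
CoverageLookup = Mapping[tuple[Platform, str, GenomicSite], int]


def classify_support(
    support: frozenset[tuple[str, Platform]],
    all_platforms: Sequence[Platform],
    coverage_ok,
) -> tuple[Label, str]:
    """Apply the consensus rules to one site's support pattern.

    ``coverage_ok(platform)`` reports whether tumor and normal depth on
    that platform both meet the threshold (None = unknown).
    """
    callers = {c for c, _ in support}
    platforms = {p for _, p in support}
    if len(callers) >= 2 and len(platforms) >= 2:
        return Label.SOMATIC, "consensus_2callers_2platforms"
    if len(callers) == 1 and len(platforms) == 1 and len(support) == 1:
        others = [p for p in all_platforms if p not in platforms]
        oks = [coverage_ok(p) for p in others]
        if any(ok is None for ok in oks):
            return Label.UNLABELED, "missing_coverage"
        if all(oks):
            return Label.NOT_SOMATIC, "singleton_covered_elsewhere"
        return Label.UNLABELED, "low_coverage_elsewhere"
    return Label.UNLABELED, "ambiguous_support"


def label_real_consensus(
    calls: Mapping[tuple[str, Platform], Iterable[GenomicSite]],
    coverage: CoverageLookup,
    min_depth: int = 10,
) -> list[tuple[GenomicSite, Label, str]]:
    """Consensus labeling over per-(caller, platform) call sets.

    ``calls`` maps (caller name, platform) to the sites that caller
    reported as somatic on that platform.
    """
    support: dict[GenomicSite, set[tuple[str, Platform]]] = {}
    for (caller, platform), sites in calls.items():
        platform = Platform(platform)
        for site in sites:
            support.setdefault(site, set()).add((caller, platform))
    all_platforms = sorted({Platform(p) for _, p in calls.keys()}, key=lambda p: p.value)

    results: list[tuple[GenomicSite, Label, str]] = []
    for site in sorted(support, key=lambda s: s.sort_key):

        def coverage_ok(platform: Platform, site=site) -> Optional[bool]:
            depths = [coverage.get((platform, sample, site)) for sample in ("normal", "tumor")]
            if any(d is None for d in depths):
                logger.info("no coverage for %s on %s; leaving unlabeled", site, platform.value)
                return None
            return all(d >= min_depth for d in depths)

        label, provenance = classify_support(frozenset(support[site]), all_platforms, coverage_ok)
        results.append((site, label, provenance))
    return results


def assemble_training_table(
    labeled: Sequence[LabeledExample], n: int, seed: int
) -> list[LabeledExample]:
    """Uniform sample without replacement of n labeled (non-UNLABELED) rows.

    Reproducible under ``seed``; mirrors building a training table by
    randomly drawing positions from the full considered set.
    """
    pool = [ex for ex in labeled if ex.label is not Label.UNLABELED]
    if n > len(pool):
        raise ValueError(f"requested {n} examples but only {len(pool)} labeled rows are available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in idx]


def export_labels(labeled: Iterable[tuple[GenomicSite, Label, str]], path) -> None:
    """Tab-delimited label export: chrom, pos, ref, alt, label, provenance."""
    with open(path, "wt") as fh:
        fh.write("chrom\tpos\tref\talt\tlabel\tprovenance\n")
        for site, label, provenance in labeled:
            fh.write(f"{site.chrom}\t{site.pos}\t{site.ref}\t{site.alt}\t{label.value}\t{provenance}\n")
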