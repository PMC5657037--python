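"""End-to-end workflows wiring I/O, integration, labeling, tree and metrics.

These are the compositions the command-line interface and the examples
use: build labeled examples from a synthetic dataset (in memory or from
a dataset directory on disk), train and cross-validate the tree, compare
the ensemble against single-caller union/intersection baselines, and
sweep normal-sample contamination.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

from . import caller_io
from .features import (
    FeatureSchema,
    MergedSite,
    build_default_schema,
    merge_by_site,
    vectorize_site,
)
from .labeling import LabeledExample, label_simulated
from .metrics import MetricSet, StrategyResult, compare_report, cross_validate
from .simulate import SimConfig, SimulatedData, called_sites, contaminate_normal, emulate_mutect, emulate_vcmm, simulate
from .sites import GenomicSite, Label, Platform
from .tree import TrainParams, TreeModel, predict, train_tree


class DatasetView:
    """Candidate sites of one dataset with labels, calls and truth."""

    def __init__(
        self,
        examples: list[LabeledExample],
        merged: list[MergedSite],
        caller_calls: dict,
        truth_sites: set[GenomicSite],
        germline_sites: set[GenomicSite],
        schema: FeatureSchema,
    ) -> None:
        self.examples = examples
        self.merged = merged
        self.caller_calls = caller_calls
        self.truth_sites = truth_sites
        self.germline_sites = germline_sites
        self.schema = schema

    @property
    def universe(self) -> set[GenomicSite]:
        return {m.site for m in self.merged} | self.truth_sites


def view_from_data(data: SimulatedData, schema: Optional[FeatureSchema] = None) -> DatasetView:
    """Run the emulated callers and assemble labeled candidates in memory."""
    schema = schema or build_default_schema()
    mutect = {p: emulate_mutect(data, p) for p in (Platform.WGS, Platform.WXS)}
    vcmm = {p: emulate_vcmm(data, p) for p in (Platform.WGS, Platform.WXS)}
    merged = merge_by_site(list(mutect.values()) + list(vcmm.values()))
    vectors = [vectorize_site(m, schema) for m in merged]
    truth_sites = data.truth_sites
    germline_sites = set(data.germline)
    examples = label_simulated(merged, truth_sites, germline_sites, vectors)
    caller_calls = {
        "MuTect": {p.value: called_sites(recs) for p, recs in mutect.items()},
        "VCMM": {p.value: called_sites(recs) for p, recs in vcmm.items()},
    }
    return DatasetView(examples, merged, caller_calls, truth_sites, germline_sites, schema)


def view_from_dir(dataset_dir, schema: Optional[FeatureSchema] = None) -> DatasetView:
    """Parse a generated dataset directory back into labeled candidates."""
    schema = schema or build_default_schema()
    d = Path(dataset_dir)
    mutect = {
        Platform.WGS: caller_io.parse_mutect_callstats(d / "mutect_wgs.call_stats.tsv", Platform.WGS),
        Platform.WXS: caller_io.parse_mutect_callstats(d / "mutect_wxs.call_stats.tsv", Platform.WXS),
    }
    vcmm = {
        Platform.WGS: caller_io.parse_vcmm_table(d / "vcmm_wgs.tsv", Platform.WGS),
        Platform.WXS: caller_io.parse_vcmm_table(d / "vcmm_wxs.tsv", Platform.WXS),
    }
    truth_sites = {r.site for r in caller_io.read_vcf_calls(d / "truth.vcf", "truth", Platform.VALIDATION)}
    germline_sites = {r.site for r in caller_io.read_vcf_calls(d / "germline.vcf", "germline", Platform.VALIDATION)}
    merged = merge_by_site(list(mutect.values()) + list(vcmm.values()))
    vectors = [vectorize_site(m, schema) for m in merged]
    examples = label_simulated(merged, truth_sites, germline_sites, vectors)
    caller_calls = {
        "MuTect": {p.value: called_sites(recs) for p, recs in mutect.items()},
        "VCMM": {p.value: called_sites(recs) for p, recs in vcmm.items()},
    }
    return DatasetView(examples, merged, caller_calls, truth_sites, germline_sites, schema)


def classify_view(model: TreeModel, view: DatasetView) -> list[tuple[GenomicSite, Label, float]]:
    """Predict every candidate site; sorted by genomic position."""
    out = []
    for ex in view.examples:
        label, score = predict(model, ex.vector)
        out.append((ex.vector.site, label, score))
    out.sort(key=lambda t: t[0].sort_key)
    return out


def strategy_comparison(
    train_view: DatasetView,
    test_view: DatasetView,
    params: Optional[TrainParams] = None,
) -> tuple[list[StrategyResult], TreeModel]:
    """Train on one dataset, evaluate ensemble vs baselines on another."""
    model = train_tree(train_view.examples, train_view.schema, params)
    classified = classify_view(model, test_view)
    ensemble_pred = {site for site, label, _ in classified if label is Label.SOMATIC}
    results = compare_report(
        test_view.truth_sites, test_view.universe, test_view.caller_calls, ensemble_pred
    )
    return results, model


def contamination_curve(
    cfg: SimConfig,
    fractions: Sequence[float] = (0.0, 0.025, 0.05, 0.075, 0.10),
    k: int = 10,
    params: Optional[TrainParams] = None,
    cv_seed: int = 0,
) -> list[tuple[float, MetricSet]]:
    """Cross-validated ensemble performance as normal contamination rises.

    One base dataset is drawn, then the normal sample is re-mixed at each
    fraction; everything else (sites, tumor reads, seeds) is held fixed.
    """
    base = simulate(cfg)
    curve: list[tuple[float, MetricSet]] = []
    for fraction in fractions:
        data = contaminate_normal(base, fraction)
        view = view_from_data(data)
        summary, _ = cross_validate(view.examples, view.schema, k=k, seed=cv_seed, params=params)
        curve.append((fraction, summary))
    return curve
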