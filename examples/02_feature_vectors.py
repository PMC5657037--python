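"""Merge caller outputs by site and inspect the 108-feature vector.

Each candidate site is described by four blocks — {genome, exome} x
{MuTect-style, VCMM-style}.  A block is missing wholesale when that
caller did not report the site; the classifier handles this natively,
so no imputation happens here.
"""

from snvensemble import Label, SimConfig, simulate, view_from_data

view = view_from_data(simulate(SimConfig(seed=1)))
print(f"{len(view.examples)} candidate sites, schema = {len(view.schema)} features")

somatic = next(ex for ex in view.examples if ex.label is Label.SOMATIC)
germline = next(ex for ex in view.examples if ex.provenance == "germline")

for name, ex in (("somatic", somatic), ("germline", germline)):
    values = ex.vector.as_dict(view.schema)
    present = sum(1 for v in ex.vector.values if v is not None)
    print(f"\n{name} example at {ex.vector.site.chrom}:{ex.vector.site.pos}"
          f" ({present}/108 features present)")
    for key in ("GM_t_alt_count", "GM_normal_f", "GM_judgement", "GV_allele_fraction", "GV_dbsnp_site"):
        print(f"  {key:22s} = {values[key]}")

# A germline site typically shows a high normal allele fraction, a REJECT
# judgement from the paired caller and dbSNP membership — exactly the
# signal the decision tree uses to discard the liberal caller's false calls.
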