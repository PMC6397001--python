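"""Arterial tone, immunoblot densitometry and PLA puncta density.

The three small deterministic quantifications of the pipeline, applied to
hand-sized inputs.
"""

from nanocoloc import assays

tone = assays.percent_tone(assays.ToneRecord(active_diameter_um=150.0, passive_diameter_um=200.0))
print(f"myogenic tone       : {tone:.1f}%  (150 µm active vs 200 µm passive)")

rec = assays.DensitometryRecord(
    band=40.0, local_background=10.0,
    reference_band=70.0, reference_background=10.0,
    control_ratio=0.5,
)
print(f"relative density    : {assays.densitometry_ratio(rec):.2f}  (normalized to control lane)")

density = assays.pla_puncta_density(puncta_count=50, cell_area_um2=400.0)
print(f"PLA puncta density  : {density:.3f} puncta/µm²")
# Tone is the percent constriction from maximal passive diameter; relative
# density 1.0 means the band matches the control lane after background and
# loading correction.
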