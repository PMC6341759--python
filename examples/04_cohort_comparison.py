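"""Generate a synthetic patient cohort and produce a comparison report.

Two groups of subjects are drawn with different stroke-volume
distributions (hyperdynamic "pre-shunt" vs normal "control" aqueductal
flow), each subject is measured through the full pipeline, and the groups
are compared metric-by-metric with the Mann-Whitney rank-sum test.
"""

import pandas as pd

from csfpulse import (
    CohortSpec,
    CohortTable,
    GroupSpec,
    cohort_report,
    eddy_correction,
    flow_waveform,
    generate_cohort,
    hydrodynamic_metrics,
    phase_to_velocity,
    segment_roi,
)
from csfpulse.pipeline import auto_static_mask

spec = CohortSpec(
    groups=(
        GroupSpec(name="pre_shunt", group="pre_shunt", n=8, site="aqueduct",
                  distributions={"sv_ul": ("normal", 124.5, 45.0),
                                 "area_mm2": ("normal", 8.0, 1.5)}),
        GroupSpec(name="control", group="control", n=6, site="aqueduct",
                  distributions={"sv_ul": ("normal", 49.7, 16.0),
                                 "area_mm2": ("normal", 4.9, 1.0)}),
    ),
    seed=1,
)
subjects, draw_log = generate_cohort(spec)
print(f"simulated {len(subjects)} subjects "
      f"({int(draw_log.filter(like='truncated').sum().sum())} truncated draws)")

rows = []
for i, (group, series, truth) in enumerate(subjects):
    roi = segment_roi(series)
    static = auto_static_mask(series.shape[:2],
                              exclude=roi.mask | (series.magnitude.mean(axis=2) > 100))
    vel = eddy_correction(phase_to_velocity(series), static, flow_roi=roi)
    m = hydrodynamic_metrics(flow_waveform(vel, roi), vel, roi)
    rows.append({"subject_id": f"sub{i:02d}", "group": group, "site": "aqueduct",
                 "pair_id": None, "area[mm2]": m.area_mm2,
                 "sv_bradley[uL]": m.sv_bradley_ul})

table = CohortTable(pd.DataFrame(rows))
plan = [{"metric": m, "site": "aqueduct", "kind": "independent",
         "group_a": "pre_shunt", "group_b": "control"}
        for m in ("area[mm2]", "sv_bradley[uL]")]
print(cohort_report(table, plan).to_markdown())
# with designed separations this large, both metrics should reach
# significance even at these small group sizes (exact test, pooled n <= 12)
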