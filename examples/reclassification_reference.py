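"""Recompute the published reclassification arithmetic from raw counts.

Loads the packaged reference cross-tabulations (clinical risk category vs
the combined clinical + acoustic category, for 63 obstructive-CAD and 165
other patients) and recomputes the categorical NRI, its components, the
category totals and the category-based predictive values - everything a
reader could derive from the printed tables.
"""

import json

from cadscore.pipeline import reproduce_reference_reclassification

report = reproduce_reference_reclassification()
c, p = report["computed"], report["published"]

print(f"{'quantity':38s} {'computed':>10s} {'published':>10s}")
for key in ("categorical_nri", "event_net_percent", "nonevent_net_percent",
            "up_events", "down_events", "npv_low_score_percent",
            "ppv_high_score_percent", "very_low_total",
            "very_low_prevalence_percent"):
    cv = c[key]
    print(f"{key:38s} {cv:10.2f} {p[key]:10.2f}" if isinstance(cv, float)
          else f"{key:38s} {cv:10d} {p[key]:10.0f}")

print("\nnotes:", report["notes"][0])
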