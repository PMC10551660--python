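"""Severity grading: default rubric bands and a stricter custom rubric.

Shows how index values map onto the light / medium / heavy screening scale,
including the signed knee axis (O-leg positive, X-leg negative) and the
severer-wins tie at exactly -3 deg.
"""

import json
import tempfile
from pathlib import Path

from posturekit import default_rubric, load_rubric

rubric = default_rubric()

print("uneven shoulders:")
for v in (1.0, 2.0, 3.99, 4.0):
    print(f"  {v:5.2f} deg -> {rubric.grade('uneven_shoulders', v)[0]}")

print("knee alignment (signed):")
for v in (-3.5, -3.0, -2.0, 0.0, 4.0, 5.0):
    grade, tag = rubric.grade("knee_alignment", v)
    leg = f" ({tag}-leg)" if tag else ""
    print(f"  {v:5.1f} deg -> {grade}{leg}")

# A clinic wanting a stricter shoulder screen can override one index's bands:
custom = {
    "version": "strict-shoulders",
    "indexes": {
        name: {
            "bands": [
                {"min": b.lo if b.lo != float("-inf") else "-inf",
                 "max": b.hi if b.hi != float("inf") else "inf",
                 "grade": b.grade, "tag": b.tag,
                 "min_inclusive": b.lo_incl, "max_inclusive": b.hi_incl}
                for b in bands
            ]
        }
        for name, bands in rubric.bands.items()
    },
}
custom["indexes"]["uneven_shoulders"]["bands"] = [
    {"min": 0, "max": 1, "grade": "light"},
    {"min": 1, "max": 3, "grade": "medium"},
    {"min": 3, "max": "inf", "grade": "heavy"},
]
with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "strict.json"
    path.write_text(json.dumps(custom))
    strict = load_rubric(path)
print("with strict rubric, 1.5 deg shoulders ->",
      strict.grade("uneven_shoulders", 1.5)[0], "(default: light)")
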