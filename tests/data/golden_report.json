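{
  "provenance": {
    "frames": {
      "anterior": 10,
      "lateral": 10,
      "posterior": 10
    },
    "rubric_version": "table-default-1",
    "window": 10
  },
  "results": [
    {
      "direction": "left_high",
      "grade": "medium",
      "grade_tag": null,
      "index": "uneven_shoulders",
      "unit": "deg",
      "value": 3.022
    },
    {
      "direction": "left_high",
      "grade": "light",
      "grade_tag": null,
      "index": "lateral_pelvic_tilt",
      "unit": "deg",
      "value": 0.804
    },
    {
      "direction": "O",
      "grade": "medium",
      "grade_tag": "O",
      "index": "knee_alignment",
      "unit": "deg",
      "value": 3.956
    },
    {
      "direction": null,
      "grade": "medium",
      "grade_tag": null,
      "index": "forward_head",
      "unit": "cm",
      "value": 3.053
    },
    {
      "direction": "anterior",
      "grade": "medium",
      "grade_tag": null,
      "index": "pelvic_tilt",
      "unit": "deg",
      "value": 18.0
    },
    {
      "direction": "convex_left",
      "grade": "medium",
      "grade_tag": null,
      "index": "scoliosis",
      "unit": "deg",
      "value": 2.5
    },
    {
      "direction": "left_high",
      "grade": "medium",
      "grade_tag": null,
      "index": "scapula_inclination",
      "unit": "deg",
      "value": 7.0
    }
  ],
  "skipped": {},
  "subject_id": "golden-figurine"
}
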