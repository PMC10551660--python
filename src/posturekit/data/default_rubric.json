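{
  "indexes": {
    "forward_head": {
      "bands": [
        {
          "grade": "light",
          "max": 2.5,
          "max_inclusive": false,
          "min": 0.0,
          "min_inclusive": true,
          "tag": null
        },
        {
          "grade": "medium",
          "max": 5.0,
          "max_inclusive": false,
          "min": 2.5,
          "min_inclusive": true,
          "tag": null
        },
        {
          "grade": "heavy",
          "max": "inf",
          "max_inclusive": false,
          "min": 5.0,
          "min_inclusive": true,
          "tag": null
        }
      ]
    },
    "knee_alignment": {
      "bands": [
        {
          "grade": "heavy",
          "max": -3.0,
          "max_inclusive": true,
          "min": "-inf",
          "min_inclusive": false,
          "tag": "X"
        },
        {
          "grade": "medium",
          "max": -1.0,
          "max_inclusive": false,
          "min": -3.0,
          "min_inclusive": true,
          "tag": "X"
        },
        {
          "grade": "light",
          "max": 3.0,
          "max_inclusive": false,
          "min": -1.0,
          "min_inclusive": true,
          "tag": null
        },
        {
          "grade": "medium",
          "max": 5.0,
          "max_inclusive": false,
          "min": 3.0,
          "min_inclusive": true,
          "tag": "O"
        },
        {
          "grade": "heavy",
          "max": "inf",
          "max_inclusive": false,
          "min": 5.0,
          "min_inclusive": true,
          "tag": "O"
        }
      ]
    },
    "lateral_pelvic_tilt": {
      "bands": [
        {
          "grade": "light",
          "max": 2.0,
          "max_inclusive": false,
          "min": 0.0,
          "min_inclusive": true,
          "tag": null
        },
        {
          "grade": "medium",
          "max": 4.0,
          "max_inclusive": false,
          "min": 2.0,
          "min_inclusive": true,
          "tag": null
        },
        {
          "grade": "heavy",
          "max": "inf",
          "max_inclusive": false,
          "min": 4.0,
          "min_inclusive": true,
          "tag": null
        }
      ]
    },
    "pelvic_tilt": {
      "bands": [
        {
          "grade": "light",
          "max": 15.0,
          "max_inclusive": false,
          "min": 0.0,
          "min_inclusive": true,
          "tag": null
        },
        {
          "grade": "medium",
          "max": 25.0,
          "max_inclusive": false,
          "min": 15.0,
          "min_inclusive": true,
          "tag": null
        },
        {
          "grade": "heavy",
          "max": "inf",
          "max_inclusive": false,
          "min": 25.0,
          "min_inclusive": true,
          "tag": null
        }
      ]
    },
    "scapula_inclination": {
      "bands": [
        {
          "grade": "light",
          "max": 5.0,
          "max_inclusive": false,
          "min": 0.0,
          "min_inclusive": true,
          "tag": null
        },
        {
          "grade": "medium",
          "max": 10.0,
          "max_inclusive": false,
          "min": 5.0,
          "min_inclusive": true,
          "tag": null
        },
        {
          "grade": "heavy",
          "max": "inf",
          "max_inclusive": false,
          "min": 10.0,
          "min_inclusive": true,
          "tag": null
        }
      ]
    },
    "scoliosis": {
      "bands": [
        {
          "grade": "light",
          "max": 2.0,
          "max_inclusive": false,
          "min": 0.0,
          "min_inclusive": true,
          "tag": null
        },
        {
          "grade": "medium",
          "max": 4.0,
          "max_inclusive": false,
          "min": 2.0,
          "min_inclusive": true,
          "tag": null
        },
        {
          "grade": "heavy",
          "max": "inf",
          "max_inclusive": false,
          "min": 4.0,
          "min_inclusive": true,
          "tag": null
        }
      ]
    },
    "uneven_shoulders": {
      "bands": [
        {
          "grade": "light",
          "max": 2.0,
          "max_inclusive": false,
          "min": 0.0,
          "min_inclusive": true,
          "tag": null
        },
        {
          "grade": "medium",
          "max": 4.0,
          "max_inclusive": false,
          "min": 2.0,
          "min_inclusive": true,
          "tag": null
        },
        {
          "grade": "heavy",
          "max": "inf",
          "max_inclusive": false,
          "min": 4.0,
          "min_inclusive": true,
          "tag": null
        }
      ]
    }
  },
  "version": "table-default-1"
}
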