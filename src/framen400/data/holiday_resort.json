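{
  "format_version": 1,
  "name": "holiday_resort",
  "constraint_level": "HC",
  "sorts": [
    {
      "name": "plant",
      "parent": null
    },
    {
      "name": "tree",
      "parent": "plant"
    },
    {
      "name": "flower",
      "parent": "plant"
    }
  ],
  "attributes": [
    {
      "name": "habitat",
      "values": [
        "tropics",
        "moderate"
      ]
    },
    {
      "name": "height",
      "values": [
        "tall",
        "small"
      ]
    },
    {
      "name": "look",
      "values": [
        "tropical",
        "moderate"
      ]
    }
  ],
  "categories": {
    "palms": {
      "sort": "tree",
      "provenance": "fixture-choice",
      "distributions": {
        "habitat": {
          "tropics": 0.9,
          "moderate": 0.1
        },
        "height": {
          "tall": 0.9,
          "small": 0.1
        }
      },
      "fixed": []
    },
    "pines": {
      "sort": "tree",
      "provenance": "fixture-choice",
      "distributions": {
        "habitat": {
          "tropics": 0.1,
          "moderate": 0.9
        },
        "height": {
          "tall": 0.9,
          "small": 0.1
        }
      },
      "fixed": []
    },
    "theme_of_planting": {
      "sort": "plant",
      "provenance": "paper",
      "distributions": {
        "habitat": {
          "tropics": 0.9,
          "moderate": 0.1
        },
        "height": {
          "tall": 0.6,
          "small": 0.4
        }
      },
      "fixed": [
        {
          "chain": "look",
          "value": "tropical"
        }
      ]
    },
    "tulips": {
      "sort": "flower",
      "provenance": "fixture-choice",
      "distributions": {
        "habitat": {
          "tropics": 0.1,
          "moderate": 0.9
        },
        "height": {
          "tall": 0.1,
          "small": 0.9
        }
      },
      "fixed": []
    }
  },
  "critical_words": {
    "palms": "palms",
    "pines": "pines",
    "tulips": "tulips"
  },
  "arg_concept": {
    "category": "theme_of_planting",
    "context_independent": [],
    "context_dependent": [
      "habitat",
      "height"
    ],
    "threshold_r": 0.5,
    "contrast": {
      "antecedent": "look",
      "actual_value": "tropical",
      "alternatives": {
        "moderate": {
          "habitat": {
            "tropics": 0.1,
            "moderate": 0.9
          }
        }
      }
    }
  }
}
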