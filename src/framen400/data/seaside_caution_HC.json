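{
  "format_version": 1,
  "name": "seaside_caution_HC",
  "constraint_level": "HC",
  "sorts": [
    {
      "name": "entity",
      "parent": null
    },
    {
      "name": "animate",
      "parent": "entity"
    },
    {
      "name": "inanimate",
      "parent": "entity"
    }
  ],
  "attributes": [
    {
      "name": "afloat",
      "values": [
        "yes",
        "no"
      ]
    },
    {
      "name": "can_move",
      "values": [
        "yes",
        "no"
      ]
    },
    {
      "name": "danger.location",
      "values": [
        "water",
        "beach"
      ]
    },
    {
      "name": "in_danger",
      "values": [
        "yes",
        "no"
      ]
    },
    {
      "name": "location",
      "values": [
        "water",
        "beach"
      ]
    },
    {
      "name": "sentient",
      "values": [
        "yes",
        "no"
      ]
    }
  ],
  "categories": {
    "drawer": {
      "sort": "inanimate",
      "provenance": "fixture-choice",
      "distributions": {
        "afloat": {
          "yes": 0.1,
          "no": 0.9
        },
        "in_danger": {
          "yes": 0.05,
          "no": 0.95
        },
        "location": {
          "water": 0.05,
          "beach": 0.95
        }
      },
      "fixed": []
    },
    "swimmers": {
      "sort": "animate",
      "provenance": "fixture-choice",
      "distributions": {
        "afloat": {
          "yes": 0.9,
          "no": 0.1
        },
        "can_move": {
          "yes": 0.99,
          "no": 0.01
        },
        "in_danger": {
          "yes": 0.8,
          "no": 0.2
        },
        "location": {
          "water": 0.95,
          "beach": 0.05
        },
        "sentient": {
          "yes": 0.99,
          "no": 0.01
        }
      },
      "fixed": []
    },
    "theme_of_caution": {
      "sort": "entity",
      "provenance": "fixture-choice",
      "distributions": {
        "afloat": {
          "yes": 0.85,
          "no": 0.15
        },
        "can_move": {
          "yes": 0.95,
          "no": 0.05
        },
        "in_danger": {
          "yes": 0.9,
          "no": 0.1
        },
        "location": {
          "water": 0.9,
          "beach": 0.1
        },
        "sentient": {
          "yes": 0.95,
          "no": 0.05
        }
      },
      "fixed": [
        {
          "chain": "danger.location",
          "value": "water"
        }
      ]
    },
    "trainees": {
      "sort": "animate",
      "provenance": "fixture-choice",
      "distributions": {
        "afloat": {
          "yes": 0.5,
          "no": 0.5
        },
        "can_move": {
          "yes": 0.99,
          "no": 0.01
        },
        "in_danger": {
          "yes": 0.5,
          "no": 0.5
        },
        "location": {
          "water": 0.5,
          "beach": 0.5
        },
        "sentient": {
          "yes": 0.99,
          "no": 0.01
        }
      },
      "fixed": []
    }
  },
  "critical_words": {
    "drawer": "drawer",
    "swimmers": "swimmers",
    "trainees": "trainees"
  },
  "arg_concept": {
    "category": "theme_of_caution",
    "context_independent": [
      "can_move",
      "in_danger",
      "sentient"
    ],
    "context_dependent": [
      "afloat",
      "location"
    ],
    "threshold_r": 0.5,
    "contrast": {
      "antecedent": "danger.location",
      "actual_value": "water",
      "alternatives": {
        "beach": {
          "afloat": {
            "yes": 0.15,
            "no": 0.85
          },
          "location": {
            "water": 0.1,
            "beach": 0.9
          }
        }
      }
    }
  }
}
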