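{
  "format_version": 1,
  "name": "birthday_party",
  "constraint_level": "HC",
  "sorts": [
    {
      "name": "food",
      "parent": null
    }
  ],
  "attributes": [
    {
      "name": "nutrition_value",
      "values": [
        "healthy",
        "not_healthy"
      ]
    },
    {
      "name": "served_at",
      "values": [
        "birthday_party",
        "not_birthday_party"
      ]
    },
    {
      "name": "taste",
      "values": [
        "sweet",
        "not_sweet"
      ]
    }
  ],
  "categories": {
    "cake": {
      "sort": "food",
      "provenance": "paper",
      "distributions": {
        "nutrition_value": {
          "healthy": 0.2,
          "not_healthy": 0.8
        },
        "served_at": {
          "birthday_party": 0.98,
          "not_birthday_party": 0.02
        },
        "taste": {
          "sweet": 0.9,
          "not_sweet": 0.1
        }
      },
      "fixed": []
    },
    "dessert": {
      "sort": "food",
      "provenance": "paper",
      "distributions": {
        "nutrition_value": {
          "healthy": 0.05,
          "not_healthy": 0.95
        },
        "served_at": {
          "birthday_party": 0.98,
          "not_birthday_party": 0.02
        },
        "taste": {
          "sweet": 0.95,
          "not_sweet": 0.05
        }
      },
      "fixed": []
    },
    "veggies": {
      "sort": "food",
      "provenance": "paper",
      "distributions": {
        "nutrition_value": {
          "healthy": 0.9,
          "not_healthy": 0.1
        },
        "served_at": {
          "birthday_party": 0.02,
          "not_birthday_party": 0.98
        },
        "taste": {
          "sweet": 0.2,
          "not_sweet": 0.8
        }
      },
      "fixed": []
    }
  },
  "critical_words": {
    "cake": "cake",
    "veggies": "veggies"
  },
  "arg_concept": {
    "category": "dessert",
    "context_independent": [],
    "context_dependent": [
      "nutrition_value",
      "served_at",
      "taste"
    ],
    "threshold_r": 0.5,
    "diagnosticity": {
      "nutrition_value": 0.1,
      "served_at": 0.45,
      "taste": 0.45
    }
  },
  "prenominal_updates": {
    "healthy": {
      "evidence": {
        "chain": "nutrition_value",
        "value": "healthy"
      },
      "revisions": {
        "served_at": {
          "birthday_party": 0.95,
          "not_birthday_party": 0.05
        },
        "taste": {
          "sweet": 0.4,
          "not_sweet": 0.6
        }
      }
    },
    "sweet": {
      "evidence": {
        "chain": "taste",
        "value": "sweet"
      },
      "revisions": {
        "nutrition_value": {
          "healthy": 0.02,
          "not_healthy": 0.98
        }
      }
    }
  }
}
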