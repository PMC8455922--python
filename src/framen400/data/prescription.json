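{
  "format_version": 1,
  "name": "prescription",
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
      "name": "actor.animacy",
      "values": [
        "animate",
        "inanimate"
      ]
    },
    {
      "name": "actor.profession",
      "values": [
        "medical",
        "nonmedical"
      ]
    },
    {
      "name": "recipient.animacy",
      "values": [
        "animate",
        "inanimate"
      ]
    },
    {
      "name": "recipient.condition",
      "values": [
        "mental",
        "other"
      ]
    },
    {
      "name": "theme.form",
      "values": [
        "medicine",
        "other"
      ]
    }
  ],
  "categories": {
    "fence": {
      "sort": "inanimate",
      "provenance": "fixture-choice",
      "distributions": {
        "theme.form": {
          "medicine": 0.02,
          "other": 0.98
        }
      },
      "fixed": []
    },
    "guard": {
      "sort": "animate",
      "provenance": "fixture-choice",
      "distributions": {
        "actor.profession": {
          "medical": 0.2,
          "nonmedical": 0.8
        },
        "recipient.condition": {
          "mental": 0.2,
          "other": 0.8
        }
      },
      "fixed": [
        {
          "chain": "actor.animacy",
          "value": "animate"
        },
        {
          "chain": "recipient.animacy",
          "value": "animate"
        }
      ]
    },
    "pill": {
      "sort": "inanimate",
      "provenance": "fixture-choice",
      "distributions": {
        "theme.form": {
          "medicine": 0.95,
          "other": 0.050000000000000044
        }
      },
      "fixed": []
    },
    "prescribed_medicine": {
      "sort": "inanimate",
      "provenance": "fixture-choice",
      "distributions": {
        "theme.form": {
          "medicine": 0.9,
          "other": 0.1
        }
      },
      "fixed": []
    },
    "psychiatrist": {
      "sort": "animate",
      "provenance": "fixture-choice",
      "distributions": {
        "actor.profession": {
          "medical": 0.95,
          "nonmedical": 0.050000000000000044
        },
        "recipient.condition": {
          "mental": 0.3,
          "other": 0.7
        }
      },
      "fixed": [
        {
          "chain": "actor.animacy",
          "value": "animate"
        },
        {
          "chain": "recipient.animacy",
          "value": "animate"
        }
      ]
    },
    "recipient_of_prescription": {
      "sort": "animate",
      "provenance": "fixture-choice",
      "distributions": {
        "recipient.condition": {
          "mental": 0.9,
          "other": 0.1
        }
      },
      "fixed": [
        {
          "chain": "recipient.animacy",
          "value": "animate"
        }
      ]
    },
    "schizophrenic": {
      "sort": "animate",
      "provenance": "fixture-choice",
      "distributions": {
        "actor.profession": {
          "medical": 0.05,
          "nonmedical": 0.95
        },
        "recipient.condition": {
          "mental": 0.95,
          "other": 0.050000000000000044
        }
      },
      "fixed": [
        {
          "chain": "actor.animacy",
          "value": "animate"
        },
        {
          "chain": "recipient.animacy",
          "value": "animate"
        }
      ]
    },
    "writer_of_prescription": {
      "sort": "animate",
      "provenance": "fixture-choice",
      "distributions": {
        "actor.profession": {
          "medical": 0.9,
          "nonmedical": 0.1
        }
      },
      "fixed": [
        {
          "chain": "actor.animacy",
          "value": "animate"
        }
      ]
    }
  },
  "critical_words": {
    "fence": "fence",
    "guard": "guard",
    "pill": "pill",
    "psychiatrist": "psychiatrist",
    "schizophrenic": "schizophrenic"
  },
  "arg_concept": {
    "category": "writer_of_prescription",
    "context_independent": [
      "actor.animacy"
    ],
    "context_dependent": [
      "actor.profession"
    ],
    "threshold_r": 0.5,
    "diagnosticity": {
      "actor.profession": 1.0
    }
  },
  "roles": [
    {
      "name": "actor",
      "weight": 0.5,
      "category": "writer_of_prescription",
      "profile": {
        "actor.profession": 1.0
      },
      "restrictions": [
        "actor.animacy"
      ]
    },
    {
      "name": "recipient",
      "weight": 0.35,
      "category": "recipient_of_prescription",
      "profile": {
        "recipient.condition": 1.0
      },
      "restrictions": [
        "recipient.animacy"
      ]
    },
    {
      "name": "theme",
      "weight": 0.15,
      "category": "prescribed_medicine",
      "profile": {
        "theme.form": 1.0
      },
      "restrictions": []
    }
  ]
}
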