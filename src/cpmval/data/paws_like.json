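{
 "name": "paws_like",
 "type": "risk_score",
 "provenance": "illustrative fixture: age-banded vital-sign warning score; bands and points are NOT the published ones",
 "age_range": [
  0.08333333333333333,
  16.0
 ],
 "age_band_unit": "years",
 "items": [
  {
   "variable": "heart_rate",
   "bands": [
    {
     "age": [
      0.0,
      1.0
     ],
     "intervals": [
      {
       "value": [
        0,
        90
       ],
       "points": 2
      },
      {
       "value": [
        90,
        161
       ],
       "points": 0
      },
      {
       "value": [
        161,
        400
       ],
       "points": 2
      }
     ]
    },
    {
     "age": [
      1.0,
      5.0
     ],
     "intervals": [
      {
       "value": [
        0,
        80
       ],
       "points": 2
      },
      {
       "value": [
        80,
        141
       ],
       "points": 0
      },
      {
       "value": [
        141,
        400
       ],
       "points": 2
      }
     ]
    },
    {
     "age": [
      5.0,
      12.0
     ],
     "intervals": [
      {
       "value": [
        0,
        70
       ],
       "points": 2
      },
      {
       "value": [
        70,
        121
       ],
       "points": 0
      },
      {
       "value": [
        121,
        400
       ],
       "points": 2
      }
     ]
    },
    {
     "age": [
      12.0,
      16.0
     ],
     "intervals": [
      {
       "value": [
        0,
        60
       ],
       "points": 2
      },
      {
       "value": [
        60,
        101
       ],
       "points": 0
      },
      {
       "value": [
        101,
        400
       ],
       "points": 2
      }
     ]
    }
   ]
  },
  {
   "variable": "resp_rate",
   "bands": [
    {
     "age": [
      0.0,
      1.0
     ],
     "intervals": [
      {
       "value": [
        0,
        25
       ],
       "points": 2
      },
      {
       "value": [
        25,
        51
       ],
       "points": 0
      },
      {
       "value": [
        51,
        200
       ],
       "points": 2
      }
     ]
    },
    {
     "age": [
      1.0,
      5.0
     ],
     "intervals": [
      {
       "value": [
        0,
        20
       ],
       "points": 2
      },
      {
       "value": [
        20,
        41
       ],
       "points": 0
      },
      {
       "value": [
        41,
        200
       ],
       "points": 2
      }
     ]
    },
    {
     "age": [
      5.0,
      12.0
     ],
     "intervals": [
      {
       "value": [
        0,
        15
       ],
       "points": 2
      },
      {
       "value": [
        15,
        31
       ],
       "points": 0
      },
      {
       "value": [
        31,
        200
       ],
       "points": 2
      }
     ]
    },
    {
     "age": [
      12.0,
      16.0
     ],
     "intervals": [
      {
       "value": [
        0,
        10
       ],
       "points": 2
      },
      {
       "value": [
        10,
        26
       ],
       "points": 0
      },
      {
       "value": [
        26,
        200
       ],
       "points": 2
      }
     ]
    }
   ]
  },
  {
   "variable": "temperature",
   "bands": [
    {
     "age": [
      0.0,
      16.0
     ],
     "intervals": [
      {
       "value": [
        34.0,
        36.0
       ],
       "points": 1
      },
      {
       "value": [
        36.0,
        38.5
       ],
       "points": 0
      },
      {
       "value": [
        38.5,
        43.0
       ],
       "points": 1
      }
     ]
    }
   ]
  },
  {
   "variable": "oxygen_sat_low",
   "points": {
    "0": 0,
    "1": 2
   }
  },
  {
   "variable": "ill_appearance",
   "points": {
    "0": 0,
    "1": 2
   }
  },
  {
   "variable": "conscious_level",
   "points": {
    "alert": 0,
    "voice": 1,
    "pain": 2,
    "unresponsive": 3
   }
  }
 ],
 "cutoffs": [
  {
   "name": "positive",
   "op": ">=",
   "value": 3
  }
 ],
 "schema_ref": {
  "variables": [
   {
    "name": "age",
    "kind": "continuous",
    "units": "years",
    "non_deviant_default": null,
    "allowed_range": [
     0.0,
     18.0
    ],
    "aliases": []
   },
   {
    "name": "temperature",
    "kind": "continuous",
    "units": "\u00b0C",
    "non_deviant_default": 37.0,
    "allowed_range": [
     34.0,
     43.0
    ],
    "aliases": []
   },
   {
    "name": "crp",
    "kind": "continuous",
    "units": "mg/L",
    "non_deviant_default": 5.0,
    "allowed_range": [
     0.1,
     400.0
    ],
    "aliases": [
     "poc_crp"
    ]
   },
   {
    "name": "ill_appearance",
    "kind": "binary",
    "units": "",
    "non_deviant_default": 0,
    "allowed_range": [
     0,
     1
    ],
    "aliases": [
     "ill_appearing"
    ]
   },
   {
    "name": "tachypnoea",
    "kind": "binary",
    "units": "",
    "non_deviant_default": 0,
    "allowed_range": [
     0,
     1
    ],
    "aliases": []
   },
   {
    "name": "oxygen_sat_low",
    "kind": "binary",
    "units": "",
    "non_deviant_default": 0,
    "allowed_range": [
     0,
     1
    ],
    "aliases": [
     "hypoxia"
    ]
   },
   {
    "name": "vomiting",
    "kind": "binary",
    "units": "",
    "non_deviant_default": 0,
    "allowed_range": [
     0,
     1
    ],
    "aliases": []
   },
   {
    "name": "heart_rate",
    "kind": "continuous",
    "units": "/min",
    "non_deviant_default": 110.0,
    "allowed_range": [
     40.0,
     250.0
    ],
    "aliases": []
   },
   {
    "name": "resp_rate",
    "kind": "continuous",
    "units": "/min",
    "non_deviant_default": 25.0,
    "allowed_range": [
     5.0,
     120.0
    ],
    "aliases": []
   },
   {
    "name": "conscious_level",
    "kind": "categorical",
    "units": "",
    "non_deviant_default": "alert",
    "allowed_range": [
     "alert",
     "voice",
     "pain",
     "unresponsive"
    ],
    "aliases": []
   }
  ]
 }
}
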