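{
 "name": "sbi_score_like",
 "type": "risk_score",
 "provenance": "illustrative fixture: additive clinical-item score; points are NOT the published ones",
 "age_range": [
  0.08333333333333333,
  16.0
 ],
 "age_band_unit": "years",
 "items": [
  {
   "variable": "ill_appearance",
   "points": {
    "0": 0,
    "1": 3
   }
  },
  {
   "variable": "tachypnoea",
   "points": {
    "0": 0,
    "1": 2
   }
  },
  {
   "variable": "oxygen_sat_low",
   "points": {
    "0": 0,
    "1": 3
   }
  },
  {
   "variable": "vomiting",
   "points": {
    "0": 0,
    "1": 1
   }
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
        38.0,
        39.5
       ],
       "points": 1
      },
      {
       "value": [
        39.5,
        43.0
       ],
       "points": 2
      }
     ]
    }
   ]
  },
  {
   "variable": "crp",
   "bands": [
    {
     "age": [
      0.0,
      16.0
     ],
     "intervals": [
      {
       "value": [
        20.0,
        100.0
       ],
       "points": 2
      },
      {
       "value": [
        100.0,
        400.0
       ],
       "points": 4
      }
     ]
    }
   ]
  }
 ],
 "cutoffs": [
  {
   "name": "low",
   "op": "<=",
   "value": 5
  },
  {
   "name": "high",
   "op": ">",
   "value": 8
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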