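{
 "name": "sbi_model_like",
 "type": "binomial",
 "provenance": "illustrative fixture: binomial serious-bacterial-infection model; coefficients are NOT published values",
 "categories": [
  "no_sbi",
  "sbi"
 ],
 "reference": "no_sbi",
 "terms": [
  {
   "variable": "temperature",
   "transform": "identity"
  },
  {
   "variable": "crp",
   "transform": "log"
  },
  {
   "variable": "ill_appearance",
   "transform": "identity"
  },
  {
   "variable": "vomiting",
   "transform": "identity"
  }
 ],
 "coefficients": {
  "sbi": {
   "intercept": -17.0,
   "betas": [
    0.35,
    0.8,
    0.95,
    0.3
   ]
  }
 },
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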