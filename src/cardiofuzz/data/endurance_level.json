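{
 "name": "endurance-level",
 "description": "Scores cardiorespiratory endurance (0-100) from resting heart rate (bpm) and heart rate recovery (bpm).",
 "inputs": [
  {
   "name": "RHR",
   "universe": [
    50,
    90
   ],
   "terms": [
    {
     "label": "S",
     "knots": [
      50,
      50,
      55,
      60
     ],
     "shoulder": "left"
    },
    {
     "label": "E",
     "knots": [
      55,
      60.0,
      60.0,
      65
     ]
    },
    {
     "label": "G",
     "knots": [
      60,
      65.0,
      65.0,
      70
     ]
    },
    {
     "label": "AA",
     "knots": [
      65,
      70.0,
      70.0,
      75
     ]
    },
    {
     "label": "A",
     "knots": [
      70,
      75.0,
      75.0,
      80
     ]
    },
    {
     "label": "BA",
     "knots": [
      75,
      80.0,
      80.0,
      85
     ]
    },
    {
     "label": "P",
     "knots": [
      80,
      85,
      90,
      90
     ],
     "shoulder": "right"
    }
   ]
  },
  {
   "name": "HRR",
   "universe": [
    20,
    70
   ],
   "terms": [
    {
     "label": "O",
     "knots": [
      20,
      20,
      29,
      38
     ],
     "shoulder": "left"
    },
    {
     "label": "SO",
     "knots": [
      29,
      38.0,
      38.0,
      47
     ]
    },
    {
     "label": "Q",
     "knots": [
      38,
      47.0,
      47.0,
      56
     ]
    },
    {
     "label": "SY",
     "knots": [
      47,
      56.0,
      56.0,
      65
     ]
    },
    {
     "label": "Y",
     "knots": [
      55,
      65,
      70,
      70
     ],
     "shoulder": "right"
    }
   ]
  }
 ],
 "output": {
  "name": "CEL",
  "universe": [
   0,
   100
  ],
  "terms": [
   {
    "label": "PS",
    "knots": [
     0,
     0,
     10,
     30
    ],
    "shoulder": "left"
   },
   {
    "label": "M",
    "knots": [
     10,
     30.0,
     30.0,
     50
    ]
   },
   {
    "label": "G",
    "knots": [
     30,
     50.0,
     50.0,
     70
    ]
   },
   {
    "label": "E",
    "knots": [
     50,
     70.0,
     70.0,
     90
    ]
   },
   {
    "label": "SE",
    "knots": [
     70,
     90,
     100,
     100
    ],
    "shoulder": "right"
   }
  ]
 },
 "rules": [
  {
   "if": {
    "HRR": "O",
    "RHR": "P"
   },
   "then": "PS"
  },
  {
   "if": {
    "HRR": "O",
    "RHR": "BA"
   },
   "then": "PS"
  },
  {
   "if": {
    "HRR": "O",
    "RHR": "A"
   },
   "then": "PS"
  },
  {
   "if": {
    "HRR": "O",
    "RHR": "AA"
   },
   "then": "M"
  },
  {
   "if": {
    "HRR": "O",
    "RHR": "G"
   },
   "then": "M"
  },
  {
   "if": {
    "HRR": "O",
    "RHR": "E"
   },
   "then": "G"
  },
  {
   "if": {
    "HRR": "O",
    "RHR": "S"
   },
   "then": "G"
  },
  {
   "if": {
    "HRR": "SO",
    "RHR": "P"
   },
   "then": "PS"
  },
  {
   "if": {
    "HRR": "SO",
    "RHR": "BA"
   },
   "then": "PS"
  },
  {
   "if": {
    "HRR": "SO",
    "RHR": "A"
   },
   "then": "M"
  },
  {
   "if": {
    "HRR": "SO",
    "RHR": "AA"
   },
   "then": "M"
  },
  {
   "if": {
    "HRR": "SO",
    "RHR": "G"
   },
   "then": "G"
  },
  {
   "if": {
    "HRR": "SO",
    "RHR": "E"
   },
   "then": "G"
  },
  {
   "if": {
    "HRR": "SO",
    "RHR": "S"
   },
   "then": "E"
  },
  {
   "if": {
    "HRR": "Q",
    "RHR": "P"
   },
   "then": "PS"
  },
  {
   "if": {
    "HRR": "Q",
    "RHR": "BA"
   },
   "then": "M"
  },
  {
   "if": {
    "HRR": "Q",
    "RHR": "A"
   },
   "then": "M"
  },
  {
   "if": {
    "HRR": "Q",
    "RHR": "AA"
   },
   "then": "G"
  },
  {
   "if": {
    "HRR": "Q",
    "RHR": "G"
   },
   "then": "G"
  },
  {
   "if": {
    "HRR": "Q",
    "RHR": "E"
   },
   "then": "E"
  },
  {
   "if": {
    "HRR": "Q",
    "RHR": "S"
   },
   "then": "E"
  },
  {
   "if": {
    "HRR": "SY",
    "RHR": "P"
   },
   "then": "M"
  },
  {
   "if": {
    "HRR": "SY",
    "RHR": "BA"
   },
   "then": "M"
  },
  {
   "if": {
    "HRR": "SY",
    "RHR": "A"
   },
   "then": "G"
  },
  {
   "if": {
    "HRR": "SY",
    "RHR": "AA"
   },
   "then": "G"
  },
  {
   "if": {
    "HRR": "SY",
    "RHR": "G"
   },
   "then": "E"
  },
  {
   "if": {
    "HRR": "SY",
    "RHR": "E"
   },
   "then": "E"
  },
  {
   "if": {
    "HRR": "SY",
    "RHR": "S"
   },
   "then": "SE"
  },
  {
   "if": {
    "HRR": "Y",
    "RHR": "P"
   },
   "then": "M"
  },
  {
   "if": {
    "HRR": "Y",
    "RHR": "BA"
   },
   "then": "G"
  },
  {
   "if": {
    "HRR": "Y",
    "RHR": "A"
   },
   "then": "G"
  },
  {
   "if": {
    "HRR": "Y",
    "RHR": "AA"
   },
   "then": "E"
  },
  {
   "if": {
    "HRR": "Y",
    "RHR": "G"
   },
   "then": "E"
  },
  {
   "if": {
    "HRR": "Y",
    "RHR": "E"
   },
   "then": "SE"
  },
  {
   "if": {
    "HRR": "Y",
    "RHR": "S"
   },
   "then": "SE"
  }
 ],
 "cog_samples": 1201,
 "display": {
  "PS": [
   "Please improve",
   "Please Strengthen"
  ],
  "M": [
   "Medium"
  ],
  "G": [
   "Good"
  ],
  "E": [
   "Excellent"
  ],
  "SE": [
   "Special Excellent"
  ]
 }
}
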