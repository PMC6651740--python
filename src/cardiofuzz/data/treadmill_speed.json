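{
 "name": "treadmill-speed",
 "description": "Recommends a treadmill speed (km/h) from resting heart rate (bpm) and planned exercise time (min).",
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
   "name": "Time",
   "universe": [
    10,
    70
   ],
   "terms": [
    {
     "label": "VF",
     "knots": [
      10,
      10,
      15,
      25
     ],
     "shoulder": "left"
    },
    {
     "label": "F",
     "knots": [
      15,
      25.0,
      25.0,
      35
     ]
    },
    {
     "label": "S",
     "knots": [
      25,
      35.0,
      35.0,
      45
     ]
    },
    {
     "label": "M",
     "knots": [
      35,
      45.0,
      45.0,
      55
     ]
    },
    {
     "label": "VM",
     "knots": [
      45,
      55,
      70,
      70
     ],
     "shoulder": "right"
    }
   ]
  }
 ],
 "output": {
  "name": "TS",
  "universe": [
   0,
   12
  ],
  "terms": [
   {
    "label": "SS",
    "knots": [
     0,
     0,
     1.5,
     3
    ],
    "shoulder": "left"
   },
   {
    "label": "LS",
    "knots": [
     1.5,
     3.0,
     3.0,
     4.5
    ]
   },
   {
    "label": "S",
    "knots": [
     3,
     4.5,
     4.5,
     6
    ]
   },
   {
    "label": "O",
    "knots": [
     4.5,
     6.0,
     6.0,
     7.5
    ]
   },
   {
    "label": "Q",
    "knots": [
     6,
     7.5,
     7.5,
     9
    ]
   },
   {
    "label": "LQ",
    "knots": [
     7.5,
     9.0,
     9.0,
     10.5
    ]
   },
   {
    "label": "SQ",
    "knots": [
     9,
     10.5,
     12,
     12
    ],
    "shoulder": "right"
   }
  ]
 },
 "rules": [
  {
   "if": {
    "RHR": "P",
    "Time": "VF"
   },
   "then": "S"
  },
  {
   "if": {
    "RHR": "BA",
    "Time": "VF"
   },
   "then": "O"
  },
  {
   "if": {
    "RHR": "A",
    "Time": "VF"
   },
   "then": "Q"
  },
  {
   "if": {
    "RHR": "AA",
    "Time": "VF"
   },
   "then": "LQ"
  },
  {
   "if": {
    "RHR": "G",
    "Time": "VF"
   },
   "then": "LQ"
  },
  {
   "if": {
    "RHR": "E",
    "Time": "VF"
   },
   "then": "SQ"
  },
  {
   "if": {
    "RHR": "S",
    "Time": "VF"
   },
   "then": "SQ"
  },
  {
   "if": {
    "RHR": "P",
    "Time": "F"
   },
   "then": "LS"
  },
  {
   "if": {
    "RHR": "BA",
    "Time": "F"
   },
   "then": "S"
  },
  {
   "if": {
    "RHR": "A",
    "Time": "F"
   },
   "then": "O"
  },
  {
   "if": {
    "RHR": "AA",
    "Time": "F"
   },
   "then": "Q"
  },
  {
   "if": {
    "RHR": "G",
    "Time": "F"
   },
   "then": "Q"
  },
  {
   "if": {
    "RHR": "E",
    "Time": "F"
   },
   "then": "LQ"
  },
  {
   "if": {
    "RHR": "S",
    "Time": "F"
   },
   "then": "SQ"
  },
  {
   "if": {
    "RHR": "P",
    "Time": "S"
   },
   "then": "LS"
  },
  {
   "if": {
    "RHR": "BA",
    "Time": "S"
   },
   "then": "S"
  },
  {
   "if": {
    "RHR": "A",
    "Time": "S"
   },
   "then": "O"
  },
  {
   "if": {
    "RHR": "AA",
    "Time": "S"
   },
   "then": "O"
  },
  {
   "if": {
    "RHR": "G",
    "Time": "S"
   },
   "then": "Q"
  },
  {
   "if": {
    "RHR": "E",
    "Time": "S"
   },
   "then": "Q"
  },
  {
   "if": {
    "RHR": "S",
    "Time": "S"
   },
   "then": "LQ"
  },
  {
   "if": {
    "RHR": "P",
    "Time": "M"
   },
   "then": "SS"
  },
  {
   "if": {
    "RHR": "BA",
    "Time": "M"
   },
   "then": "LS"
  },
  {
   "if": {
    "RHR": "A",
    "Time": "M"
   },
   "then": "S"
  },
  {
   "if": {
    "RHR": "AA",
    "Time": "M"
   },
   "then": "O"
  },
  {
   "if": {
    "RHR": "G",
    "Time": "M"
   },
   "then": "O"
  },
  {
   "if": {
    "RHR": "E",
    "Time": "M"
   },
   "then": "Q"
  },
  {
   "if": {
    "RHR": "S",
    "Time": "M"
   },
   "then": "Q"
  },
  {
   "if": {
    "RHR": "P",
    "Time": "VM"
   },
   "then": "SS"
  },
  {
   "if": {
    "RHR": "BA",
    "Time": "VM"
   },
   "then": "SS"
  },
  {
   "if": {
    "RHR": "A",
    "Time": "VM"
   },
   "then": "LS"
  },
  {
   "if": {
    "RHR": "AA",
    "Time": "VM"
   },
   "then": "LS"
  },
  {
   "if": {
    "RHR": "G",
    "Time": "VM"
   },
   "then": "S"
  },
  {
   "if": {
    "RHR": "E",
    "Time": "VM"
   },
   "then": "O"
  },
  {
   "if": {
    "RHR": "S",
    "Time": "VM"
   },
   "then": "O"
  }
 ],
 "cog_samples": 1201,
 "display": {
  "SS": [
   "Special Slow"
  ],
  "LS": [
   "Little Slow"
  ],
  "S": [
   "Slow"
  ],
  "O": [
   "Ordinary"
  ],
  "Q": [
   "Quick"
  ],
  "LQ": [
   "Little Quick"
  ],
  "SQ": [
   "Special Quick"
  ]
 }
}
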