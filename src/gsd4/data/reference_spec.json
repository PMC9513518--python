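{
 "cells": [
  {
   "count": 8,
   "n": "N3",
   "h": "H0",
   "cardiac": "absent",
   "outcome": {
    "vital": "deceased",
    "death_age_range": [
     0.5,
     3.5
    ]
   }
  },
  {
   "count": 5,
   "n": "N3",
   "h": "H0",
   "outcome": {
    "vital": "deceased",
    "death_age_range": [
     0.5,
     3.5
    ]
   }
  },
  {
   "count": 3,
   "n": "N2",
   "h": "H0",
   "cardiac": "present",
   "outcome": {
    "followup_age_range": [
     84.0,
     180.0
    ]
   }
  },
  {
   "count": 2,
   "n": "N1",
   "h": "H0",
   "cardiac": "absent",
   "outcome": {
    "followup_age_range": [
     12.0,
     240.0
    ]
   }
  },
  {
   "count": 2,
   "n": "N0",
   "h": "H1",
   "cardiac": "absent",
   "outcome": {
    "vital": "deceased",
    "death_age_range": [
     48.5,
     120.0
    ]
   }
  },
  {
   "count": 6,
   "n": "N0",
   "h": "H1",
   "cardiac": "absent",
   "outcome": {
    "followup_age_range": [
     12.0,
     240.0
    ]
   }
  },
  {
   "count": 1,
   "n": "N0",
   "h": "H1",
   "cardiac": "present",
   "outcome": {
    "followup_age_range": [
     12.0,
     240.0
    ]
   }
  },
  {
   "count": 1,
   "n": "N0",
   "h": "H1",
   "outcome": {
    "followup_age_range": [
     12.0,
     240.0
    ]
   }
  },
  {
   "count": 2,
   "n": "N0",
   "h": "H2",
   "cardiac": "absent",
   "outcome": {
    "vital": "deceased",
    "death_age_range": [
     60.5,
     240.0
    ]
   }
  },
  {
   "count": 1,
   "n": "N0",
   "h": "H2",
   "cardiac": "present",
   "outcome": {
    "followup_age_range": [
     60.5,
     240.0
    ]
   }
  },
  {
   "count": 4,
   "n": "N0",
   "h": "H3",
   "cardiac": "absent",
   "outcome": {
    "vital": "deceased",
    "death_age_range": [
     6.5,
     34.5
    ]
   }
  },
  {
   "count": 1,
   "n": "N0",
   "h": "H3",
   "cardiac": "present",
   "outcome": {
    "vital": "deceased",
    "death_age_range": [
     6.5,
     34.5
    ]
   }
  },
  {
   "count": 2,
   "n": "N0",
   "h": "H3",
   "outcome": {
    "followup_age_range": [
     60.5,
     180.0
    ],
    "transplant_age_range": [
     10.0,
     50.0
    ]
   }
  },
  {
   "count": 7,
   "n": "N1",
   "h": "H1",
   "cardiac": "present",
   "outcome": {
    "followup_age_range": [
     12.0,
     240.0
    ]
   }
  },
  {
   "count": 8,
   "n": "N1",
   "h": "H1",
   "cardiac": "absent",
   "outcome": {
    "followup_age_range": [
     12.0,
     240.0
    ]
   }
  },
  {
   "count": 4,
   "n": "N1",
   "h": "H1",
   "cardiac": "absent",
   "outcome": {
    "vital": "deceased",
    "death_age_range": [
     6.5,
     34.5
    ]
   }
  },
  {
   "count": 1,
   "n": "N1",
   "h": "H1",
   "cardiac": "absent",
   "outcome": {
    "vital": "deceased",
    "death_age_range": [
     48.5,
     120.0
    ]
   }
  },
  {
   "count": 1,
   "n": "N1",
   "h": "H3",
   "cardiac": "present",
   "outcome": {
    "vital": "deceased",
    "death_age_range": [
     6.5,
     34.5
    ]
   }
  },
  {
   "count": 3,
   "n": "N1",
   "h": "H3",
   "cardiac": "absent",
   "outcome": {
    "vital": "deceased",
    "death_age_range": [
     6.5,
     34.5
    ]
   }
  },
  {
   "count": 1,
   "n": "N2",
   "h": "H1",
   "cardiac": "present",
   "outcome": {
    "vital": "deceased",
    "death_age_range": [
     6.5,
     34.5
    ]
   }
  },
  {
   "count": 1,
   "n": "N2",
   "h": "H1",
   "cardiac": "absent",
   "outcome": {
    "vital": "deceased",
    "death_age_range": [
     6.5,
     34.5
    ]
   }
  },
  {
   "count": 1,
   "n": "N2",
   "h": "H2",
   "cardiac": "present",
   "outcome": {
    "vital": "deceased",
    "death_age_range": [
     60.5,
     240.0
    ]
   }
  },
  {
   "count": 1,
   "n": "N2",
   "h": "H3",
   "cardiac": "present",
   "outcome": {
    "vital": "deceased",
    "death_age_range": [
     6.5,
     34.5
    ]
   }
  },
  {
   "count": 2,
   "n": "N2",
   "h": "H3",
   "cardiac": "absent",
   "outcome": {
    "vital": "deceased",
    "death_age_range": [
     6.5,
     34.5
    ]
   }
  },
  {
   "count": 4,
   "n": "N3",
   "h": "H1",
   "cardiac": "present",
   "outcome": {
    "vital": "deceased",
    "death_age_range": [
     0.5,
     3.5
    ]
   }
  },
  {
   "count": 8,
   "n": "N3",
   "h": "H1",
   "cardiac": "absent",
   "outcome": {
    "vital": "deceased",
    "death_age_range": [
     0.5,
     3.5
    ]
   }
  },
  {
   "count": 2,
   "n": "N0",
   "h": "H0",
   "cardiac": "present",
   "outcome": {
    "followup_age_range": [
     12.0,
     240.0
    ]
   }
  },
  {
   "count": 3,
   "n": "N*",
   "h": "H1",
   "cardiac": "present",
   "outcome": {
    "vital": "deceased",
    "death_age_range": [
     0.5,
     3.5
    ]
   }
  },
  {
   "count": 5,
   "n": "N*",
   "h": "H1",
   "cardiac": "absent",
   "outcome": {
    "vital": "deceased",
    "death_age_range": [
     0.5,
     3.5
    ]
   }
  },
  {
   "count": 17,
   "n": "N*",
   "h": "H1",
   "outcome": {
    "followup_age_range": [
     12.0,
     240.0
    ]
   }
  },
  {
   "count": 3,
   "n": "N*",
   "h": "H1",
   "outcome": {
    "vital": "unknown"
   }
  },
  {
   "count": 2,
   "n": "N?",
   "h": "H?",
   "cardiac": "present",
   "outcome": {
    "vital": "deceased",
    "death_age_range": [
     0.5,
     3.5
    ]
   }
  },
  {
   "count": 8,
   "n": "N?",
   "h": "H?",
   "cardiac": "present",
   "outcome": {
    "followup_age_range": [
     12.0,
     240.0
    ]
   }
  },
  {
   "count": 3,
   "n": "N?",
   "h": "H?",
   "cardiac": "absent",
   "outcome": {
    "followup_age_range": [
     12.0,
     240.0
    ]
   }
  },
  {
   "count": 4,
   "n": "N?",
   "h": "H?",
   "outcome": {
    "vital": "unknown"
   }
  }
 ],
 "n_prenatal_deaths": 19,
 "seed": 20220913
}
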