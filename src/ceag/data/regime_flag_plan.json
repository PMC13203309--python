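{
 "note": "Fixture-pinned per-item flag layout for the packaged synthetic benchmark and public check. The cross-regime overlap structure (which items err in which regime) is not derivable from marginal rates alone; this layout pins it so paired masked-delta comparisons are reproducible. Positions index items in corpus order. ce01 = (C=0,E=1) veneer cell; ce10 = (C=1,E=0); ce00 = (C=0,E=0); remaining items are (C=1,E=1). n1/h1/o1 list positions with N=1, H=1, O=1.",
 "synthetic": {
  "n": 120,
  "regimes": {
   "RUSH": {
    "ce01": [
     0,
     1,
     2,
     3,
     12,
     13,
     14,
     15,
     16,
     17,
     21,
     22,
     23,
     24,
     25,
     26,
     27,
     28,
     29,
     30,
     31,
     32,
     33,
     34,
     35,
     36,
     37,
     38,
     39,
     40,
     41
    ],
    "ce10": [
     42,
     43,
     44,
     45,
     46,
     47,
     48
    ],
    "ce00": [
     49
    ],
    "n1": [
     50,
     51,
     52,
     53,
     54,
     55,
     56,
     57,
     58,
     59,
     60,
     61,
     62,
     63,
     64,
     65,
     66,
     67,
     68,
     69,
     70,
     71,
     72,
     73,
     74
    ],
    "h1": [
     21,
     22,
     23,
     24,
     25,
     26,
     27,
     28,
     29,
     30,
     31,
     32,
     33
    ],
    "o1": []
   },
   "VERIFY": {
    "ce01": [
     0,
     1,
     2,
     3
    ],
    "ce10": [],
    "ce00": [],
    "n1": [
     21,
     22,
     23,
     24,
     25,
     26,
     27,
     28,
     29,
     30,
     31,
     50,
     51,
     52,
     53,
     54,
     55,
     56,
     57,
     58,
     59,
     60,
     61,
     62,
     63,
     64,
     65,
     66,
     67,
     68,
     69,
     70,
     71,
     72,
     73,
     74,
     75,
     76
    ],
    "h1": [],
    "o1": []
   },
   "POETIC": {
    "ce01": [
     0,
     1,
     2,
     3,
     4,
     5,
     6,
     7,
     8,
     9,
     10,
     11,
     12,
     13,
     14,
     15,
     16,
     17
    ],
    "ce10": [
     18,
     19,
     20,
     21,
     22,
     23,
     24,
     25,
     26,
     27,
     28,
     29,
     30,
     31,
     32,
     33,
     34,
     35,
     36,
     37,
     38,
     39,
     40,
     41,
     42,
     43
    ],
    "ce00": [
     44,
     45,
     46,
     47
    ],
    "n1": [
     48,
     49,
     50,
     51,
     52,
     53,
     54,
     55,
     56,
     57,
     58,
     59,
     60,
     61,
     62,
     63,
     64,
     65,
     66,
     67,
     68,
     69,
     70,
     71,
     72
    ],
    "h1": [
     0,
     1,
     2,
     3,
     4,
     5,
     6,
     7,
     8,
     9,
     10,
     11,
     12,
     13,
     14,
     15,
     16,
     17,
     18,
     19,
     20,
     21,
     22,
     23,
     24,
     25,
     26,
     27,
     28,
     29,
     30,
     31,
     32,
     33,
     34,
     35,
     36,
     37,
     38,
     39,
     40,
     41,
     42,
     43,
     44,
     45,
     46,
     47,
     48,
     49,
     50,
     51,
     52,
     53,
     54,
     55,
     56,
     57,
     58,
     59
    ],
    "o1": [
     48,
     49,
     50,
     51,
     52,
     53
    ]
   },
   "POSTER": {
    "ce01": [
     0,
     1,
     2,
     3,
     4,
     5,
     6,
     7,
     8,
     9,
     10
    ],
    "ce10": [
     11,
     12,
     13
    ],
    "ce00": [],
    "n1": [
     21,
     22,
     23,
     24,
     25,
     26,
     27,
     28,
     29,
     30,
     31,
     50,
     51,
     52,
     53,
     54,
     55,
     56,
     57,
     58,
     59,
     60,
     61,
     62,
     77,
     78
    ],
    "h1": [],
    "o1": [
     0,
     1,
     2,
     3,
     4,
     5,
     6,
     7,
     8,
     9,
     10,
     11,
     12,
     13,
     14,
     15,
     16,
     17,
     18,
     19,
     20,
     21,
     22,
     23,
     24,
     25,
     26,
     27,
     28,
     29,
     30,
     31,
     32,
     33,
     34,
     35,
     36,
     37,
     38,
     39,
     40,
     41,
     42,
     43,
     44,
     45,
     46,
     47,
     48,
     49,
     50,
     51,
     52,
     53,
     54,
     55,
     56,
     57,
     58,
     59,
     60,
     61,
     62,
     63,
     64,
     65,
     66,
     67,
     68,
     69,
     70,
     71,
     72,
     73,
     74,
     75,
     76,
     77,
     78,
     79,
     80,
     81,
     82,
     83,
     84,
     85,
     86,
     87,
     88,
     89,
     90,
     91,
     92,
     93,
     94,
     95,
     96,
     97,
     98,
     99,
     100,
     101,
     102,
     103,
     104,
     105,
     106,
     107,
     108,
     109,
     110,
     111,
     112,
     113,
     114,
     115,
     116,
     117,
     118,
     119
    ]
   }
  }
 },
 "public": {
  "n": 12,
  "regimes": {
   "RUSH": {
    "ce01": [
     0,
     1,
     2,
     3,
     4,
     5,
     6,
     7
    ],
    "ce10": [],
    "ce00": [],
    "n1": [
     8,
     9,
     10
    ],
    "h1": [
     0
    ],
    "o1": []
   },
   "VERIFY": {
    "ce01": [],
    "ce10": [],
    "ce00": [],
    "n1": [
     0,
     1,
     2,
     3,
     4,
     5
    ],
    "h1": [],
    "o1": []
   },
   "POETIC": {
    "ce01": [
     0,
     1
    ],
    "ce10": [],
    "ce00": [],
    "n1": [
     2,
     3,
     4,
     5,
     6
    ],
    "h1": [
     0,
     1,
     2,
     3,
     4,
     5,
     6,
     7
    ],
    "o1": [
     2
    ]
   },
   "POSTER": {
    "ce01": [],
    "ce10": [],
    "ce00": [],
    "n1": [
     0,
     1,
     2,
     3,
     4,
     5
    ],
    "h1": [],
    "o1": [
     0,
     1,
     2,
     3,
     4,
     5,
     6,
     7,
     8,
     9,
     10,
     11
    ]
   }
  }
 }
}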