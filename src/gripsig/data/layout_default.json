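{
 "pitch_mm": 4.0,
 "sensel_area_mm2": 16.0,
 "pressure_max_kPa": 517.0,
 "n_sensels_total": 361,
 "regions": [
  {
   "id": 1,
   "label": "Thumb, distal phalanx",
   "class": "thumb",
   "sensel_ids": [
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
    16
   ],
   "render_xy": [
    1.0,
    4.2
   ]
  },
  {
   "id": 2,
   "label": "Thumb, proximal phalanx",
   "class": "thumb",
   "sensel_ids": [
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
    28
   ],
   "render_xy": [
    1.4,
    3.2
   ]
  },
  {
   "id": 3,
   "label": "Index finger, distal phalanx",
   "class": "finger",
   "sensel_ids": [
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
    44
   ],
   "render_xy": [
    2.4,
    6.2
   ]
  },
  {
   "id": 4,
   "label": "Index finger, intermediate phalanx",
   "class": "finger",
   "sensel_ids": [
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
    56
   ],
   "render_xy": [
    2.4,
    5.2
   ]
  },
  {
   "id": 5,
   "label": "Index finger, proximal phalanx",
   "class": "finger",
   "sensel_ids": [
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
    68
   ],
   "render_xy": [
    2.4,
    4.2
   ]
  },
  {
   "id": 6,
   "label": "Middle finger, distal phalanx",
   "class": "finger",
   "sensel_ids": [
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
    84
   ],
   "render_xy": [
    3.3,
    6.6
   ]
  },
  {
   "id": 7,
   "label": "Middle finger, intermediate phalanx",
   "class": "finger",
   "sensel_ids": [
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
    96
   ],
   "render_xy": [
    3.3,
    5.6
   ]
  },
  {
   "id": 8,
   "label": "Middle finger, proximal phalanx",
   "class": "finger",
   "sensel_ids": [
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
    108
   ],
   "render_xy": [
    3.3,
    4.6
   ]
  },
  {
   "id": 9,
   "label": "Ring finger, distal phalanx",
   "class": "finger",
   "sensel_ids": [
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
    119,
    120,
    121,
    122,
    123,
    124
   ],
   "render_xy": [
    4.2,
    6.3
   ]
  },
  {
   "id": 10,
   "label": "Ring finger, intermediate phalanx",
   "class": "finger",
   "sensel_ids": [
    125,
    126,
    127,
    128,
    129,
    130,
    131,
    132,
    133,
    134,
    135,
    136
   ],
   "render_xy": [
    4.2,
    5.3
   ]
  },
  {
   "id": 11,
   "label": "Ring finger, proximal phalanx",
   "class": "finger",
   "sensel_ids": [
    137,
    138,
    139,
    140,
    141,
    142,
    143,
    144,
    145,
    146,
    147,
    148
   ],
   "render_xy": [
    4.2,
    4.3
   ]
  },
  {
   "id": 12,
   "label": "Little finger, distal phalanx",
   "class": "finger",
   "sensel_ids": [
    149,
    150,
    151,
    152,
    153,
    154,
    155,
    156,
    157,
    158,
    159,
    160,
    161,
    162,
    163,
    164
   ],
   "render_xy": [
    5.1,
    5.6
   ]
  },
  {
   "id": 13,
   "label": "Little finger, intermediate phalanx",
   "class": "finger",
   "sensel_ids": [
    165,
    166,
    167,
    168,
    169,
    170,
    171,
    172,
    173,
    174,
    175,
    176
   ],
   "render_xy": [
    5.1,
    4.8
   ]
  },
  {
   "id": 14,
   "label": "Little finger, proximal phalanx",
   "class": "finger",
   "sensel_ids": [
    177,
    178,
    179,
    180,
    181,
    182,
    183,
    184,
    185,
    186,
    187,
    188
   ],
   "render_xy": [
    5.1,
    4.0
   ]
  },
  {
   "id": 15,
   "label": "Distal palm, second metacarpal",
   "class": "palm",
   "sensel_ids": [
    189,
    190,
    191,
    192,
    193,
    194,
    195,
    196,
    197,
    198,
    199,
    200,
    201,
    202,
    203,
    204
   ],
   "render_xy": [
    2.6,
    3.2
   ]
  },
  {
   "id": 16,
   "label": "Distal palm, third to fifth metacarpal",
   "class": "palm",
   "sensel_ids": [
    205,
    206,
    207,
    208,
    209,
    210,
    211,
    212,
    213,
    214,
    215,
    216,
    217,
    218,
    219,
    220,
    221,
    222,
    223,
    224,
    225,
    226,
    227,
    228,
    229,
    230,
    231,
    232,
    233,
    234,
    235,
    236,
    237,
    238,
    239,
    240,
    241,
    242,
    243,
    244,
    245,
    246,
    247,
    248,
    249,
    250,
    251,
    252,
    253,
    254,
    255,
    256,
    257,
    258,
    259,
    260,
    261,
    262,
    263,
    264
   ],
   "render_xy": [
    3.9,
    3.1
   ]
  },
  {
   "id": 17,
   "label": "Thenar eminence",
   "class": "palm",
   "sensel_ids": [
    265,
    266,
    267,
    268,
    269,
    270,
    271,
    272,
    273,
    274,
    275,
    276,
    277,
    278,
    279,
    280,
    281,
    282,
    283,
    284,
    285,
    286,
    287,
    288,
    289,
    290,
    291,
    292,
    293,
    294,
    295,
    296,
    297,
    298,
    299,
    300,
    301,
    302,
    303,
    304,
    305,
    306,
    307,
    308,
    309
   ],
   "render_xy": [
    2.0,
    2.0
   ]
  },
  {
   "id": 18,
   "label": "Hypothenar eminence",
   "class": "palm",
   "sensel_ids": [
    310,
    311,
    312,
    313,
    314,
    315,
    316,
    317,
    318,
    319,
    320,
    321,
    322,
    323,
    324,
    325,
    326,
    327,
    328,
    329,
    330,
    331,
    332,
    333,
    334,
    335,
    336,
    337,
    338,
    339,
    340,
    341,
    342,
    343,
    344,
    345,
    346,
    347,
    348,
    349,
    350,
    351,
    352,
    353,
    354,
    355,
    356,
    357,
    358,
    359,
    360,
    361
   ],
   "render_xy": [
    4.4,
    2.0
   ]
  }
 ]
}
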