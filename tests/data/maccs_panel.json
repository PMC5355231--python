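[
 {
  "name": "benzene",
  "smiles": "c1ccccc1",
  "on_bits": [
   161,
   162,
   164
  ]
 },
 {
  "name": "ethanol",
  "smiles": "CCO",
  "on_bits": [
   81,
   108,
   113,
   138,
   152,
   154,
   156,
   159,
   163
  ]
 },
 {
  "name": "acetic_acid",
  "smiles": "CC(=O)O",
  "on_bits": [
   122,
   138,
   153,
   156,
   158,
   159,
   163
  ]
 },
 {
  "name": "toluene",
  "smiles": "Cc1ccccc1",
  "on_bits": [
   159,
   161,
   162,
   164
  ]
 },
 {
  "name": "phenol",
  "smiles": "Oc1ccccc1",
  "on_bits": [
   112,
   126,
   138,
   142,
   151,
   156,
   161,
   162,
   163,
   164
  ]
 },
 {
  "name": "aniline",
  "smiles": "Nc1ccccc1",
  "on_bits": [
   83,
   132,
   134,
   150,
   155,
   157,
   160,
   161,
   162,
   164
  ]
 },
 {
  "name": "pyridine",
  "smiles": "c1ccncc1",
  "on_bits": [
   64,
   97,
   120,
   136,
   160,
   161,
   162,
   164
  ]
 },
 {
  "name": "naphthalene",
  "smiles": "c1ccc2ccccc2c1",
  "on_bits": [
   100,
   104,
   124,
   144,
   161,
   162,
   164
  ]
 },
 {
  "name": "caffeine",
  "smiles": "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",
  "on_bits": [
   36,
   37,
   64,
   74,
   76,
   78,
   79,
   82,
   84,
   88,
   91,
   92,
   94,
   95,
   96,
   97,
   100,
   104,
   105,
   109,
   112,
   116,
   119,
   120,
   121,
   124,
   126,
   135,
   136,
   140,
   141,
   142,
   143,
   147,
   148,
   149,
   153,
   155,
   157,
   158,
   159,
   160,
   161,
   162,
   163,
   164
  ]
 },
 {
  "name": "aspirin",
  "smiles": "CC(=O)Oc1ccccc1C(=O)O",
  "on_bits": [
   88,
   112,
   122,
   125,
   126,
   135,
   138,
   139,
   142,
   143,
   145,
   149,
   151,
   153,
   156,
   158,
   159,
   161,
   162,
   163,
   164
  ]
 },
 {
  "name": "glucose",
  "smiles": "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O",
  "on_bits": [
   52,
   53,
   56,
   71,
   81,
   88,
   89,
   90,
   97,
   108,
   122,
   126,
   130,
   131,
   136,
   138,
   139,
   142,
   145,
   149,
   151,
   152,
   154,
   156,
   158,
   162,
   163,
   164
  ]
 },
 {
  "name": "ibuprofen",
  "smiles": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
  "on_bits": [
   73,
   114,
   122,
   138,
   140,
   148,
   153,
   154,
   156,
   158,
   159,
   161,
   162,
   163,
   164
  ]
 },
 {
  "name": "paracetamol",
  "smiles": "CC(=O)Nc1ccc(O)cc1",
  "on_bits": [
   91,
   109,
   112,
   116,
   126,
   130,
   132,
   134,
   138,
   142,
   150,
   151,
   153,
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
  ]
 },
 {
  "name": "nicotine",
  "smiles": "CN1CCC[C@H]1c1cccnc1",
  "on_bits": [
   61,
   64,
   74,
   79,
   82,
   84,
   85,
   92,
   95,
   97,
   99,
   107,
   110,
   114,
   115,
   117,
   119,
   120,
   121,
   128,
   136,
   141,
   146,
   147,
   149,
   152,
   155,
   157,
   159,
   160,
   161,
   162,
   164
  ]
 },
 {
  "name": "cyclohexane",
  "smiles": "C1CCCCC1",
  "on_bits": [
   117,
   127,
   128,
   146,
   162,
   164
  ]
 },
 {
  "name": "urea",
  "smiles": "NC(N)=O",
  "on_bits": [
   36,
   42,
   76,
   83,
   105,
   109,
   116,
   130,
   141,
   150,
   153,
   155,
   157,
   160,
   163
  ]
 },
 {
  "name": "chlorobenzene",
  "smiles": "Clc1ccccc1",
  "on_bits": [
   86,
   102,
   106,
   133,
   161,
   162,
   164
  ]
 },
 {
  "name": "doxorubicin",
  "smiles": "COc1cccc2C(=O)c3c(O)c4C[C@](O)(C[C@H](O[C@H]5C[C@H](N)[C@H](O)[C@H](C)O5)c4c(O)c3C(=O)c12)C(=O)CO",
  "on_bits": [
   52,
   53,
   56,
   65,
   71,
   81,
   83,
   88,
   89,
   90,
   92,
   94,
   96,
   97,
   100,
   103,
   104,
   107,
   108,
   110,
   111,
   112,
   122,
   124,
   125,
   126,
   127,
   128,
   130,
   131,
   132,
   135,
   136,
   138,
   139,
   142,
   143,
   144,
   145,
   148,
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
  ]
 },
 {
  "name": "daunorubicin",
  "smiles": "COc1cccc2C(=O)c3c(O)c4C[C@](O)(C[C@H](O[C@H]5C[C@H](N)[C@H](O)[C@H](C)O5)c4c(O)c3C(=O)c12)C(C)=O",
  "on_bits": [
   53,
   56,
   65,
   71,
   83,
   88,
   89,
   90,
   92,
   94,
   96,
   97,
   100,
   103,
   104,
   107,
   110,
   111,
   112,
   115,
   122,
   124,
   125,
   126,
   127,
   130,
   131,
   132,
   135,
   136,
   138,
   139,
   140,
   142,
   143,
   144,
   145,
   148,
   149,
   150,
   151,
   153,
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
  ]
 },
 {
  "name": "methotrexate",
  "smiles": "CN(Cc1cnc2nc(N)nc(N)c2n1)c1ccc(cc1)C(=O)N[C@@H](CCC(=O)O)C(=O)O",
  "on_bits": [
   24,
   37,
   52,
   53,
   64,
   76,
   78,
   79,
   83,
   84,
   85,
   89,
   90,
   91,
   92,
   94,
   97,
   99,
   100,
   103,
   104,
   105,
   109,
   110,
   114,
   116,
   117,
   119,
   120,
   121,
   122,
   124,
   130,
   131,
   132,
   134,
   135,
   136,
   138,
   139,
   141,
   144,
   145,
   146,
   147,
   150,
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
  ]
 }
]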