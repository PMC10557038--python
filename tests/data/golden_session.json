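{
 "Forward": {
  "Dt": 5e-09,
  "T0": 0.0,
  "T1": 5e-09,
  "WavelengthNm": 785.0
 },
 "Media": [
  {
   "alphaDb": 1e-08,
   "g": 0.01,
   "mua": 0.0164,
   "mus": 0.7474747474747475,
   "n": 1.37
  },
  {
   "alphaDb": 0.0,
   "g": 0.01,
   "mua": 0.0115,
   "mus": 0.9494949494949495,
   "n": 1.37
  },
  {
   "alphaDb": 0.0,
   "g": 0.01,
   "mua": 0.0026,
   "mus": 0.010101010101010102,
   "n": 1.37
  },
  {
   "alphaDb": 6e-06,
   "g": 0.01,
   "mua": 0.0186,
   "mus": 1.1212121212121213,
   "n": 1.37
  },
  {
   "alphaDb": 6e-06,
   "g": 0.01,
   "mua": 0.0186,
   "mus": 1.1212121212121213,
   "n": 1.37
  }
 ],
 "Mesh": {
  "MeshID": "head.msh"
 },
 "Optode": {
  "Detector": [
   {
    "AchievedMM": 5.01,
    "Dir": [
     0.0,
     0.0,
     -1.0
    ],
    "Pos": [
     5.0,
     0.0,
     69.5
    ],
    "R": 0.7,
    "RequestedMM": 5.0
   },
   {
    "AchievedMM": 49.97,
    "Dir": [
     0.0,
     0.0,
     -1.0
    ],
    "Pos": [
     10.0,
     0.0,
     68.5
    ],
    "R": 0.7,
    "RequestedMM": 50.0
   }
  ],
  "Source": {
   "Dir": [
    0.0,
    0.0,
    -1.0
   ],
   "Pos": [
    0.0,
    0.0,
    70.0
   ],
   "Type": "pencil"
  }
 },
 "POI": [
  5.0,
  0.0,
  69.5
 ],
 "Session": {
  "ID": "golden",
  "Photons": 12345,
  "RNGSeed": 7
 }
}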