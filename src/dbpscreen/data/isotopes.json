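{
  "_comment": "IUPAC/CODATA isotope exact masses (Da) and natural abundances (mole fraction) for the elements supported by Formula. Entries are [mass, abundance], sorted by mass.",
  "C":  [[12.0, 0.9893], [13.00335484, 0.0107]],
  "H":  [[1.00782503, 0.999885], [2.01410178, 0.000115]],
  "N":  [[14.00307401, 0.99636], [15.00010890, 0.00364]],
  "O":  [[15.99491462, 0.99757], [16.99913176, 0.00038], [17.99915961, 0.00205]],
  "S":  [[31.97207100, 0.9499], [32.97145876, 0.0075], [33.96786690, 0.0425], [35.96708076, 0.0001]],
  "P":  [[30.97376163, 1.0]],
  "Si": [[27.97692653, 0.92223], [28.97649466, 0.04685], [29.97377017, 0.03092]],
  "F":  [[18.99840322, 1.0]],
  "Cl": [[34.96885268, 0.7576], [36.96590259, 0.2424]],
  "Br": [[78.91833710, 0.5069], [80.91629060, 0.4931]],
  "I":  [[126.90447300, 1.0]]
}
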