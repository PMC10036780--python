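{
 "0.80": [
  -85.62360451448949,
  0.0015777751962262557,
  0.7555463692196571,
  0.755213342951311,
  3.199782591074262e-05,
  0.9775542931175971,
  0.9994277324649506,
  0.9997259338740737,
  2.263215661407576e-08,
  0.9999980044953494,
  0.0002004029742678577,
  0.47526560422322567,
  0.0031744085664115293,
  0.9531235214740732,
  6.008311924341439e-05,
  2.951036895353584e-06,
  0.046813444320914846,
  9.700313059153993,
  135.85587844709477,
  8.547945100791008e-05,
  0.000627403882102134,
  3.18771643884616,
  2.0455114136390944,
  0.006270663565595625,
  0.03143332210242449,
  0.03787294248625522,
  -1.0
 ],
 "0.85": [
  -85.60625521040527,
  0.001583607783998599,
  0.7550805362489355,
  0.7546663097802709,
  3.207196081734386e-05,
  0.9777002302050194,
  0.9994276563511111,
  0.9996073788343849,
  2.269797630127156e-08,
  0.9999979974902645,
  0.00020093517106005643,
  0.475085179241478,
  0.003178616107918563,
  0.9454797979382223,
  9.694472177309969e-05,
  5.579723271447176e-06,
  0.05441767757270757,
  9.677979545086467,
  135.86728366432146,
  8.717662345317652e-05,
  0.0008891506885069604,
  3.253212398639426,
  2.1075087264737022,
  0.008181877368995326,
  0.07847172147644417,
  0.08647316754496163,
  -1.0
 ],
 "0.90": [
  -85.59574469018396,
  0.0015871516205200745,
  0.754795240180396,
  0.7542508995902267,
  3.211697828402422e-05,
  0.9777381173917138,
  0.9994269792569485,
  0.9994347848410601,
  2.2738133541484838e-08,
  0.9999979931871943,
  0.00020129998943674228,
  0.47497577992696555,
  0.0031821297076761175,
  0.9378538473541068,
  0.00011750184544619497,
  7.77048730459331e-06,
  0.062020880264821714,
  9.684643750385304,
  135.8563669706752,
  8.808926133837847e-05,
  0.001039168890512165,
  3.278644214992842,
  2.1518484476119255,
  0.01010372072065044,
  0.1252026709632495,
  0.13464728123694222,
  -1.0
 ]
}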