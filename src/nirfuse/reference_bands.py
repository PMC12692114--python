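"""Characteristic wavelengths (nm) retained by the best published model for
each quality trait of 'Dinosaur Egg' apricot plum.

SSC bands come from an SFLA-PLSR model, MC and FF bands from CARS-PLSR
models.  One FF entry was printed with a stray semicolon in place of the
decimal point ("1224;131") and is canonicalised here to 1224.131 nm, matching
the grid spacing of its neighbours.
"""

SSC_BANDS_NM = [
    1200.389, 1206.325, 1265.668, 1313.122, 1319.052, 1324.982, 1330.912,
    1384.267, 1419.824, 1425.75, 1431.675, 1520.513, 1526.433, 1532.353,
    1567.867, 1573.785, 1579.702, 1585.62, 1591.537, 1621.118,
]

MC_BANDS_NM = [
    1069.725, 1188.516, 1230.065, 1265.668, 1313.122, 1354.628, 1425.75,
    1538.273, 1573.785,
]

FF_BANDS_NM = [
    1040.009, 1069.725, 1075.667, 1081.609, 1117.255, 1123.195, 1176.642,
    1182.579, 1224.131, 1384.267, 1396.121, 1419.824, 1425.75, 1461.295,
    1514.592, 1520.513, 1550.111, 1579.702, 1615.202, 1621.118,
]

TRAIT_BAND_LISTS = {
    "ssc_brix": SSC_BANDS_NM,
    "mc_fraction": MC_BANDS_NM,
    "ff_newton": FF_BANDS_NM,
}
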