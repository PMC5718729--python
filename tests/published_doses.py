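"""Published point-dose comparison tables for pediatric anthropomorphic
phantoms (newborn and 12-year-old chest and skull, whole-body axial scans
at 120 kVp, 10 mm beam width, doses in mGy/100 mAs).

Each row: (label, measured, sd, plan, sd, pct_measured_plan,
mc, sd, pct_mc_measured, pct_mc_plan); the percent columns are as printed
in the source tables — measurement-vs-calculation columns normalized to
the TLD measurement, the calculation-vs-calculation column normalized to
the Monte Carlo value.
"""

NEWBORN_CHEST = [
    ("Left Lung",    30.7, 2.0, 29.2, 0.3,  4.9, 30.8, 0.5,  0.3,  5.2),
    ("Right Lung",   28.8, 2.3, 27.6, 0.3,  4.2, 29.3, 0.5,  1.7,  5.8),
    ("Left Rib",     31.4, 2.4, 31.5, 0.3,  0.3, 32.5, 0.5,  3.5,  3.1),
    ("Right Rib",    27.3, 1.5, 29.2, 0.3,  7.0, 31.1, 0.5, 13.9,  6.1),
    ("Sternum",      32.8, 2.1, 31.1, 0.3,  5.2, 30.8, 0.5,  6.1,  1.0),
    ("Left Breast",  28.9, 2.6, 32.3, 0.3, 11.8, 31.1, 0.5,  7.6,  3.9),
    ("Right Breast", 30.8, 3.0, 32.7, 0.3,  6.2, 31.5, 0.5,  2.3,  3.8),
]

CHILD_CHEST = [
    ("Left Lung",    20.2, 1.2, 18.9, 0.1,  6.4, 19.7, 0.8,  2.5,  4.1),
    ("Right Lung",   21.8, 1.2, 19.9, 0.1,  8.7, 20.4, 0.8,  6.4,  2.5),
    ("Left Rib",     19.7, 1.0, 22.0, 0.1, 11.7, 18.5, 0.8,  6.1, 18.9),
    ("Right Rib",    20.7, 1.3, 22.8, 0.1, 10.1, 19.2, 0.8,  7.2, 18.8),
    ("Sternum",      25.9, 1.6, 26.4, 0.2,  1.9, 22.0, 0.8, 15.1, 20.0),
    ("Left Breast",  22.8, 1.3, 20.6, 0.5,  9.6, 19.0, 0.8, 16.7,  8.4),
    ("Right Breast", 23.8, 1.4, 20.8, 0.4, 12.6, 19.2, 0.8, 19.3,  8.3),
]

NEWBORN_SKULL = [
    ("Skull",     23.8, 1.7, 28.1, 0.3, 18.1, 25.3, 0.4, 6.3, 11.1),
    ("Left Eye",  24.7, 1.4, 30.3, 0.3, 22.7, 24.0, 0.4, 2.8, 26.3),
    ("Right Eye", 24.1, 1.5, 30.0, 0.3, 24.5, 23.9, 0.4, 0.8, 25.5),
    ("Jaw",       26.8, 1.9, 29.1, 0.3,  8.6, 29.1, 0.4, 8.6,  0.0),
]

CHILD_SKULL = [
    ("Skull",     18.9, 1.1, 22.8, 0.2, 20.6, 23.1, 0.6, 22.2, 1.3),
    ("Left Eye",  22.3, 1.3, 24.2, 0.2,  8.5, 23.7, 0.6,  6.3, 2.1),
    ("Right Eye", 20.9, 1.3, 22.7, 0.2,  8.6, 22.8, 0.6,  9.1, 0.4),
    ("Jaw",       18.9, 1.0, 22.4, 0.2, 18.5, 21.8, 0.6, 15.3, 2.8),
]

ALL_TABLES = {
    "newborn_chest": NEWBORN_CHEST,
    "child_chest": CHILD_CHEST,
    "newborn_skull": NEWBORN_SKULL,
    "child_skull": CHILD_SKULL,
}
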