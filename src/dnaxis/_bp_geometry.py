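"""Frozen idealized base-pair template coordinates.

Synthetic idealized geometry, generated once by
``scripts/generate_bp_templates.py``: planar base heavy atoms in the
standard base-pair reference frame (helix axis = +z, pseudo-dyad = x,
strand-I backbone side = +y) plus a generic C2'-endo sugar-phosphate
backbone solved by least squares over standard bond lengths, angles
and B-form torsion priors under the 10.4 bp/turn, 3.4 A-rise helix
symmetry.  Strand II is the dyad image (x, -y, -z).  Heavy atoms only.
"""

# fmt: off
BASE_ATOMS = {
    'A': [
        ('N9', -1.2910,  4.4980,  0.0000),
        ('C8',  0.0240,  4.8970,  0.0000),
        ('N7',  0.8770,  3.9020,  0.0000),
        ('C5',  0.0710,  2.7710,  0.0000),
        ('C6',  0.3690,  1.3980,  0.0000),
        ('N6',  1.6110,  0.9090,  0.0000),
        ('N1', -0.6680,  0.5320,  0.0000),
        ('C2', -1.9120,  1.0230,  0.0000),
        ('N3', -2.3200,  2.2900,  0.0000),
        ('C4', -1.2670,  3.1240,  0.0000),
    ],
    'G': [
        ('N9', -1.2890,  4.5510,  0.0000),
        ('C8',  0.0230,  4.9620,  0.0000),
        ('N7',  0.8700,  3.9690,  0.0000),
        ('C5',  0.0710,  2.8330,  0.0000),
        ('C6',  0.4240,  1.4600,  0.0000),
        ('O6',  1.5540,  0.9550,  0.0000),
        ('N1', -0.7000,  0.6410,  0.0000),
        ('C2', -1.9990,  1.0870,  0.0000),
        ('N2', -2.9490,  0.1390, -0.0010),
        ('N3', -2.3420,  2.3640,  0.0010),
        ('C4', -1.2650,  3.1770,  0.0000),
    ],
    'C': [
        ('N1', -1.2850,  4.5420,  0.0000),
        ('C2', -1.4720,  3.1580,  0.0000),
        ('O2', -2.6280,  2.7090,  0.0010),
        ('N3', -0.3910,  2.3440,  0.0000),
        ('C4',  0.8370,  2.8680,  0.0000),
        ('N4',  1.8750,  2.0270,  0.0010),
        ('C5',  1.0560,  4.2750,  0.0000),
        ('C6', -0.0230,  5.0680,  0.0000),
    ],
    'T': [
        ('N1', -1.2840,  4.5000,  0.0000),
        ('C2', -1.4620,  3.1350,  0.0000),
        ('O2', -2.5620,  2.6080,  0.0000),
        ('N3', -0.2980,  2.4070,  0.0000),
        ('C4',  0.9940,  2.8970,  0.0000),
        ('O4',  1.9440,  2.1190,  0.0000),
        ('C5',  1.1060,  4.3380,  0.0000),
        ('C7',  2.4660,  4.9610,  0.0010),
        ('C6', -0.0240,  5.0570,  0.0000),
    ],
}

# generic strand-I sugar-phosphate backbone (C1' anchors the base)
BACKBONE_ATOMS = [
    ('P', -3.0587,  8.2138, -2.1151),
    ('OP1', -3.3476,  9.6298, -2.4570),
    ('OP2', -1.6834,  7.8217, -1.7153),
    ("O5'", -4.0617,  7.7690, -0.9595),
    ("C5'", -3.7747,  8.0365,  0.4266),
    ("C4'", -3.8039,  6.7496,  1.2144),
    ("O4'", -2.4819,  6.1589,  1.1486),
    ("C3'", -4.7403,  5.6878,  0.6270),
    ("O3'", -5.6200,  5.1827,  1.6263),
    ("C2'", -3.7993,  4.5988,  0.1041),
    ("C1'", -2.4800,  5.3460,  0.0000),
]
# fmt: on
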