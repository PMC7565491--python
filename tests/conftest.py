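"""Shared fixtures: the published citcol peptide panel and reference CRPs."""

import pytest

# isolated citcol peptides: name -> (printed [M+H]+, sequence)
CITCOLS = {
    "citcol-1": (3658.1, "VCLFVGKPCWSDADCPSGCSCKPLPLIDAGYCGFL"),
    "citcol-2": (3734.1, "VCLFVGKPCWSDADCPSGCYCKPLPLIDAGYCGFL"),
    "citcol-3": (3814.4, "VGVCLFVGKPCWSDADCPSGCSCKPLPLIDAGYCGFL"),
    "citcol-4": (3890.2, "VGVCLFVGKPCWSDADCPSGCYCKPLPLIDAGYCGFL"),
    "citcol-5": (4046.9, "RVGVCLFVGKPCWSDADCPSGCYCKPLPLIDAGYCGFL"),
    "citcol-6": (4084.1, "NRVGVCLFVGKPCWSDADCPSGCSCKPLPLIDAGYCGFL"),
    "citcol-7": (4101.2, "NRVGVCLFVGKPCKSDANCPSGCYCKPLPLIDAGYCGFL"),
    "citcol-8": (4160.3, "NRVGVCLFVGKPCWSDADCPSGCYCKPLPLIDAGYCGFL"),
}

CITCOL2 = CITCOLS["citcol-2"][1]
CITCOL8 = CITCOLS["citcol-8"][1]

# reference cysteine-rich peptides with printed percent similarity to citcol-8
REFERENCE_CRPS = {
    "P82410": ("QRACPRILKKCRRDSDCPGECICKENGYCG", 43.6),  # MCoTI-III, trypsin inhibitor
    "P01075": ("HADPICNKPCKTHDDCSGAWFCQACWNSARTCGPY", 38.5),
    "P81418": ("AGCIKNGGRCNASAGPPYCCSSYCFQIAGQSYGVCKNR", 31.7),
    "P84781": ("EDKCSPSGAICSGFGPPEQCCSGACVPHPILRIFVCQ", 29.5),
    "P80403": ("CIPKWNRCGPKMDGVPCCEPYTCTSDYYGNCS", 27.3),
    "Q5I2B2": ("AGECVQGRCPSGMCCSQFGYCGRGPKYCGR", 26.7),
    "Q07A30": ("TYSCGGHIDCKDFCKSEGYRGFKCTPKKTCTCFH", 20.0),
}

MCOTI_III = REFERENCE_CRPS["P82410"][0]

# six-amino-acid-variant homolog recovered from the Cucumis melo genome
C_MELO_HOMOLOG = "RLGVCLLVGKPCMSDADCPSGCYCKPVPLLDIGYCGFL"

# observed partial-digest fragment masses of carbamidomethylated citcol-2
CITCOL2_FRAGMENT_MASSES = {
    "VCLFVGK": (822.4, "trypsin"),
    "PLPLIDAGYCGFL": (1435.7, "trypsin"),
    "PCWSDADCPSGCYCKPLPLIDAGYCGFL": (3279.2, "trypsin"),
    "CKPLPLIDAGY": (1246.6, "chymotrypsin"),
    "CKPLPLIDAGYCGFL": (1723.8, "chymotrypsin"),
    "VGKPCWSDADCPSGCY": (1858.6, "chymotrypsin"),
}


@pytest.fixture
def citcols():
    return CITCOLS


@pytest.fixture
def citcol2():
    return CITCOL2


@pytest.fixture
def citcol8():
    return CITCOL8


@pytest.fixture
def reference_crps():
    return REFERENCE_CRPS
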