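"""Small published-scale data tables bundled for worked examples.

These are the desk-scale inputs of the BMP5 sporadic-colorectal-cancer
case series: the eight somatic BMP5 mutations found by exome plus expanded
deep sequencing (sample label and protein-level change), the expanded
cohort size, and the immunohistochemistry positivity counts from the
tissue-microarray survey used for the contingency tests.
"""

from __future__ import annotations

from .assoc_stats import ContingencyTable2x2

#: (sample label, HGVS-style protein change) for the eight BMP5 somatic
#: mutations of the sCRC case series; one mutation per distinct sample.
BMP5_MUTATIONS: list[tuple[str, str]] = [
    ("In-1", "p. R174*"),
    ("In-2", "p. D183G"),
    ("Ex-50", "p. E179*"),
    ("Ex-36", "p. N211I"),
    ("Ex-92", "p. K223D"),
    ("Ex-93", "p. R321*"),
    ("Ex-70", "p. V289 M"),
    ("Ex-2", "p. G384G"),
]

#: expanded deep-sequencing cohort size (distinct sCRC patients screened)
BMP5_COHORT_SIZE: int = 104

#: IHC BMP5 positivity, colorectal tissue microarray:
#: rows normal / adenocarcinoma, columns positive / negative (n = 129 each)
IHC_COLORECTAL = ContingencyTable2x2(a=116, b=13, c=89, d=40)

#: IHC BMP5 positivity, breast tissue microarray:
#: rows invasive ductal carcinoma / normal, columns positive / negative
IHC_BREAST = ContingencyTable2x2(a=21, b=19, c=5, d=35)
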