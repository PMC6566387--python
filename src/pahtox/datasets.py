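"""Small published summary tables used as worked-example inputs.

These are printed dataset-level summaries (a dozen rows each), shipped so
the worked examples and the acceptance script can run without any external
download.  They are inputs to the analysis functions, never expected
outputs baked into them.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["cyp1a_induction_table", "CLUSTER_B_PAHS", "EC80_DOSE_SERIES"]

#: The six AhR-activating exposures that form transcriptomic cluster B.
CLUSTER_B_PAHS = ("retene", "BkF", "BjF", "DB(a,i)P", "DB(a,h)P", "BbF")

_CYP1A_TSV = """\
pah	bin	cluster	log2fc	padj
4h-CPdefP	1	A	0.09	0.76
3-NF	2	A	0.24	0.82
carbazole	2	A	0.15	0.62
9-MA	4	A	0.31	0.13
fluoranthene	5	A	0.26	0.34
1,5-DMN	6	A	0.04	0.76
acenaphthene	6	A	0.16	0.67
2-MN	6	A	0.02	0.99
phenanthrene	7	A	0.11	0.86
anthracene	8	A	0.33	0.99
retene	1	B	2.06	3.05e-57
BkF	2	B	2.18	2.00e-64
BjF	2	B	2.08	1.44e-58
DB(a,i)P	3	B	1.37	1.84e-24
DB(a,h)P	4	B	1.22	1.09e-19
BbF	5	B	1.16	2.71e-17
"""


def cyp1a_induction_table() -> pd.DataFrame:
    """Published cyp1a log2 fold-change and adjusted p-value per exposure.

    One row per PAH treatment at 48 hpf, with its developmental-toxicity bin
    and transcriptomic cluster membership.  The ``cluster`` column is the
    reported grouping, carried along for cross-checks; the elevation call
    itself comes from :func:`pahtox.biomarker.marker_status`.
    """
    return pd.read_csv(io.StringIO(_CYP1A_TSV), sep="\t")


#: Dose series (µM) used to establish the concentration-response of the six
#: morphologically active exposures; keyed by chemical.
EC80_DOSE_SERIES = {
    "4h-CPdefP": (8.5, 11.2, 13.9, 16.7, 19.4, 22.1, 24.8, 27.5, 30.2, 32.9, 35.6),
    "retene": (2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 22),
    "BkF": (0.5, 1.5, 2.5, 3.5, 4.5, 5.5, 6.5, 7.5, 8.5, 9.5, 10.5),
    "3-NF": (0.25, 1, 2.1, 3.3, 4.4, 5.5, 6.6, 7.8, 8.9, 10.1, 11.2),
    "BjF": (4.5, 6.9, 9.3, 11.7, 14.1, 16.5, 18.8, 21.2, 23.6, 26, 28.4),
    "carbazole": (8.5, 12.7, 16.8, 21, 25.1, 29.3, 33.4, 37.6, 41.7, 45.9, 50),
}
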