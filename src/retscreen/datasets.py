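"""Bundled reference cross-tabulations from a published screening validation.

A large teleophthalmology validation study (3520 diabetic patients from ten
primary-care centres) compared an automated fundus-analysis algorithm (ALG)
and screening primary-care physicians (PCP) against the consensus diagnosis
of three reference ophthalmologists (OPH), each grader issuing one of
{DR, NODR, UNG} per patient. Its published patient-level cross-tabulations
are reproduced here as fixture data: they exercise every statistic in
:mod:`retscreen.diagstats` and serve as the worked example for the whole
validation battery.

Rows are the test grader, columns the reference, label order (DR, NODR, UNG).
"""

from __future__ import annotations

import numpy as np

from retscreen.diagstats import ContingencyTable2x2, RaterTable

#: ALG vs OPH, n = 3520 patients.
ALG_VS_OPH = RaterTable(
    counts=np.array(
        [
            [455, 379, 33],
            [80, 1582, 64],
            [118, 499, 310],
        ]
    ),
    test_label="ALG",
    reference_label="OPH",
)

#: PCP vs OPH, n = 3520 patients.
PCP_VS_OPH = RaterTable(
    counts=np.array(
        [
            [373, 233, 25],
            [214, 2005, 209],
            [66, 222, 173],
        ]
    ),
    test_label="PCP",
    reference_label="OPH",
)

#: Paired sample (patients gradable under all three strategies, n = 2335).
PAIRED_ALG_VS_OPH = ContingencyTable2x2(tp=418, fp=351, fn=75, tn=1491)
PAIRED_PCP_VS_OPH = ContingencyTable2x2(tp=300, fp=200, fn=193, tn=1642)


def screening_crosstabs() -> dict:
    """All bundled reference tables keyed by comparison name."""
    return {
        "alg_vs_oph": ALG_VS_OPH,
        "pcp_vs_oph": PCP_VS_OPH,
        "paired_alg_vs_oph": PAIRED_ALG_VS_OPH,
        "paired_pcp_vs_oph": PAIRED_PCP_VS_OPH,
    }
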