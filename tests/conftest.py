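"""Shared fixtures: the printed reference statistics and a brute-force oracle.

``PRINTED_TABLE2`` freezes the published per-disease P, RR and PAF values
(3 significant figures) that the bundled count table should reproduce.

``brute_force_statistics`` recomputes P, RR and PAF by explicitly
enumerating the 2*N_T individual twins and tallying the co-twin-exposure
2x2 table directly — an independent route kept deliberately free of the
package's closed-form expressions.
"""

from __future__ import annotations

import math

import pytest

from twinpaf import bundled_table2, estimate

# disease -> (P %, RR, PAF %) as printed at 3 significant figures.
# Known print inconsistency, kept verbatim: the Parkinson row prints P = 10.6,
# yet 2*9/(2*9+151) = 10.6509 -> 10.7; its printed RR and PAF are consistent
# with the unrounded 10.6509.
PRINTED_TABLE2 = {
    "Bladder cancer": (5.03, 8.28, 4.42),
    "Breast cancer (female)": (14.3, 4.60, 11.2),
    "Colorectal cancer": (12.6, 9.35, 11.3),
    "Leukemia": (3.74, 11.3, 3.41),
    "Lung cancer": (10.8, 11.4, 9.89),
    "Ovarian cancer (female)": (4.58, 6.13, 3.83),
    "Pancreatic cancer": (4.65, 11.8, 4.26),
    "Prostate cancer (male)": (21.1, 9.94, 19.0),
    "Stomach cancer": (8.98, 12.5, 8.26),
    "Thyroid autoimmunity": (45.2, 14.3, 42.0),
    "Type 1 diabetes": (23.1, 99.1, 22.8),
    "Type 2 diabetes": (33.9, 25.3, 32.6),
    "Gallstone disease": (19.0, 4.16, 14.4),
    "Alzheimer's disease": (33.3, 32.7, 32.3),
    "Dementia": (27.3, 13.2, 25.2),
    "Chronic fatigue": (31.4, 2.10, 16.4),
    "Gastroesophageal reflux disorder": (33.9, 3.48, 24.2),
    "Irritable bowel syndrome": (22.4, 5.49, 18.3),
    "Coronary heart disease death": (36.4, 2.46, 21.6),
    "Stroke-related death": (18.1, 4.20, 13.8),
    "General dystocia (female)": (31.6, 2.93, 20.8),
    "Pelvic organ prolapse (female)": (30.2, 12.6, 27.8),
    "Stress urinary incontinence (female)": (23.0, 17.6, 21.7),
    "Migraine": (35.7, 4.15, 27.1),
    "Rheumatoid arthritis": (22.0, 28.1, 21.2),
    "Asthma": (53.5, 11.0, 48.6),
    "Parkinson disease": (10.6, 12.0, 9.76),
    "Chronic obstructive pulmonary disease": (19.5, 20.0, 18.5),
}


def brute_force_statistics(nt: int, nc: int, nd: int):
    """(P, RR, PAF) by explicit enumeration of the 2*nt individual twins.

    Returns RR = inf / raises nothing special: mirrors the estimator's
    degenerate conventions so the two routes are comparable wherever the
    statistics are defined; returns None when no individual is affected or
    the unexposed group is empty.
    """
    individuals = []  # (affected, cotwin_affected) per twin
    individuals += [(1, 1), (1, 1)] * nc
    individuals += [(1, 0), (0, 1)] * nd
    individuals += [(0, 0), (0, 0)] * (nt - nc - nd)

    affected = [a for a, _ in individuals if a]
    if not affected:
        return None
    affected_with_affected_cotwin = sum(
        1 for a, e in individuals if a and e
    )
    p = 100.0 * affected_with_affected_cotwin / len(affected)

    exposed = [(a, e) for a, e in individuals if e]
    unexposed = [(a, e) for a, e in individuals if not e]
    if not unexposed:
        return None
    risk_exposed = sum(a for a, _ in exposed) / len(exposed) if exposed else 0.0
    risk_unexposed = sum(a for a, _ in unexposed) / len(unexposed)
    if p == 0.0:
        return (p, risk_exposed / risk_unexposed if risk_unexposed else math.inf, 0.0)
    if risk_unexposed == 0.0:
        return (p, math.inf, p)
    rr = risk_exposed / risk_unexposed
    return (p, rr, p * (rr - 1.0) / rr)


@pytest.fixture(scope="session")
def table2_records():
    return bundled_table2()


@pytest.fixture(scope="session")
def table2_estimates(table2_records):
    return [estimate(r) for r in table2_records]
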