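"""Literature reference values for the OT_n and IS_n index tables.

These are the values as printed in the published tables and closed-form
theorems for the octahedral (OT) and icosahedral (IS) sheet families.  They
are kept verbatim — including their rounding noise and internal
inconsistencies — so that the discrepancy report can compare them against
the definition-faithful values this package computes, rather than silently
patching either side.

Known quirks carried by the printed data (surfaced by
:func:`irrnet.report.discrepancy_report`):

* the IS IRGA row is printed at half the value implied by the IRGA
  definition's prefactor of 2 (the OT table uses the full prefactor), and
  the published IS closed form for IRGA (114.5513 n^2 - 12.72792 n) matches
  neither convention — it is therefore omitted from the closed-form
  reference below;
* the IS IRLA row prints rounding noise on exact integers
  (e.g. 32.000016 where the exact value is 32);
* the IS IRB cell at n = 4 (720.736120) is inconsistent with the published
  closed form for the same row, which gives 720.60612 at n = 4.
"""

from __future__ import annotations

__all__ = [
    "REFERENCE_TABLES",
    "REFERENCE_CLOSED_FORMS",
    "TABLE_N_VALUES",
]

TABLE_N_VALUES: tuple[int, ...] = (1, 2, 3, 4, 5)

#: Printed per-n index values, family -> index id -> values at n = 1..5.
REFERENCE_TABLES: dict[str, dict[str, tuple[float, ...]]] = {
    "OT": {
        "IRDIF": (54, 216, 486, 864, 1350),
        "AL": (144, 576, 1296, 2304, 3600),
        "IRL": (24.953299, 99.813196, 224.579691, 399.252784, 623.832475),
        "IRLU": (36, 144, 324, 576, 900),
        "IRLF": (25.455844, 101.823376, 229.102596, 407.293504, 636.3961),
        "IRF": (576, 2304, 5184, 9216, 14400),
        "IRLA": (24, 96, 216, 384, 600),
        "IRD1": (57.939768, 231.759072, 521.457912, 927.036288, 1448.494200),
        "IRA": (0.772078, 3.088312, 6.948702, 12.353248, 19.30195),
        "IRGA": (4.240189, 16.960756, 38.161701, 67.843024, 106.004725),
        "IRB": (24.70649, 98.82596, 222.35841, 395.30384, 617.66225),
        "IRRt": (72, 288, 648, 1152, 1800),
    },
    "IS": {
        "IRDIF": (72, 306, 702, 1260, 1980),
        "AL": (240, 1020, 2340, 4200, 6600),
        "IRL": (33.271056, 141.40198, 324.392796, 582.24348, 914.954040),
        "IRLU": (48, 204, 468, 840, 1320),
        "IRLF": (33.941136, 144.249828, 330.926076, 593.969880, 933.381240),
        "IRF": (1200, 5100, 11700, 21000, 33000),
        "IRLA": (32.000016, 136.000068, 312.000156, 560.000280, 880.000440),
        "IRD1": (86.004432, 365.518836, 838.543212, 1505.07756, 2365.1218),
        "IRA": (0.823536, 3.500028, 8.029476, 14.411880, 22.647240),
        "IRGA": (2.826768, 12.013764, 27.560988, 49.468440, 77.736120),
        "IRB": (41.177472, 175.004256, 401.480352, 720.736120, 1132.380480),
        "IRRt": (120, 510, 1170, 2100, 3300),
    },
}

#: Printed closed-form coefficients (a2, a1) of a2 n^2 + a1 n per family and
#: index (the constant term is 0 throughout).  The IS IRGA entry is omitted:
#: the printed coefficient set is internally inconsistent (see module
#: docstring); the package reports the definition-faithful form instead.
REFERENCE_CLOSED_FORMS: dict[str, dict[str, tuple[float, float]]] = {
    "OT": {
        "IRDIF": (54, 0),
        "AL": (144, 0),
        "IRL": (24.953299, 0),
        "IRLU": (36, 0),
        "IRLF": (25.455844, 0),
        "IRF": (576, 0),
        "IRLA": (24, 0),
        "IRD1": (57.939768, 0),
        "IRA": (0.772078, 0),
        "IRGA": (4.240189, 0),
        "IRB": (24.70649, 0),
        "IRRt": (72, 0),
    },
    "IS": {
        "IRDIF": (81, -9),
        "AL": (270, -30),
        "IRL": (37.429938, -4.158883),
        "IRLU": (54, -6),
        "IRLF": (38.18377, -4.242641),
        "IRF": (1350, -150),
        "IRLA": (36, -4),
        "IRD1": (96.7550, -10.75056),
        "IRA": (0.926494, -0.102944),
        "IRB": (46.32468, -5.14719),
        "IRRt": (135, -15),
    },
}
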