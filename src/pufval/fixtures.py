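"""Published summary tables, embedded so analyses run offline.

``table8`` holds the pilot sample's unanchored weights (decrements) for
the EQ-5D dimensions and levels on a 0-1 scale; ``table9`` the
dead-anchored social-utility-function (value set) decrements.  Both were
computed over the n = 60 respondents with tailored adaptive tasks,
excluding one outlier.  Columns: min, 1st quartile, median, mean,
3rd quartile, max, SD, SE.
"""

from __future__ import annotations

import io

import pandas as pd

from .aggregation import DecrementSummary

_TABLE8 = """\
dimension,level,min,q1,median,mean,q3,max,sd,se
MO,2,0.0000,0.0774,0.1092,0.1133,0.1571,0.2857,0.0630,0.0115
MO,3,0.0364,0.1955,0.2066,0.2061,0.2236,0.2941,0.0375,0.0069
SC,2,0.0000,0.0716,0.0922,0.0954,0.1200,0.2105,0.0448,0.0082
SC,3,0.0714,0.1745,0.1967,0.1905,0.2081,0.3125,0.0391,0.0071
UA,2,0.0000,0.0736,0.0997,0.1044,0.1397,0.2857,0.0544,0.0099
UA,3,0.0735,0.1818,0.1929,0.1942,0.2093,0.2857,0.0359,0.0066
PD,2,0.0000,0.0630,0.1105,0.1104,0.1468,0.3571,0.0653,0.0119
PD,3,0.1266,0.1998,0.2099,0.2188,0.2346,0.3636,0.0413,0.0075
AD,2,0.0000,0.0568,0.0970,0.0916,0.1169,0.2353,0.0518,0.0095
AD,3,0.0000,0.1800,0.1939,0.1904,0.2131,0.2941,0.0526,0.0096
"""

_TABLE9 = """\
dimension,level,min,q1,median,mean,q3,max,sd,se
MO,2,0.0000,0.1238,0.1664,0.1793,0.2341,0.4706,0.1058,0.0137
MO,3,0.0660,0.2253,0.3025,0.3440,0.3950,0.8444,0.1639,0.0212
SC,2,0.0000,0.0948,0.1560,0.1600,0.2025,0.4540,0.0931,0.0120
SC,3,0.0714,0.2232,0.2794,0.3146,0.3391,0.7111,0.1431,0.0185
UA,2,0.0000,0.1083,0.1456,0.1699,0.2251,0.4191,0.0979,0.0126
UA,3,0.0735,0.2203,0.2941,0.3198,0.3575,0.8000,0.1418,0.0183
PD,2,0.0000,0.1032,0.1600,0.1801,0.2351,0.4959,0.1197,0.0154
PD,3,0.1618,0.2345,0.3237,0.3653,0.4338,0.8889,0.1709,0.0221
AD,2,0.0000,0.0832,0.1426,0.1536,0.2145,0.3944,0.1040,0.0134
AD,3,0.0000,0.2091,0.2874,0.3234,0.4151,0.7556,0.1697,0.0219
"""

_FIXTURES = {"table8": _TABLE8, "table9": _TABLE9}
_FIXTURE_N = 60


def load_paper_fixture(name: str) -> DecrementSummary:
    """Return an embedded published summary table by name.

    ``"table8"`` — unanchored dimension/level weights; ``"table9"`` — the
    dead-anchored value-set decrements.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {sorted(_FIXTURES)}")
    df = pd.read_csv(io.StringIO(_FIXTURES[name])).set_index(["dimension", "level"])
    return DecrementSummary(table=df, n=_FIXTURE_N)
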