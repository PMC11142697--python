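"""Published reference inputs for the world yield-projection analysis.

The projection equations below are the selected trend-regression fits (and the
competing ARIMA candidates' RMSEs) reported for world average and top-national
yields of rice, wheat, maize and soybean on FAOSTAT series 1961-2019, under
the ordinal convention x = 1 at 1961.  They are frozen here as *inputs*: the
gap, potential-limit and percent-change arithmetic of the 2020-2030 horizon is
fully determined by these equations, with no data download.

``TOP_COUNTRY_YEARS`` transcribes the documented record of which country held
the world-top yield of each crop in each year 1961-2021.  One inconsistency in
the source record (rights to 1989 for soybean claimed by both Ethiopia PDR and
Italy) is resolved in favour of Ethiopia PDR, the only reading consistent with
the published per-country totals (Italy 19 years, Ethiopia PDR 12, sum 61).
"""
from __future__ import annotations

from .trend import TrendResults

__all__ = [
    "REFERENCE_TRENDS",
    "REFERENCE_ARIMA",
    "TOP_COUNTRY_YEARS",
    "top_country_map",
    "T_PRE_INDUSTRIAL",
    "WARMING_FLOOR",
    "WARMING_CEILING",
]

ORIGIN = 1961
_WINDOW = (1961, 2019)


def _trend(form, params, rmse):
    return TrendResults.from_params(form, params, origin=ORIGIN, rmse=rmse,
                                    fitting_window=_WINDOW)


#: Selected trend equations, params ordered (b0, b1[, b2]) for
#: y = b0 + b1 x + b2 x^2, or (b0, b1) for the power form y = b0 x^b1.
REFERENCE_TRENDS: dict[tuple[str, str], TrendResults] = {
    ("rice", "average"): _trend("polynomial2", (1740.0, 60.072, -0.1531), 79.8150),
    ("wheat", "average"): _trend("polynomial2", (1055.0, 46.042, -0.0941), 84.1059),
    ("maize", "average"): _trend("polynomial2", (1919.3, 54.812, 0.2025), 172.1341),
    ("soybean", "average"): _trend("polynomial2", (1163.0, 24.648, 0.0372), 87.4512),
    ("rice", "top"): _trend("polynomial2", (6285.3, 104.09, -0.6739), 170.5170),
    ("wheat", "top"): _trend("polynomial2", (3388.1, 184.25, -1.2742), 507.2709),
    ("maize", "top"): _trend("polynomial2", (5516.6, 167.46, 5.8741), 2884.0172),
    ("soybean", "top"): _trend("power", (1764.4, 0.2062), 520.1776),
}

#: The competing ARIMA candidate reported for each series: (p, d, q), RMSE kg/ha.
REFERENCE_ARIMA: dict[tuple[str, str], tuple[tuple[int, int, int], float]] = {
    ("rice", "average"): ((1, 1, 1), 328.9316),
    ("wheat", "average"): ((1, 1, 2), 248.9672),
    ("maize", "average"): ((0, 1, 1), 292.9550),
    ("soybean", "average"): ((0, 0, 1), 141.1935),
    ("rice", "top"): ((1, 1, 2), 1059.049),
    ("wheat", "top"): ((1, 1, 1), 1047.800),
    ("maize", "top"): ((1, 1, 2), 3720.655),
    ("soybean", "top"): ((0, 0, 2), 669.1066),
}

# Year specs are single years or inclusive (first, last) ranges.
_TOP_COUNTRY_SPECS: dict[str, dict[str, tuple]] = {
    "rice": {
        "Australia": (1962, (1965, 1969), 1971, 1973, 1989, 1991, (1998, 1999),
                      2001, 2010, (2013, 2019), 2020),
        "Dominica": (1992,),
        "Egypt": ((1996, 1997), 2000, 2002, (2004, 2009), (2011, 2012), 2021),
        "North Korea": (1993,),
        "Puerto Rico": (1961, (1963, 1964), 1970, 1972, (1974, 1983)),
        "Swaziland": ((1984, 1988), 1990),
        "Syria": ((1994, 1995),),
        "Uzbekistan": (2003,),
    },
    "wheat": {
        "Belgium": (1997, 2009),
        "Denmark": (1961, (1965, 1966), 1968, 1975),
        "France": (1972,),
        "Ireland": (1969, (1987, 1988), (1990, 1991), 1996, (1999, 2002), 2004,
                    2006, 2011, (2014, 2017), 2019, 2021),
        "Luxembourg": (1998,),
        "Netherlands": ((1962, 1964), 1967, (1970, 1971), (1973, 1974),
                        (1976, 1986), 1989, (1992, 1995), 2003, 2005, 2010),
        "New Zealand": (2007, (2012, 2013), 2018, 2020),
        "Zambia": (2008,),
    },
    "maize": {
        "France": ((1961, 1968),),
        "Greece": ((1983, 1984),),
        "Israel": ((1985, 1987), 1990, (2010, 2011)),
        "Jordan": (1992, (2002, 2003), 2005, 2019, 2020),
        "Kuwait": (1981, 1988, 1996),
        "Netherlands": ((1977, 1978),),
        "New Zealand": ((1969, 1976), (1979, 1980), 1982),
        "Qatar": (1989,),
        "Saint Vincent and the Grenadines": (2012, 2021),
        "United Arab Emirates": (1991, (1993, 1995), (1997, 2001), 2004,
                                 (2006, 2009), (2013, 2018)),
    },
    "soybean": {
        "Canada": (1961,),
        "Egypt": (2003,),
        "Ethiopia PDR": ((1970, 1972), (1979, 1983), 1985, (1987, 1989)),
        "Italy": (1967, 1973, 1974, 1977, 1984, 1986, (1990, 1999), 2001, 2002, 2005),
        "Mexico": (1962, 1963, 1965),
        "New Zealand": (1975, 1976, 1978),
        "Paraguay": (1964, 1966, 1968, 1969),
        "Switzerland": (2000,),
        "Turkey": (2004, (2006, 2021)),
    },
}


def _expand(specs: dict[str, tuple]) -> dict[str, tuple[int, ...]]:
    out = {}
    for country, items in specs.items():
        years: list[int] = []
        for item in items:
            if isinstance(item, tuple):
                years.extend(range(item[0], item[1] + 1))
            else:
                years.append(item)
        out[country] = tuple(sorted(years))
    return out


#: crop -> country -> tuple of calendar years holding the world-top yield.
TOP_COUNTRY_YEARS: dict[str, dict[str, tuple[int, ...]]] = {
    crop: _expand(specs) for crop, specs in _TOP_COUNTRY_SPECS.items()
}


def top_country_map(crop: str) -> dict[int, str]:
    """year -> top country for one crop; the years partition 1961-2021."""
    out: dict[int, str] = {}
    for country, years in TOP_COUNTRY_YEARS[crop].items():
        for y in years:
            if y in out:
                raise ValueError(f"{crop}: year {y} assigned to both {out[y]} and {country}")
            out[y] = country
    return out


# 'Carbon Peak' climate constants: pre-industrial global mean temperature and
# the Paris-Agreement warming band.
T_PRE_INDUSTRIAL = 13.8  # deg C
WARMING_FLOOR = 1.5      # deg C
WARMING_CEILING = 2.0    # deg C
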