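"""Published summary statistics used as worked-example inputs.

These are the printed descriptive and correlation tables from a seven-year
(2008-2014) registry study of daily ischemic-stroke onset and air pollution
in Shenzhen, a subtropical coastal megacity.  The underlying registry data
are not public, so the tables serve two roles here: (i) arithmetic
worked-example inputs (the IQR identity P75 - P25, the case-mix proportions,
the collinearity pairing rule applied to the printed Spearman matrix), and
(ii) the template the synthetic-data generator's marginals emulate.

Note: the printed CO row's median (0.14) is a typographical artifact (it sits
between P25 = 0.91 and P75 = 1.43); the median is never consumed here.  All
values are as printed, rounded to two (descriptives) or four (correlations)
decimals, so identities hold to +/-0.01.
"""

from __future__ import annotations

import pandas as pd

_DESC_COLUMNS = [
    "mean", "sd", "min", "p1", "p5", "p10", "p25", "p50", "p75", "p90",
    "p95", "p99", "max", "iqr",
]

_DESC_ROWS = {
    "total": [25.03, 9.88, 4.00, 8.00, 12.00, 14.00, 18.00, 23.00, 31.00, 38.00, 43.00, 53.00, 95.00, 13.00],
    "male": [14.89, 6.55, 1.00, 4.00, 6.00, 8.00, 10.00, 14.00, 18.00, 24.00, 27.00, 35.00, 64.00, 8.00],
    "female": [10.14, 4.63, 1.00, 2.00, 4.00, 5.00, 7.00, 9.00, 13.00, 16.00, 18.00, 24.00, 42.00, 6.00],
    "elderly": [12.12, 5.51, 1.00, 3.00, 5.00, 6.00, 8.00, 11.00, 15.00, 19.00, 22.00, 29.00, 54.00, 7.00],
    "adult": [12.90, 5.69, 0.00, 3.00, 5.00, 6.00, 9.00, 12.00, 16.00, 20.00, 23.00, 29.00, 42.00, 7.00],
    "so2": [11.97, 6.95, 2.95, 3.71, 4.74, 5.61, 7.35, 10.06, 14.44, 20.35, 25.50, 37.86, 70.63, 7.09],
    "no2": [45.89, 19.96, 13.13, 18.51, 23.17, 25.93, 32.30, 41.29, 54.14, 72.11, 85.04, 116.26, 166.14, 21.84],
    "pm10": [55.91, 30.26, 10.86, 16.14, 21.04, 23.96, 31.44, 48.29, 74.66, 97.67, 114.17, 145.94, 182.23, 43.21],
    "co": [1.22, 0.44, 0.37, 0.50, 0.66, 0.75, 0.91, 0.14, 1.43, 1.88, 2.10, 2.46, 3.25, 0.52],
    "o3": [53.49, 21.85, 6.02, 16.00, 23.80, 28.89, 36.73, 49.82, 67.78, 83.71, 93.99, 111.57, 143.33, 31.04],
    "temperature": [23.03, 5.66, 5.40, 8.80, 12.20, 14.60, 19.00, 24.50, 27.80, 29.30, 29.80, 30.60, 32.00, 8.80],
    "relative_humidity": [72.83, 13.35, 19.00, 32.00, 47.00, 54.00, 66.00, 75.00, 82.00, 88.00, 91.00, 97.00, 100.00, 16.00],
}

#: Printed descriptive table (mean, SD, percentiles, IQR) per daily variable.
REFERENCE_DESCRIPTIVES = pd.DataFrame.from_dict(
    _DESC_ROWS, orient="index", columns=_DESC_COLUMNS
)

_SPEARMAN_VARS = ["so2", "no2", "pm10", "o3", "co", "temperature", "relative_humidity"]
_SPEARMAN = [
    [1.0000, 0.6344, 0.7017, 0.1404, 0.4063, -0.2481, -0.4962],
    [0.6344, 1.0000, 0.7008, 0.0685, 0.2926, -0.3123, -0.2382],
    [0.7017, 0.7008, 1.0000, 0.4623, 0.3485, -0.3225, -0.5461],
    [0.1404, 0.0685, 0.4623, 1.0000, -0.0101, -0.0380, -0.4165],
    [0.4063, 0.2926, 0.3485, -0.0101, 1.0000, -0.3223, -0.2073],
    [-0.2481, -0.3123, -0.3225, -0.0380, -0.3223, 1.0000, 0.3078],
    [-0.4962, -0.2382, -0.5461, -0.4165, -0.2073, 0.3078, 1.0000],
]

#: Printed Spearman correlation matrix among pollutants and meteorology.
REFERENCE_SPEARMAN = pd.DataFrame(
    _SPEARMAN, index=_SPEARMAN_VARS, columns=_SPEARMAN_VARS
)

#: Printed case totals over the study period (for the case-mix proportions).
REFERENCE_CASE_COUNTS = {"total": 63_997, "male": 38_070, "elderly": 31_000}
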