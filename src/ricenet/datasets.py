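"""Small reference datasets bundled with the package.

Mean grain-yield component values of five transgenic HYR rice lines and
their wild-type control, from replicated pot trials under well-watered and
reproductive-stage drought conditions.  ``pct_increase_gy_printed`` is the
percent-increase column as originally reported (computed by its authors
from unrounded means, so recomputing from the 1-2 decimal GY means printed
here can differ by up to 0.1 percentage points).
"""

from __future__ import annotations

import pandas as pd

_WELL_WATERED = [
    # genotype, NP, PL, NSP, NFG, NGP, GY (g/plant), printed % increase GY
    ("WT", 9.2, 19.5, 72.9, 223.9, 76.4, 13.8, None),
    ("HYR-2", 11.4, 22.05, 77.3, 306.4, 82.5, 17.9, 29.7),
    ("HYR-4", 11.0, 23.04, 77.7, 289.8, 80.1, 17.53, 27.0),
    ("HYR-12", 11.3, 22.82, 77.8, 331.9, 80.5, 14.85, 7.6),
    ("HYR-16", 11.2, 23.15, 78.3, 193.3, 81.2, 16.08, 16.5),
    ("HYR-45", 10.8, 22.09, 78.6, 270.7, 80.6, 17.52, 26.9),
]

_DROUGHT = [
    ("WT", 8.0, 15.26, 67.4, 194.2, 68.4, 9.96, None),
    ("HYR-2", 10.7, 20.02, 72.6, 271.1, 79.4, 13.86, 39.1),
    ("HYR-4", 9.6, 21.99, 74.5, 256.9, 76.6, 12.22, 22.7),
    ("HYR-12", 9.9, 20.33, 73.3, 282.7, 76.1, 11.35, 13.9),
    ("HYR-16", 9.5, 20.56, 74.2, 199.1, 77.9, 11.76, 18.0),
    ("HYR-45", 9.6, 19.91, 75.6, 249.8, 77.5, 11.94, 19.8),
]

_COLUMNS = ["genotype", "NP", "PL", "NSP", "NFG", "NGP", "GY", "pct_increase_gy_printed"]

#: Grain-yield means recomputed exactly from the printed GY columns agree
#: with the printed percent-increase cells on these genotypes; the remaining
#: cells reflect the authors' unrounded means (|difference| <= 0.1).
EXACTLY_CONSISTENT_CELLS = {
    "well_watered": ("HYR-2", "HYR-4", "HYR-12", "HYR-16"),
    "drought": ("HYR-4",),
}


def grain_yield_trials() -> dict[str, pd.DataFrame]:
    """Yield-component means per water regime, one row per genotype."""
    return {
        "well_watered": pd.DataFrame(_WELL_WATERED, columns=_COLUMNS),
        "drought": pd.DataFrame(_DROUGHT, columns=_COLUMNS),
    }
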