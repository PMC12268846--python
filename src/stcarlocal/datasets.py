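"""Bundled reference tables.

The package ships one small plain-text table: published posterior
relative-risk estimates and cluster labels for the 34 Indonesian provinces
over 2020-2022, from a five-group spatio-temporal localized CAR analysis of
national stunting counts.  The underlying count data are not publicly
downloadable, but the published point estimates are useful as fixed inputs
for exercising the ranking and cluster-summary machinery.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def published_indonesia_stunting_risk() -> pd.DataFrame:
    """Published province-level stunting RR estimates, long format.

    Columns: ``area`` (province), ``time`` (year, as string), ``ls``
    (cluster label 1-5 of the localized structure) and ``rr`` (posterior
    relative risk).  34 provinces x 3 years = 102 rows.
    """
    with resources.files("stcarlocal.data").joinpath(
        "indonesia_stunting_rr_2020_2022.csv"
    ).open() as fh:
        df = pd.read_csv(fh, dtype={"time": str})
    return df
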