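"""Small packaged tables for the worked segregation examples.

These reproduce the printed genotype/phenotype summaries this package's
statistics are validated against: maturity-date segregation counts in two
F1 crosses, the landrace TE-carrier survey, the haplotype-combination →
colour-intensity rule table, and the marker–phenotype co-segregation
counts (143 carrier/blood + 190 non-carrier/non-blood individuals).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_md_segregation() -> pd.DataFrame:
    """Maturity-date (FDP class) segregation counts in two F1 crosses,
    split by blood-TE carrier status, with the printed chi-square values."""
    return _load("md_segregation.tsv")


def load_te_carrier_survey(expand: bool = False) -> pd.DataFrame:
    """Blood-TE carriers among wild varieties and landrace groups.

    With ``expand=True`` the aggregated counts are unrolled to one row per
    accession (columns ``group``, ``carrier``), the shape
    :func:`bloodpeach.segregation.carrier_ratio` consumes.
    """
    df = _load("te_carrier_survey.tsv")
    if not expand:
        return df
    rows = [
        {"group": r.group, "carrier": i < r.carriers}
        for r in df.itertuples()
        for i in range(r.n)
    ]
    return pd.DataFrame(rows)


def load_color_rules() -> pd.DataFrame:
    """Haplotype combination (blood TE, D, T) -> flesh-colour intensity."""
    return _load("color_rules.tsv")


def load_cosegregation(expand: bool = False) -> pd.DataFrame:
    """Blood-TE presence vs blood-flesh phenotype counts (n = 333).

    With ``expand=True``: one row per individual with boolean ``te_present``
    and ``blood_flesh`` columns.
    """
    df = _load("cosegregation.tsv")
    if not expand:
        return df
    present = df["te_present"].astype(str).str.lower() == "true"
    rows = [
        {"te_present": p, "blood_flesh": f == "blood"}
        for p, f, c in zip(present, df["flesh"], df["count"])
        for _ in range(c)
    ]
    return pd.DataFrame(rows)
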