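"""Bundled reference tables from the motivating study.

The package was built around a faecal-metabolome study of paediatric Crohn's
disease during exclusive enteral nutrition (EEN): eleven healthy controls
(``HC``) and eleven patients sampled before (``PA``), during (``PB``–``PD``)
and after (``PE``) treatment.  The raw LC-MS data are not public, but three
small published summary tables are shipped here as worked examples and as
fixed points for the statistics this package implements:

* :func:`load_model_verdicts` — validation summaries (R2X, R2, Q2,
  permutation outcome, CV-ANOVA p, validity/significance labels) for all 15
  pairwise OPLS-DA group models;
* :func:`load_fatty_acid_concentrations` — per-sample arachidonic- and
  eicosatrienoic-acid concentrations (µg/g dry faeces) for the control and
  pre-treatment groups, from external-calibration quantification;
* :func:`load_marker_evidence` — the eight-marker evidence table of the
  pre-treatment vs control comparison (fold ratio, p, q, AUC, VIP split).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_model_verdicts",
    "load_fatty_acid_concentrations",
    "load_marker_evidence",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("metabomark.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_model_verdicts() -> pd.DataFrame:
    """Published validation summary for the 15 pairwise OPLS-DA models."""
    df = _read("een_model_verdicts.csv")
    for col in ("permutation_pass", "valid", "significant"):
        df[col] = df[col] == "yes"
    return df


def load_fatty_acid_concentrations() -> pd.DataFrame:
    """Quantified fatty acids (µg/g dry faeces) for HC and PA samples."""
    return _read("fatty_acid_concentrations.csv")


def load_marker_evidence() -> pd.DataFrame:
    """Evidence table for the eight PA-vs-HC marker metabolites."""
    return _read("pa_hc_markers.csv")
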